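# clinterm

Multiword terminology extraction for morphologically tagged clinical text
in inflectional languages, built around C-value / NC-value termhood
ranking with a C₁ context-counting variant suited to languages with rich
nominal inflection (the shipped grammar and test lexicon target Polish
hospital discharge summaries).

## Who it is for

Clinical-NLP practitioners who have a POS/morphology-tagged corpus of
domain text (e.g. discharge summaries) and want a ranked list of candidate
domain terms — single nouns, acronyms and multiword noun phrases — as raw
material for dictionaries, extraction rules or ontologies.  No term list
or annotated training data is required; the method is unsupervised.

## The method

1. **Candidate extraction.**  A cascade of six ordered sets of shallow
   rules chunks each sentence into maximal noun phrases.  Rules rewrite
   matched item sequences bottom-up (basic nominals and adjectives →
   hyphenated compounds and agreement pairs → adjectival phrases → basic
   noun phrases → genitive chains → full phrases), unifying case, gender
   and number; non-inflecting items (acronyms, foreign words) are
   agreement wildcards.  Stop-lemma classes (time words, introductory
   words) may not open a phrase.  A `simplified` mode ignores all
   morphological constraints (POS-only matching) for ablation studies.

2. **Nested phrases and normalisation.**  Every proper sub-span of a
   maximal phrase that the grammar itself accepts as a noun phrase is a
   nested candidate.  Candidates are identified by their *simplified base
   form* — the sequence of token lemmas — so inflectional variants of the
   same phrase, and the same phrase nested in differently inflected
   containers, all merge.

3. **Ranking.**  For a phrase *p* with total frequency *freq(p)*
   (standalone + nested), token length *length(p)*, *r* distinct nesting
   contexts and total nested frequency *F*:

       C-value(p) = l(p) · freq(p)                 if r = 0
       C-value(p) = l(p) · (freq(p) − F / r)       if r > 0

   with *l(p) = log₂(length(p))*, and *l(p) = 0.1* for single words.  A
   phrase that never occurs standalone and has at most one distinct
   context scores 0.  Three context-counting schemes are provided:
   `original` (distinct containing phrases), `grouped_words` (distinct
   adjacent words, both sides pooled) and `max_separate` — the **C₁**
   variant, max of the distinct-left-word and distinct-right-word counts —
   which stops a single super phrase with varying decorations from
   inflating a fragment's score.  NC-value then mixes in external
   one-word contexts shared with the top-ranked terms:

       NC(t) = 0.8 · C(t) + 0.2 · Σ_b f_t(b) · weight(b),
       weight(b) = t(b) / n

   over adjective/noun/verb neighbours *b* of the top *n* = 300 terms.

4. **Optional stages.**  Comparison against the same pipeline's output on
   a general reference corpus (annotation only), and tiered matching
   against a controlled vocabulary (exact → nested-in-entry → approximate
   with suffix-stripping and a position-weighted Levenshtein similarity
   in which edits near the end of a word — where inflection lives — cost
   less than edits near the start).

## Worked example

The corpus format is one token per line (`surface TAB lemma TAB tag`),
blank line between sentences.  Generate a synthetic tagged corpus with a
known phrase plan and run the pipeline:

    clinterm gen-fixtures --out corpus.vert \
        --plan karta4=1164 --plan karta5=1
    clinterm extract --corpus corpus.vert --out inventory.tsv
    clinterm rank --inventory inventory.tsv --out ranked.tsv --top-k 10

`ranked.tsv` begins:

    rank  form                                           length  c_value  c1_value  nc_value  freq_standalone  freq_nested
    1     karta informacyjny leczyć szpitalny            4       2328.0   2328.0    1862.4    1164             1
    2     poprzedni karta informacyjny leczyć szpitalny  5       2.32     2.32      1.86      1                0
    3     karta                                          1       58.25    0.0       0.0       0                1165
    4     karta informacyjny                             2       582.5    0.0       0.0       0                1165
    5     karta informacyjny leczyć                      3       923.24   0.0       0.0       0                1165

Reading the top row: the 4-token phrase occurred 1164 times on its own
and once nested (inside the 5-token variant), giving C₁ =
log₂(4)·(1165 − 1/1) = 2328; with no eligible external context words its
NC-value is 0.8·2328 = 1862.40.  The 3-token prefix `karta informacyjny
leczyć` never occurs standalone and keeps the same right neighbour in
both containers, so the C₁ scheme sees a single context and zeroes it —
while the `original` scheme, which counts distinct containing phrases,
would have scored the never-observed fragment 923.24 (the `c_value`
column), illustrating exactly the fragment-promotion problem the C₁
variant exists to fix.

The remaining commands wire up the optional stages:
`clinterm compare-ref` annotates a ranked list against a reference-corpus
ranking, and `clinterm match-thesaurus` reports the match tier of each
term against a plain-text controlled vocabulary.

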