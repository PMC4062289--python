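# Methods

## Problem and scope

`clinterm` extracts and ranks candidate domain terms from a corpus of
morphologically tagged clinical text in an inflectional language.  The
input is assumed to be already tokenised and tagged (surface, lemma, word
class, case/gender/number); running a tagger is out of scope, as are
spelling correction, prepositional-phrase terms, noun coordination and
acronym-definition mining.  Only nominal terms are targeted: in clinical
sublanguage almost all terminology is realised as noun phrases.

## Candidate extraction: the cascade

The grammar is six ordered rule sets applied as a cascade: each level
scans its input left to right, at each position tries all of its rules,
rewrites the longest match (ties resolved by file order) into a single
categorized item, and continues after it.  The output of level VI is a
sequence in which items of category `X` are the maximal noun phrases.
This leftmost-longest, single-segmentation policy is what makes the
parser deterministic and the phrase set non-overlapping — both properties
the counting stage relies on.

Agreement is enforced by unification variables over case, gender and
number.  Non-inflecting items (acronym abbreviations, foreign-word runs
of up to three tokens) carry no features and unify with anything — they
can head or close a phrase but can never be a *source* of feature values.
Head indices (`head:` in the rule file) say which right-hand-side
position supplies the morphology of the rewritten item, e.g. the
adjective in an adverb–adjective group, or the trailing adjective in a
hyphenated compound (`adja + "-" + adj`), where the feature copy from the
final element is the reading we adopt for the head-marking of the
compound rules.

Two deliberate deviations from a minimal transcription of the rule
schema:

* **Stop-class rules fire at level I.**  Stop nouns (NZ) and stop
  modifiers (AZ) — time and duration words, month/weekday names,
  introductory words like "cel" (goal) or "kierunek" (direction) — are
  recognised before the plain nominal/adjective rules, so a stop lemma
  never becomes a nominal and no phrase can open with one.  Only
  phrase-initial stop items are excluded; a stop lemma later in a phrase
  does not break it.  The shipped lists contain the documented members
  and the three stated classes and are plain editable text files.
* **A bare non-inflecting nominal is promoted to a basic noun phrase.**
  Without this, no acronym-headed phrase (`USG jamy brzusznej`) and no
  single-acronym term (`RTG`) could ever be recognised, although both
  are canonical term shapes.  The promotion happens at level VI
  (acronym-headed phrase rule) rather than level IV, so the
  trailing-acronym rule (`X -> NG + NC`) stays expressible and remains
  gated behind `allow_trailing_acronym` — it is known to over-generate
  when punctuation is sparse, so users can disable it.

`simplified` mode keeps the category structure and drops every
morphological constraint (agreement variables and literal case
requirements alike).  Its candidate set is a superset of the full mode's
on the shipped fixtures, which the tests assert; this is an empirical
property of noun-phrase-dominated input, not a theorem about arbitrary
cascades.

## Nested phrases and simplified base forms

A term's identity is its *simplified base form*: the sequence of its
tokens' lower-cased lemmas, with special-character tokens (the hyphen of
a compound) contributing their surface.  This deliberately avoids
generating a grammatical nominative phrase: the lemma sequence of a
nested phrase is always a contiguous slice of its container's lemma
sequence, which makes nested counting a pure substring affair.  The known
cost is conflation — singular/plural genitive modifiers, adjective
degrees, negated/positive participles, and gerund/participle pairs
sharing an infinitive lemma all merge — and is accepted.

Nested candidates are found by **re-parsing every proper sub-span** of a
maximal phrase with the same cascade and keeping those that reduce to a
single noun phrase.  The alternative — reading nested phrases off the
derivation tree — misses truncations that cross constituent boundaries
(e.g. a 4-token phrase's 3-token prefix whose last word opens the
container's genitive group), and exactly such truncations are the
motivating examples for the C₁ scheme.  Re-parsing is O(L²) sub-spans per
phrase with L ≤ ~12 in practice; cost is negligible.  Adjective-only
fragments can never qualify because no rule derives a noun phrase from a
bare adjectival group.

Each nested occurrence stores the full lemma sequences flanking it inside
its container, once per containing token occurrence (1164 repetitions of
one super phrase are 1164 nested counts).  From these the three context
notions are derived without re-scanning the corpus.

## Ranking

Definitions as in the README.  Numerical and policy choices:

* `unigram_l = 0.1`.  Single words keep a non-zero score but are strongly
  demoted; with 1.0 they would flood the top of the list in data where a
  third of candidates are single words.
* The zero rule applies only to candidates with `freq_standalone = 0`
  and at most one distinct context: an observed standalone phrase is
  never zeroed merely for having one context.
* Under every context scheme the subtracted term keeps the **total**
  nested frequency `F`; only the divisor `r` changes.  Empty context
  sides (phrase-initial/final nesting) are not counted as context words.
* C₁ ≤ C holds structurally: the max-of-sides count never exceeds the
  distinct-container count, and both zero rules coincide.  The property
  suite checks this on random records and on generated corpora.
* NC uses the lemmas, not surfaces, of adjacent words (appropriate for
  an inflectional language), restricted to adjective/noun/verb classes;
  punctuation and prepositions are ignored.  Context statistics are
  collected from a term's standalone (maximal-phrase) occurrences only:
  the neighbours of a nested occurrence lie inside another candidate and
  are already the C-value's business.  `n` in `weight(b) = t(b)/n` is
  the size of the considered top list (`top_k = 300`; all terms, with a
  warning, when fewer exist).
* Ties in ranking are broken by total frequency, then lexicographically
  by form, so runs are exactly reproducible.

## Reference-corpus comparison and thesaurus matching

The reference stage annotates each domain term as absent / present /
present-with-higher-reference-C₁ against a ranked list produced by the
same pipeline on a general corpus, and tallies the groups split by
single- vs multi-word.  It does not filter: in clinical text the
common phrases are mostly still medical, and corpus sizes are not
comparable.

Thesaurus matching is tiered: exact word-sequence equality (headings and
synonyms), containment as a contiguous subsequence of a longer entry,
then approximate matching in which every term word must have a
sufficiently similar entry word at stem level.  Stems are produced by
stripping one longest matching suffix from a shipped table of nominal and
adjectival endings (never below 3 characters).  Similarity is a weighted
Levenshtein: an edit at alignment position *i* of a pair whose longer
word has length *L* costs `1 − (i−1)/(2L)` — a linear end-discount, so an
edit at the last position costs about half of one at the first —
normalised by the all-positions worst case.  The qualitative requirement
is only that end differences (residual inflection) matter less than stem
differences; the linear form is our choice, isolated in one function,
with the ordering property enforced by test.  The similarity threshold
(default 0.8) is configurable; no canonical value exists.  Because
approximate matching on simplified forms misses gerund heads whose lemma
is an infinitive ("leczenie" vs lemma "leczyć"), `match_term` also
accepts caller-supplied alternative word sequences which the exact and
containment tiers consider.

## Synthetic fixtures: what they do and do not show

No clinical corpus can be shipped, so all tests run on generated corpora.
A fixture is a plan mapping hand-tagged phrase templates to occurrence
counts; the generator realises the plan exactly, one phrase per sentence
with a sentence-final period, optionally interleaves filler sentences
drawn from a closed non-nominal vocabulary (so filler can never create a
candidate), and shuffles sentences with a fixed seed.  Templates cover
the canonical structures: adjective pre/post-modification, genitive
chains, gerund heads, acronym heads, hyphenated compounds, stop-word
prefixes and an agreement-violating pair.  Each template declares which
of its sub-spans are noun phrases; that metadata is hand-derived from the
rule definitions, not computed by the parser, and the expected C/C₁
scores are obtained from it by a direct transcription of the defining
formula — together they form the end-to-end oracle.

Plan counts in the shipped scenarios reproduce published
frequency/nesting configurations (e.g. 1164 standalone + 1 nested
occurrence of a 4-token phrase; 116/117/833/1156 standalone occurrences
at lengths 2 and 4), so the corresponding scores are recomputed rather
than asserted; corpora of a thousand-odd short sentences run the whole
pipeline in seconds.

What passing these tests does **not** show: robustness to tagging
errors, to ad-hoc abbreviations without dictionary entries, to
misspellings, to the full thousand-tag national tagset, or to the
density and ambiguity of real ward notes.  The fixture morphology is a
miniature paradigm (two cases × two numbers × three genders); the
grammar only consults the agreement triple, so this suffices for
correctness of the mechanics, not for coverage claims on real data.
One worked example is idealised: the genitive-chain template tags its
middle noun as genitive although the natural phrase has an oblique
(instrumental) complement, which the genitive-only grammar would split;
with the idealised tagging the re-parse enumeration also yields the
head and the head+first-modifier prefix among the nested candidates.

## Known limitations

* Coordination is supported only inside adjectival phrases (single
  conjunction lemma "i"); noun-phrase coordination and prepositional
  complements are not extracted.
* Simplified-form conflation can merge antonyms (negated participles).
* The trailing-acronym rule over-generates on punctuation-poor text;
  disable it via `allow_trailing_acronym=False` / `--no-trailing-acronym`
  if that matters more than acronym-final terms.
* The NC step changes little on phrase-dominated corpora (most contexts
  are punctuation) — consistent with its published behaviour; it is kept
  because it is cheap and occasionally reorders the lower list.
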