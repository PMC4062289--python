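from collections import Counter

from clinterm import fixtures
from clinterm.grammar import parse_sentence
from clinterm.inventory import (
    aggregate,
    enumerate_nested,
    read_inventory,
    simplify,
    write_inventory,
)

from conftest import sentence_from


def _forms_of_nested(sentence, cascade):
    phrase = parse_sentence(sentence, cascade)[0]
    lemmas = phrase.lemmas
    start = phrase.span[0]
    return {
        lemmas[i - start:j - start]
        for i, j in enumerate_nested(phrase, cascade)
    }


def test_simplify_is_the_lemma_sequence(full_cascade):
    phrase = parse_sentence(sentence_from("zakazenie"), full_cascade)[0]
    assert simplify(phrase) == ("zakażenie", "wirus", "grypa")
    # hyphen keeps its surface
    phrase = parse_sentence(sentence_from("oddzial_chir"), full_cascade)[0]
    assert simplify(phrase) == ("oddział", "chirurgiczny", "-", "urazowy")
    assert simplify(phrase) == simplify(phrase)  # idempotent identity key


def test_gerund_and_participle_share_a_simplified_form(full_cascade):
    from clinterm.corpus_io import Sentence, _token_from_fields

    gerund = Sentence((
        _token_from_fields("usunięcie", "usunąć", "ger:nom:n:sg", 1),
        _token_from_fields("kamienia", "kamień", "subst:gen:m:sg", 2),
    ))
    participle = Sentence((
        _token_from_fields("usunięty", "usunąć", "ppas:nom:m:sg", 1),
        _token_from_fields("kamień", "kamień", "subst:nom:m:sg", 2),
    ))
    forms = {
        simplify(parse_sentence(s, full_cascade)[0])
        for s in (gerund, participle)
    }
    assert forms == {("usunąć", "kamień")}


def test_nested_excludes_adjective_only_fragments(full_cascade):
    nested = _forms_of_nested(sentence_from("pecherzyk"), full_cascade)
    assert nested == {("pęcherzyk",), ("pęcherzyk", "żółciowy")}


def test_nested_of_genitive_chain_contains_paper_set(full_cascade):
    nested = _forms_of_nested(sentence_from("zakazenie"), full_cascade)
    assert {("wirus", "grypa"), ("wirus",), ("grypa",)} <= nested
    assert ("wirus", "grypa") in nested  # the multiword nested term
    assert all(len(f) < 3 for f in nested)  # proper sub-spans only


def test_single_token_phrase_has_no_nested(full_cascade):
    sentence = sentence_from("w_trakcie")
    phrase = parse_sentence(sentence, full_cascade)[0]
    assert enumerate_nested(phrase, full_cascade) == []


def test_aggregate_background_example(full_cascade):
    sentences = [sentence_from("lewa_nerka")]
    inv = aggregate(sentences, full_cascade)
    assert len(inv.records) == 4
    nerka = inv.records[("nerka",)]
    assert nerka.freq_standalone == 0
    assert nerka.freq_nested == 1
    full = inv.records[("lewy", "nerka", "prawidłowy")]
    assert full.freq_standalone == 1 and full.freq_nested == 0


def test_nested_only_records_are_retained(examples_inventory):
    # the 4-token card phrase's 3-token prefix never occurs standalone
    rec = examples_inventory.records[("karta", "informacyjny", "leczyć")]
    assert rec.freq_standalone == 0
    assert rec.freq_nested == 1165


def test_super_phrase_bookkeeping(examples_inventory):
    rec = examples_inventory.records[("karta", "informacyjny", "leczyć")]
    supers = rec.super_forms
    assert supers[("karta", "informacyjny", "leczyć", "szpitalny")] == 1164
    assert supers[
        ("poprzedni", "karta", "informacyjny", "leczyć", "szpitalny")
    ] == 1
    assert sorted(Counter(rec.left_words).items()) == [("", 1164), ("poprzedni", 1)]
    assert Counter(rec.right_words) == {"szpitalny": 1165}


def test_conservation_invariants(examples_corpus, examples_inventory):
    _, truth = examples_corpus
    inv = examples_inventory
    assert (
        sum(r.freq_standalone for r in inv.records.values())
        == inv.maximal_occurrences
    )
    assert inv.maximal_occurrences == truth.maximal_occurrences
    for rec in inv.records.values():
        assert len(rec.left_words) == rec.freq_nested
        assert len(rec.right_words) == rec.freq_nested
        assert rec.freq == rec.freq_standalone + rec.freq_nested


def test_aggregate_matches_plan_ground_truth(examples_corpus,
                                             examples_inventory):
    """The central end-to-end oracle: pipeline counts equal the analytic
    counts derived from the fixture plan alone."""
    _, truth = examples_corpus
    inv = examples_inventory
    assert set(inv.records) == set(truth.records)
    for form, expected in truth.records.items():
        rec = inv.records[form]
        assert rec.freq_standalone == expected.freq_standalone, form
        assert rec.contexts == expected.contexts, form


def test_brute_force_subspan_oracle(full_cascade):
    """On a small mixed corpus, aggregated counts equal an independent
    enumeration of all grammar-accepted sub-spans of the maximal phrases."""
    spec = fixtures.FixtureSpec(
        templates=fixtures.BUILTIN_TEMPLATES,
        plan={
            "lewa_nerka": 3, "pecherzyk": 2, "zakazenie": 2,
            "usg_jamy": 4, "powiekszenie3": 2, "karta5": 1,
            "ostry_dyzur": 5, "w_trakcie": 2,
        },
        seed=7,
        noise=0.3,
    )
    sentences, _ = fixtures.generate(spec)
    assert len(sentences) <= 50

    standalone = Counter()
    contexts = {}
    for sentence in sentences:
        for phrase in parse_sentence(sentence, full_cascade):
            lemmas = phrase.lemmas
            standalone[lemmas] += 1
            n = len(lemmas)
            for i in range(n):
                for j in range(i + 1, n + 1):
                    if j - i == n:
                        continue
                    if full_cascade.accepts_as_phrase(phrase.tokens[i:j]):
                        sub = contexts.setdefault(lemmas[i:j], Counter())
                        sub[(lemmas[:i], lemmas[j:])] += 1

    inv = aggregate(sentences, full_cascade)
    assert {f: c for f, c in standalone.items()} == {
        f: r.freq_standalone
        for f, r in inv.records.items()
        if r.freq_standalone
    }
    for form, rec in inv.records.items():
        assert rec.contexts == contexts.get(form, Counter()), form


def test_inventory_tsv_round_trip(examples_inventory, tmp_path):
    path = tmp_path / "inventory.tsv"
    write_inventory(examples_inventory, path)
    loaded = read_inventory(path)
    assert loaded.corpus_token_count == examples_inventory.corpus_token_count
    assert loaded.maximal_occurrences == examples_inventory.maximal_occurrences
    assert set(loaded.records) == set(examples_inventory.records)
    for form, rec in examples_inventory.records.items():
        other = loaded.records[form]
        assert other.freq_standalone == rec.freq_standalone
        assert other.contexts == rec.contexts
        assert other.ext_contexts == rec.ext_contexts
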