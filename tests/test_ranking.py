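import math
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinterm import fixtures
from clinterm.inventory import Inventory, TermRecord, aggregate
from clinterm.ranking import (
    CValueParams,
    NCParams,
    RankedTerm,
    build_context_model,
    c_value,
    context_type_count,
    length_weight,
    nc_value,
    rank_and_cut,
    score_band_summary,
    score_inventory,
)


def record(form, standalone=0, contexts=None, ext=None):
    rec = TermRecord(form=tuple(form), length_tokens=len(form),
                     freq_standalone=standalone)
    for (left, right), count in (contexts or {}).items():
        rec.contexts[(tuple(left), tuple(right))] = count
    for key, count in (ext or {}).items():
        rec.ext_contexts[key] = count
    return rec


# -- length weight ----------------------------------------------------------

def test_length_weight_values():
    assert length_weight(2) == 1.0
    assert length_weight(4) == 2.0
    assert length_weight(1) == pytest.approx(0.1)
    assert length_weight(3) == pytest.approx(math.log2(3))
    with pytest.raises(ValueError):
        length_weight(0)


def test_params_validation():
    with pytest.raises(ValueError):
        CValueParams(unigram_l=0.0)
    with pytest.raises(ValueError):
        CValueParams(context_scheme="nope")
    with pytest.raises(ValueError):
        NCParams(alpha=0.9, beta=0.2)


# -- context counting schemes ----------------------------------------------

@pytest.fixture()
def lymph_nodes_record(full_cascade):
    """'węzłów chłonnych' aggregated over its four containing phrases."""
    spec = fixtures.FixtureSpec(
        templates=fixtures.BUILTIN_TEMPLATES,
        plan={f"powiekszenie{i}": 1 for i in (1, 2, 3, 4)},
        seed=0,
    )
    sentences, _ = fixtures.generate(spec)
    inv = aggregate(sentences, full_cascade)
    return inv.records[("węzeł", "chłonny")]


@pytest.mark.parametrize(
    "scheme,expected",
    [("original", 4), ("grouped_words", 3), ("max_separate", 2)],
)
def test_context_schemes_on_worked_example(lymph_nodes_record, scheme,
                                           expected):
    assert context_type_count(lymph_nodes_record, scheme) == expected


def test_context_count_zero_for_standalone_only():
    rec = record(["kod", "pacjent"], standalone=5)
    for scheme in ("original", "grouped_words", "max_separate"):
        assert context_type_count(rec, scheme) == 0


# -- C-value ----------------------------------------------------------------

def test_c_value_standalone_only():
    rec = record(["karta", "informacyjny", "leczyć", "szpitalny"],
                 standalone=116)
    assert c_value(rec) == pytest.approx(232.0)


def test_c_value_with_single_nesting():
    rec = record(
        ["karta", "informacyjny", "leczyć", "szpitalny"],
        standalone=1164,
        contexts={(("poprzedni",), ()): 1},
    )
    assert c_value(rec) == pytest.approx(2328.0)


def test_zero_rule_for_nested_only_single_context():
    rec = record(
        ["karta", "informacyjny", "leczyć"],
        standalone=0,
        contexts={((), ("szpitalny",)): 1164,
                  (("poprzedni",), ("szpitalny",)): 1},
    )
    assert c_value(rec, CValueParams(context_scheme="max_separate")) == 0.0
    # under the original scheme the two containing phrases count separately
    original = c_value(rec, CValueParams(context_scheme="original"))
    assert original == pytest.approx(math.log2(3) * (1165 - 1165 / 2))
    # the zero rule is a parameter
    relaxed = c_value(
        rec, CValueParams(context_scheme="max_separate", zero_rule=False)
    )
    assert relaxed == pytest.approx(math.log2(3) * (1165 - 1165 / 1))


def test_zero_rule_spares_standalone_terms():
    rec = record(["ostry", "dyżur"], standalone=3,
                 contexts={((), ("nocny",)): 2})
    assert c_value(rec) > 0


# -- property suite ---------------------------------------------------------

_words = st.sampled_from(["a", "b", "c", "d"])
_side = st.lists(_words, max_size=2).map(tuple)
# a nested span is a *proper* sub-span of its container, so at least one
# side of its context is non-empty
_contexts = st.dictionaries(
    st.tuples(_side, _side).filter(lambda lr: lr[0] or lr[1]),
    st.integers(min_value=1, max_value=50),
    max_size=6,
)


@settings(deadline=None, max_examples=200)
@given(
    length=st.integers(min_value=1, max_value=6),
    standalone=st.integers(min_value=0, max_value=100),
    contexts=_contexts,
)
def test_c1_never_exceeds_original_c(length, standalone, contexts):
    rec = TermRecord(form=tuple("w" * length), length_tokens=length,
                     freq_standalone=standalone,
                     contexts=Counter(contexts))
    original = c_value(rec, CValueParams(context_scheme="original"))
    c1 = c_value(rec, CValueParams(context_scheme="max_separate"))
    assert c1 <= original + 1e-9
    if not contexts:
        assert c1 == original


@settings(deadline=None, max_examples=100)
@given(
    standalone=st.integers(min_value=0, max_value=50),
    extra=st.integers(min_value=1, max_value=20),
    contexts=_contexts,
)
def test_c_monotone_in_standalone_frequency(standalone, extra, contexts):
    base = TermRecord(form=("x", "y"), length_tokens=2,
                      freq_standalone=standalone,
                      contexts=Counter(contexts))
    more = TermRecord(form=("x", "y"), length_tokens=2,
                      freq_standalone=standalone + extra,
                      contexts=Counter(contexts))
    assert c_value(more) >= c_value(base) - 1e-9


# -- NC value ---------------------------------------------------------------

def test_nc_without_context_words_is_fraction_of_c():
    inv = Inventory()
    rec = record(["karta", "informacyjny", "leczyć", "szpitalny"],
                 standalone=116,
                 ext=({(".", "interp"): 116}))  # punctuation-only contexts
    inv.records[rec.form] = rec
    terms = score_inventory(inv)
    terms = nc_value(terms, NCParams(top_k=10))
    assert terms[0].nc_value == pytest.approx(185.60)


def test_nc_hand_computed_on_ten_term_fixture():
    """Context word shared by 3 of n=10 terms gets weight 0.3; the NC of a
    term seeing it twice gains 0.2 * 2 * 0.3."""
    inv = Inventory()
    for i in range(10):
        ext = {}
        if i < 3:
            ext[("stwierdzić", "fin")] = 2 if i == 0 else 1
        rec = record([f"term{i}", "x"], standalone=10 - i, ext=ext)
        inv.records[rec.form] = rec
    terms = score_inventory(inv)
    model = build_context_model(terms, NCParams(top_k=10))
    assert model.n_terms == 10
    assert model.weight("stwierdzić") == pytest.approx(0.3)
    terms = nc_value(terms, NCParams(top_k=10))
    by_form = {t.record.form: t for t in terms}
    top = by_form[("term0", "x")]
    assert top.c1_value == pytest.approx(10.0)
    assert top.nc_value == pytest.approx(0.8 * 10 + 0.2 * (2 * 0.3))
    plain = by_form[("term5", "x")]
    assert plain.nc_value == pytest.approx(0.8 * plain.c1_value)


def test_nc_ignores_ineligible_pos():
    inv = Inventory()
    rec = record(["a", "b"], standalone=5,
                 ext={(",", "interp"): 4, ("w", "prep"): 3})
    inv.records[rec.form] = rec
    terms = nc_value(score_inventory(inv), NCParams(top_k=5))
    assert terms[0].nc_value == pytest.approx(0.8 * terms[0].c1_value)


# -- ranking ----------------------------------------------------------------

def test_rank_ties_broken_by_frequency_then_form():
    terms = [
        RankedTerm(record=record(["b"], standalone=5), c1_value=1.0),
        RankedTerm(record=record(["a"], standalone=5), c1_value=1.0),
        RankedTerm(record=record(["c"], standalone=9), c1_value=1.0),
    ]
    ordered = rank_and_cut(terms, "c1_value")
    assert [t.record.form for t in ordered] == [("c",), ("a",), ("b",)]
    assert [t.rank for t in ordered] == [1, 2, 3]


def test_rank_cutoffs():
    terms = [
        RankedTerm(record=record([f"t{i}"], standalone=i), c1_value=float(i))
        for i in range(10)
    ]
    assert len(rank_and_cut(terms, "c1_value", cutoff_rank=4)) == 4
    assert len(rank_and_cut(terms, "c1_value", cutoff_rank=200)) == 10
    kept = rank_and_cut(terms, "c1_value", cutoff_score=5.0)
    assert all(t.c1_value >= 5.0 for t in kept)
    with pytest.raises(ValueError):
        rank_and_cut(terms, "bogus")


def test_ranking_deterministic_across_runs(examples_inventory):
    first = [
        t.record.form
        for t in rank_and_cut(score_inventory(examples_inventory), "c1_value")
    ]
    second = [
        t.record.form
        for t in rank_and_cut(score_inventory(examples_inventory), "c1_value")
    ]
    assert first == second


def test_score_bands_partition():
    terms = [
        RankedTerm(record=record([f"t{i}"], standalone=i), c1_value=v)
        for i, v in enumerate([0.0, 0.5, 1.0, 2.0, 7.0, 0.0])
    ]
    bands = score_band_summary(terms, "c1_value")
    assert bands["total"] == 6
    assert (
        bands["C=0"] + bands["0<C<1"] + bands["C=1"]
        + bands["1<C<=2.5"] + bands["C>2.5"]
    ) == bands["total"]


# -- brute-force oracle over a generated corpus -----------------------------

def test_c_values_match_direct_formula_on_fixture(full_cascade):
    """Pipeline C-values equal a direct transcription of the defining
    formula over analytically known counts, for every scheme."""
    spec = fixtures.FixtureSpec(
        templates=fixtures.BUILTIN_TEMPLATES,
        plan={
            "lewa_nerka": 4, "zakazenie": 3, "usg_jamy": 2,
            "powiekszenie1": 1, "powiekszenie2": 1, "powiekszenie3": 1,
            "powiekszenie4": 1, "kod": 6, "oddzial_chir": 2,
        },
        seed=11,
    )
    sentences, truth = fixtures.generate(spec)
    assert len(sentences) <= 50
    inv = aggregate(sentences, full_cascade)
    for scheme in ("original", "grouped_words", "max_separate"):
        params = CValueParams(context_scheme=scheme)
        for form, expected in truth.records.items():
            got = c_value(inv.records[form], params)
            want = fixtures.expected_c_value(expected, scheme)
            assert got == pytest.approx(want), (form, scheme)
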