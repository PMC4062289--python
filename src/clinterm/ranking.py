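"""Termhood ranking: C-value, its C₁ context-counting variant, NC-value.

The C-value of a candidate phrase p combines its length, its total
frequency (standalone plus nested) and a penalty for occurring nested::

    C(p) = l(p) * freq(p)                          if r = 0
    C(p) = l(p) * (freq(p) - (1/r) * F)            if r > 0

where F is the total nested frequency, r the number of distinct nesting
contexts, and l(p) = log2(length(p)) for multiword phrases.  Length-1
phrases use a small positive constant (default 0.1) instead of the zero
logarithm, which keeps single words rankable without flooding the top of
the list.  A phrase that never occurs standalone and has at most one
distinct context is scored 0: it is taken to be an incomplete fragment of
its (single) containing phrase.

What counts as a "distinct context" is the crux for inflectional clinical
text, where a nested term's neighbourhood is often one fixed super phrase
inflected many ways.  Three schemes are supported:

``original``       distinct (left word sequence, right word sequence)
                   pairs — effectively distinct containing phrases;
``grouped_words``  distinct single adjacent words, both sides pooled;
``max_separate``   the maximum of the distinct-left-word and
                   distinct-right-word counts taken separately (the C₁
                   variant, default) — a super phrase whose variants only
                   re-decorate one side no longer inflates the count.

NC-value then folds in external one-word contexts shared with top-ranked
terms::

    NC(t) = 0.8 * C(t) + 0.2 * sum_b f_t(b) * weight(b),
    weight(b) = t(b) / n

where b ranges over the eligible words (adjectives, nouns, verbs) directly
adjacent to t's occurrences, t(b) is the number of top-n terms b
co-occurs with and n the size of the considered top list.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .inventory import EMPTY, Inventory, TermRecord

__all__ = [
    "CValueParams",
    "NCParams",
    "NCContextModel",
    "RankedTerm",
    "length_weight",
    "context_type_count",
    "c_value",
    "score_inventory",
    "build_context_model",
    "nc_value",
    "rank_and_cut",
    "write_ranked",
    "read_reference_scores",
    "score_band_summary",
]

ContextScheme = Literal["original", "grouped_words", "max_separate"]

#: word classes eligible as NC context words
DEFAULT_CONTEXT_POS = frozenset(
    {"subst", "ger",                       # nouns
     "adj", "adja", "ppas",                # adjectives
     "fin", "praet", "inf", "impt", "verb"}  # verbs
)


@dataclass(frozen=True)
class CValueParams:
    unigram_l: float = 0.1
    context_scheme: ContextScheme = "max_separate"
    zero_rule: bool = True

    def __post_init__(self) -> None:
        if self.unigram_l <= 0:
            raise ValueError("unigram_l must be positive")
        if self.context_scheme not in (
            "original", "grouped_words", "max_separate"
        ):
            raise ValueError(f"unknown context scheme {self.context_scheme!r}")


@dataclass(frozen=True)
class NCParams:
    alpha: float = 0.8
    beta: float = 0.2
    top_k: int = 300
    context_pos: frozenset[str] = DEFAULT_CONTEXT_POS

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")


@dataclass
class RankedTerm:
    record: TermRecord
    c_value: float = 0.0
    c1_value: float = 0.0
    nc_value: float | None = None
    rank: int = 0

    @property
    def form(self):
        return self.record.form


def length_weight(length_tokens: int, params: CValueParams = CValueParams()) -> float:
    """l(p): log2 of the token length, or the unigram constant for length 1."""
    if length_tokens < 1:
        raise ValueError("phrase length must be >= 1")
    if length_tokens == 1:
        return params.unigram_l
    return math.log2(length_tokens)


def context_type_count(record: TermRecord, scheme: ContextScheme) -> int:
    """Number of distinct nesting contexts of a term under a scheme."""
    if not record.contexts:
        return 0
    if scheme == "original":
        return len(set(record.contexts.keys()))
    if scheme == "grouped_words":
        words = {w for w in record.left_words if w != EMPTY}
        words |= {w for w in record.right_words if w != EMPTY}
        return len(words)
    if scheme == "max_separate":
        left = {w for w in record.left_words if w != EMPTY}
        right = {w for w in record.right_words if w != EMPTY}
        return max(len(left), len(right))
    raise ValueError(f"unknown context scheme {scheme!r}")


def c_value(record: TermRecord, params: CValueParams = CValueParams()) -> float:
    """C-value of one aggregated term record under the given scheme."""
    weight = length_weight(record.length_tokens, params)
    r = context_type_count(record, params.context_scheme)
    if params.zero_rule and record.freq_standalone == 0 and r <= 1:
        return 0.0
    if r == 0:
        return weight * record.freq
    nested_total = record.freq_nested
    return weight * (record.freq - nested_total / r)


def score_inventory(
    inventory: Inventory, params: CValueParams = CValueParams()
) -> list[RankedTerm]:
    """Score every record with the original C-value and the C₁ variant."""
    original = replace(params, context_scheme="original")
    c1 = replace(params, context_scheme="max_separate")
    terms = [
        RankedTerm(
            record=rec,
            c_value=c_value(rec, original),
            c1_value=c_value(rec, c1),
        )
        for rec in inventory.records.values()
    ]
    return terms


@dataclass
class NCContextModel:
    """Context-word weights learned from the top-ranked terms."""

    weights: dict[str, float] = field(default_factory=dict)
    n_terms: int = 0

    def weight(self, lemma: str) -> float:
        return self.weights.get(lemma, 0.0)


def _eligible_contexts(record: TermRecord, allowed_pos: frozenset[str]) -> Counter:
    """f_t(b): frequencies of eligible context lemmas around a term."""
    out: Counter = Counter()
    for (lemma, pos), count in record.ext_contexts.items():
        if pos in allowed_pos:
            out[lemma] += count
    return out


def build_context_model(
    terms: Sequence[RankedTerm],
    params: NCParams = NCParams(),
    base: str = "c1_value",
) -> NCContextModel:
    """weight(b) = t(b)/n over the top-k terms ranked by ``base``.

    If fewer terms exist than ``top_k``, all terms are used.
    """
    pool = sorted(
        terms,
        key=lambda t: (-getattr(t, base), -t.record.freq, t.record.form),
    )[: params.top_k]
    n = len(pool)
    seen_with: Counter = Counter()
    for term in pool:
        for lemma in _eligible_contexts(term.record, params.context_pos):
            seen_with[lemma] += 1
    weights = {lemma: count / n for lemma, count in seen_with.items()} if n else {}
    return NCContextModel(weights=weights, n_terms=n)


def nc_value(
    terms: Sequence[RankedTerm],
    params: NCParams = NCParams(),
    base: str = "c1_value",
) -> list[RankedTerm]:
    """Attach NC-values and return the list re-sorted by NC."""
    model = build_context_model(terms, params, base=base)
    for term in terms:
        contexts = _eligible_contexts(term.record, params.context_pos)
        bonus = sum(
            freq * model.weight(lemma) for lemma, freq in contexts.items()
        )
        term.nc_value = params.alpha * getattr(term, base) + params.beta * bonus
    return rank_and_cut(list(terms), "nc_value")


def rank_and_cut(
    terms: list[RankedTerm],
    score_field: str = "c1_value",
    cutoff_rank: int | None = None,
    cutoff_score: float | None = None,
) -> list[RankedTerm]:
    """Order terms by a score, ties broken by frequency then form.

    Ranks are contiguous from 1; the cut (by rank or by minimum score)
    applies after ranking.
    """
    if score_field not in ("c_value", "c1_value", "nc_value"):
        raise ValueError(f"unknown score field {score_field!r}")
    ordered = sorted(
        terms,
        key=lambda t: (
            -(getattr(t, score_field) or 0.0),
            -t.record.freq,
            t.record.form,
        ),
    )
    for i, term in enumerate(ordered, start=1):
        term.rank = i
    if cutoff_rank is not None:
        ordered = ordered[:cutoff_rank]
    if cutoff_score is not None:
        ordered = [
            t for t in ordered if (getattr(t, score_field) or 0.0) >= cutoff_score
        ]
    return ordered


def write_ranked(terms: Iterable[RankedTerm], path: str | Path) -> None:
    """Ranked list as TSV (scores printed to 2 decimals, as in reports)."""
    import pandas as pd

    rows = [
        {
            "rank": t.rank,
            "form": " ".join(t.record.form),
            "length": t.record.length_tokens,
            "c_value": round(t.c_value, 2),
            "c1_value": round(t.c1_value, 2),
            "nc_value": round(t.nc_value, 2) if t.nc_value is not None else "",
            "freq_standalone": t.record.freq_standalone,
            "freq_nested": t.record.freq_nested,
        }
        for t in terms
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reference_scores(path: str | Path,
                          score_field: str = "c1_value") -> dict[tuple, float]:
    """Read a ranked TSV back as a form -> score map (for refcorpus use)."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return {
        tuple(str(row["form"]).split(" ")): float(row[score_field])
        for _, row in frame.iterrows()
    }


def score_band_summary(terms: Sequence[RankedTerm],
                       score_field: str = "c1_value") -> dict[str, int]:
    """Distribution of scores over the conventional reporting bands."""
    bands = {
        "total": 0, "C=0": 0, "0<C<1": 0, "C=1": 0,
        "1<C<=2.5": 0, "C>2.5": 0,
    }
    for term in terms:
        score = getattr(term, score_field) or 0.0
        bands["total"] += 1
        if score == 0:
            bands["C=0"] += 1
        elif score < 1:
            bands["0<C<1"] += 1
        elif score == 1:
            bands["C=1"] += 1
        elif score <= 2.5:
            bands["1<C<=2.5"] += 1
        else:
            bands["C>2.5"] += 1
    return bands
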