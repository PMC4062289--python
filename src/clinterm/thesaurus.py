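"""Matching extracted terms against a controlled vocabulary.

Simplified base forms cannot be compared with thesaurus headings (which
are grammatical nominative phrases) by plain string equality: a lemma like
*chirurgia* and the derived adjective *chirurgiczny* differ as strings
although the heading and the term correspond.  Matching therefore runs in
tiers, first exact, then containment, then approximate:

1. ``exact``            the term's word sequence equals a heading/synonym;
2. ``nested_in_entry``  it is a contiguous subsequence of a longer entry;
3. ``approximate``      some entry contains, for every term word, a word
                        whose *stem* is positionally similar enough;
4. ``none``.

Stems are produced by stripping one case/derivation suffix from a shipped
ordered table.  Similarity is a Levenshtein variant in which an edit near
the end of a word costs less than one near the beginning — inflectional
endings live at the end, so a genuine mismatch at the start of a stem is
penalised harder than residual suffix material.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ThesaurusEntry",
    "Thesaurus",
    "MatchResult",
    "load_suffix_table",
    "default_suffix_table",
    "stem_word",
    "positional_edit_similarity",
    "match_term",
    "load_thesaurus",
]

DEFAULT_MIN_STEM = 3


def load_suffix_table(path: str | Path) -> tuple[str, ...]:
    """Ordered list of strippable endings, one per line ('#' comments)."""
    suffixes = []
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if line and not line.startswith("#"):
                suffixes.append(line)
    return tuple(suffixes)


@lru_cache(maxsize=1)
def default_suffix_table() -> tuple[str, ...]:
    return load_suffix_table(Path(__file__).parent / "data" / "suffixes.txt")


def stem_word(
    word: str,
    suffix_table: Sequence[str] | None = None,
    min_stem: int = DEFAULT_MIN_STEM,
) -> str:
    """Strip the longest listed suffix once; never below ``min_stem`` chars."""
    if suffix_table is None:
        suffix_table = default_suffix_table()
    word = word.lower()
    best = ""
    for suffix in suffix_table:
        if len(suffix) <= len(best):
            continue
        if word.endswith(suffix) and len(word) - len(suffix) >= min_stem:
            best = suffix
    return word[: len(word) - len(best)] if best else word


def _position_factor(i: int, length: int) -> float:
    # cost of an edit at 1-based alignment position i over a word of
    # length `length`: linear discount, end edits cost half of start edits
    return 1.0 - (i - 1) / (2.0 * length)


def positional_edit_similarity(a: str, b: str) -> float:
    """Position-weighted Levenshtein similarity in [0, 1].

    Dynamic-programming edit distance where an edit at alignment position
    i (over the longer word, length L) costs ``1 - (i-1)/(2L)``; the
    similarity is 1 minus the distance normalised by the worst case (an
    edit at every position).  Symmetric; 1.0 iff the words are equal.
    """
    if not a or not b:
        raise ValueError("positional similarity is undefined for empty strings")
    la, lb = len(a), len(b)
    length = max(la, lb)

    def cost(i: int, j: int) -> float:
        return _position_factor(max(i, j), length)

    dist = [[0.0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        dist[i][0] = dist[i - 1][0] + cost(i, 0)
    for j in range(1, lb + 1):
        dist[0][j] = dist[0][j - 1] + cost(0, j)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            substitution = dist[i - 1][j - 1] + (
                0.0 if a[i - 1] == b[j - 1] else cost(i, j)
            )
            deletion = dist[i - 1][j] + cost(i, j)
            insertion = dist[i][j - 1] + cost(i, j)
            dist[i][j] = min(substitution, deletion, insertion)
    worst = sum(_position_factor(i, length) for i in range(1, length + 1))
    return 1.0 - dist[la][lb] / worst


@dataclass(frozen=True)
class ThesaurusEntry:
    """A controlled-vocabulary heading with synonyms and precomputed stems."""

    term: tuple[str, ...]
    synonyms: tuple[tuple[str, ...], ...] = ()
    stems: tuple[tuple[str, ...], ...] = ()  # one stem list per word list

    @property
    def word_lists(self) -> tuple[tuple[str, ...], ...]:
        return (self.term,) + self.synonyms


@dataclass
class Thesaurus:
    entries: list[ThesaurusEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("thesaurus is empty")


@dataclass(frozen=True)
class MatchResult:
    tier: str  # exact | nested_in_entry | approximate | none
    entry: ThesaurusEntry | None = None
    word_similarities: tuple[float, ...] = ()

    @property
    def min_similarity(self) -> float | None:
        return min(self.word_similarities) if self.word_similarities else None


def _contains_subsequence(haystack: Sequence[str], needle: Sequence[str]) -> bool:
    n, h = len(needle), len(haystack)
    return any(
        tuple(haystack[i:i + n]) == tuple(needle) for i in range(h - n + 1)
    )


def _normalise(words: Iterable[str]) -> tuple[str, ...]:
    return tuple(w.lower() for w in words)


def match_term(
    term: Sequence[str],
    thesaurus: Thesaurus,
    threshold: float = 0.8,
    extra_forms: Iterable[Sequence[str]] = (),
    suffix_table: Sequence[str] | None = None,
    min_stem: int = DEFAULT_MIN_STEM,
) -> MatchResult:
    """Tiered match of a term's word list against the thesaurus.

    ``extra_forms`` are alternative word sequences for the same term (e.g.
    an observed grammatical surface form next to the simplified base form);
    the exact and containment tiers consider them all, which rescues terms
    whose head lemma diverges sharply from its inflected forms (gerunds).
    """
    if not term:
        raise ValueError("empty term")
    candidates = [_normalise(term)] + [_normalise(f) for f in extra_forms if f]

    for entry in thesaurus.entries:
        for words in entry.word_lists:
            if any(cand == words for cand in candidates):
                return MatchResult(tier="exact", entry=entry)
    for entry in thesaurus.entries:
        for words in entry.word_lists:
            for cand in candidates:
                if len(cand) < len(words) and _contains_subsequence(words, cand):
                    return MatchResult(tier="nested_in_entry", entry=entry)

    term_stems = [stem_word(w, suffix_table, min_stem) for w in candidates[0]]
    best: MatchResult | None = None
    for entry in thesaurus.entries:
        for stems in entry.stems:
            sims = []
            for ts in term_stems:
                sim = max(
                    (positional_edit_similarity(ts, es) for es in stems),
                    default=0.0,
                )
                sims.append(sim)
            if sims and min(sims) >= threshold:
                result = MatchResult(
                    tier="approximate", entry=entry,
                    word_similarities=tuple(sims),
                )
                if best is None or (result.min_similarity or 0) > (
                    best.min_similarity or 0
                ):
                    best = result
    if best is not None:
        return best
    return MatchResult(tier="none")


def load_thesaurus(
    path: str | Path,
    suffix_table: Sequence[str] | None = None,
    min_stem: int = DEFAULT_MIN_STEM,
) -> Thesaurus:
    """Plain-text thesaurus: one entry per line, synonyms separated by a
    pipe, words space-separated.  Stems are precomputed at load time."""
    entries: list[ThesaurusEntry] = []
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            variants = [
                _normalise(part.split()) for part in line.split("|") if part.strip()
            ]
            if not variants:
                continue
            stems = tuple(
                tuple(stem_word(w, suffix_table, min_stem) for w in words)
                for words in variants
            )
            entries.append(
                ThesaurusEntry(
                    term=variants[0],
                    synonyms=tuple(variants[1:]),
                    stems=stems,
                )
            )
    return Thesaurus(entries=entries)
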