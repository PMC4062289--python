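"""Cascaded shallow grammar for noun-phrase candidate extraction.

The grammar is a cascade of six ordered rule sets.  Each set rewrites
matched sequences of items (tokens or categories produced by earlier sets)
into a single categorized item; the output of one level is the input of the
next.  Within a level the scan is leftmost-longest: at each position every
rule of the level is tried, the longest match wins, ties go to file order,
and the scan continues after the consumed span.  The final noun phrases are
the items of category ``X`` after level VI.

Categories
----------
``N``     inflecting nominal (noun or gerund), possibly adjective-modified
``NC``    non-inflecting nominal (acronym/abbreviation, foreign run)
``AJ``    basic inflecting adjective (optionally adverb-premodified)
``AC``    non-inflecting (abbreviation) adjective
``A``     extended adjective (adverb attachment, hyphenated compounds)
``ADJP``  compound adjectival phrase, optionally coordinated with ``i``
``NB``    basic noun phrase (nominal plus adjectival satellites)
``NG``    genitive-chain noun group
``X``     full noun phrase (head group + genitive group + trailing ADJP)
``NZ``/``AZ``  stop-lemma nominals/modifiers barred from opening a phrase

Agreement: items sharing a variable (conventionally ``C``, ``G``, ``N`` for
case, gender, number) must carry compatible values; a missing feature — e.g.
on a non-inflecting NC/AC — is compatible with anything, since such items
cannot be a source of case, gender or number values.  ``head`` on a rule
names the right-hand-side position whose morphology the rewritten item
inherits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .corpus_io import Sentence, TaggedToken

__all__ = [
    "GrammarError",
    "RuleItem",
    "GrammarRule",
    "Cascade",
    "PhraseMatch",
    "compile_cascade",
    "default_cascade",
    "parse_sentence",
    "phrase_token_length",
    "load_stop_list",
]

#: terminal word-class codes usable in rules
TERMINAL_CLASSES = frozenset(
    {
        "subst", "ger", "adj", "adja", "ppas", "adv",
        "foreign", "foreign_subst",
        "brev:pun:nw", "brev:npun:nw", "brev:pun:nphr", "brev:npun:nphr",
        "brev:adjw:pun", "brev:adjw:npun",
        "conj", "interp", "num", "other",
    }
)

#: nonterminal categories that carry the case/gender/number triple
FEATURED_CATEGORIES = frozenset({"N", "A", "AJ", "ADJP", "NB", "NG", "X"})

#: categories counting as noun phrases (for nesting and maximality)
NOUN_PHRASE_CATEGORIES = frozenset({"X"})

_VAR_TO_FEATURE_ORDER = ("case", "gender", "number")


class GrammarError(ValueError):
    """Raised for rule files that do not compile."""


@dataclass(frozen=True)
class RuleItem:
    cats: tuple[str, ...]
    optional: bool = False
    lemma: str | None = None
    surface: str | None = None
    stoplist: frozenset[str] | None = None
    agree: tuple[str, ...] = ()          # variables, positionally (case, gender, number)
    fixed: tuple[tuple[str, str], ...] = ()  # literal feature constraints


@dataclass(frozen=True)
class GrammarRule:
    level: int
    lhs: str
    rhs: tuple[RuleItem, ...]
    head: int = 1  # 1-based rhs position supplying the morphology
    name: str = ""
    flag: str | None = None


@dataclass(frozen=True)
class PhraseMatch:
    """A grammar item: a span of tokens with its category and derivation.

    Leaves are single tokens (category = word class); internal nodes carry
    the rewriting rule's left-hand-side category.  ``children`` tile the span
    left to right without overlap.
    """

    span: tuple[int, int]  # half-open token interval within the sentence
    category: str
    tokens: tuple[TaggedToken, ...]
    features: dict = field(default_factory=dict)
    children: tuple["PhraseMatch", ...] = ()
    is_maximal: bool = False

    def __len__(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def lemmas(self) -> tuple[str, ...]:
        return tuple(
            t.surface if t.is_special_char else t.lemma for t in self.tokens
        )


@dataclass
class Cascade:
    levels: dict[int, list[GrammarRule]]
    mode: str = "full"  # "full" honours morphology, "simplified" is POS-only

    def with_mode(self, mode: str) -> "Cascade":
        if mode not in ("full", "simplified"):
            raise GrammarError(f"unknown grammar mode {mode!r}")
        return Cascade(levels=self.levels, mode=mode)

    # -- matching ---------------------------------------------------------

    def _item_accepts(self, ritem: RuleItem, item: PhraseMatch,
                      bindings: dict[str, str]) -> dict[str, str] | None:
        """Return updated bindings if ``item`` satisfies ``ritem``, else None."""
        if item.category not in ritem.cats:
            return None
        if ritem.surface is not None:
            if len(item.tokens) != 1 or item.tokens[0].surface != ritem.surface:
                return None
        if ritem.lemma is not None:
            if len(item.tokens) != 1 or item.tokens[0].lemma != ritem.lemma:
                return None
        if ritem.stoplist is not None:
            if len(item.tokens) != 1 or item.tokens[0].lemma not in ritem.stoplist:
                return None
        if self.mode == "simplified":
            return bindings
        for key, required in ritem.fixed:
            value = item.features.get(key)
            if value is not None and value != required:
                return None
        if ritem.agree:
            new = dict(bindings)
            for var, key in zip(ritem.agree, _VAR_TO_FEATURE_ORDER):
                value = item.features.get(key)
                if value is None:
                    continue  # non-inflecting items are wildcards
                if var in new and new[var] != value:
                    return None
                new[var] = value
            return new
        return bindings

    def _match_rule(
        self, rule: GrammarRule, items: Sequence[PhraseMatch], start: int
    ) -> tuple[list[PhraseMatch], dict[int, PhraseMatch], dict[str, str]] | None:
        """Greedy match of ``rule`` at ``start`` (optional items taken when
        possible, with backtracking).  Returns (consumed, rhs-position map,
        bindings) for the longest such match, or None."""

        def rec(ri: int, pos: int, bindings: dict[str, str],
                taken: list[tuple[int, PhraseMatch]]):
            if ri == len(rule.rhs):
                return list(taken), dict(bindings)
            ritem = rule.rhs[ri]
            if pos < len(items):
                updated = self._item_accepts(ritem, items[pos], bindings)
                if updated is not None:
                    taken.append((ri, items[pos]))
                    result = rec(ri + 1, pos + 1, updated, taken)
                    taken.pop()
                    if result is not None:
                        return result
            if ritem.optional:
                return rec(ri + 1, pos, bindings, taken)
            return None

        result = rec(0, start, {}, [])
        if result is None:
            return None
        taken, bindings = result
        if not taken:
            return None
        consumed = [item for _, item in taken]
        position_map = {ri + 1: item for ri, item in taken}
        return consumed, position_map, bindings

    def _rewrite(self, rule: GrammarRule, consumed: list[PhraseMatch],
                 position_map: dict[int, PhraseMatch],
                 bindings: dict[str, str]) -> PhraseMatch:
        span = (consumed[0].span[0], consumed[-1].span[1])
        tokens = tuple(t for item in consumed for t in item.tokens)
        features: dict[str, str] = {}
        if rule.lhs in FEATURED_CATEGORIES and self.mode == "full":
            head_item = position_map.get(rule.head) or consumed[0]
            features = dict(head_item.features)
            for var, key in zip(("C", "G", "N"), _VAR_TO_FEATURE_ORDER):
                if var in bindings and key not in features:
                    features[key] = bindings[var]
        return PhraseMatch(
            span=span,
            category=rule.lhs,
            tokens=tokens,
            features=features,
            children=tuple(consumed),
        )

    def _apply_level(self, rules: list[GrammarRule],
                     items: list[PhraseMatch]) -> list[PhraseMatch]:
        out: list[PhraseMatch] = []
        i = 0
        while i < len(items):
            best = None
            best_len = 0
            for rule in rules:
                match = self._match_rule(rule, items, i)
                if match is None:
                    continue
                length = len(match[0])
                if length > best_len:  # ties: earlier rule wins (file order)
                    best, best_len = (rule, match), length
            if best is None:
                out.append(items[i])
                i += 1
            else:
                rule, (consumed, position_map, bindings) = best
                out.append(self._rewrite(rule, consumed, position_map, bindings))
                i += best_len
        return out

    def parse_items(self, tokens: Sequence[TaggedToken],
                    offset: int = 0) -> list[PhraseMatch]:
        """Run the full cascade over a token sequence; returns the final item
        list (mixed categories and unconsumed tokens)."""
        items = [
            PhraseMatch(
                span=(offset + i, offset + i + 1),
                category=token.pos,
                tokens=(token,),
                features={
                    k: v for k, v in token.features.items()
                    if k in _VAR_TO_FEATURE_ORDER
                },
            )
            for i, token in enumerate(tokens)
        ]
        for level in sorted(self.levels):
            items = self._apply_level(self.levels[level], items)
        return items

    def accepts_as_phrase(self, tokens: Sequence[TaggedToken]) -> bool:
        """True iff the whole token sequence reduces to a single noun phrase."""
        items = self.parse_items(tokens)
        return len(items) == 1 and items[0].category in NOUN_PHRASE_CATEGORIES


def parse_sentence(sentence: Sentence, cascade: Cascade) -> list[PhraseMatch]:
    """Extract the maximal noun phrases of a sentence, with derivations.

    Maximal phrases are pairwise non-overlapping, sorted by start position.
    Spans opened by a stop-class item (NZ/AZ) never form phrases because the
    stop rules pre-empt the nominal rules at level I.
    """
    items = cascade.parse_items(list(sentence.tokens))
    phrases = []
    for item in items:
        if item.category in NOUN_PHRASE_CATEGORIES:
            phrases.append(
                PhraseMatch(
                    span=item.span,
                    category=item.category,
                    tokens=item.tokens,
                    features=item.features,
                    children=item.children,
                    is_maximal=True,
                )
            )
    return phrases


def phrase_token_length(match: PhraseMatch) -> int:
    """Number of corpus tokens in the span; special characters (e.g. the
    hyphen of a compound adjective) count as tokens of their own."""
    return len(match)


# ---------------------------------------------------------------------------
# compilation

def _compile_item(raw: dict, stop_lists: dict[str, frozenset[str]],
                  known: frozenset[str], where: str) -> RuleItem:
    cats = raw.get("cat", raw.get("pos"))
    if cats is None:
        raise GrammarError(f"{where}: rule item without 'cat'")
    if isinstance(cats, str):
        cats = [cats]
    for cat in cats:
        if cat not in known:
            raise GrammarError(f"{where}: undefined category {cat!r}")
    stoplist = None
    if "stoplist" in raw:
        name = raw["stoplist"]
        if name not in stop_lists:
            raise GrammarError(f"{where}: unknown stop list {name!r}")
        stoplist = frozenset(stop_lists[name])
    agree = tuple(raw.get("agree", ()))
    fixed = tuple(
        (key, raw[key]) for key in _VAR_TO_FEATURE_ORDER if key in raw
    )
    return RuleItem(
        cats=tuple(cats),
        optional=bool(raw.get("optional", False)),
        lemma=raw.get("lemma"),
        surface=raw.get("surface"),
        stoplist=stoplist,
        agree=agree,
        fixed=fixed,
    )


def compile_cascade(
    rule_file: str | Path,
    stop_lists: dict[str, Iterable[str]] | None = None,
    mode: str = "full",
    allow_trailing_acronym: bool = True,
) -> Cascade:
    """Compile a YAML rule file into a :class:`Cascade`.

    The file is a list of rules ``{level, lhs, rhs, head?, flag?}``; rules
    keep file order within each level.  ``stop_lists`` maps list names used
    by ``stoplist:`` items to lemma collections.  Rules flagged
    ``trailing_acronym`` (the noun-group + trailing-acronym pattern, a known
    source of improperly structured phrases) are dropped when
    ``allow_trailing_acronym`` is false.
    """
    if mode not in ("full", "simplified"):
        raise GrammarError(f"unknown grammar mode {mode!r}")
    stop_lists = {
        name: frozenset(lemmas) for name, lemmas in (stop_lists or {}).items()
    }
    with open(rule_file, encoding="utf-8") as handle:
        raw_rules = yaml.safe_load(handle)
    if not isinstance(raw_rules, list) or not raw_rules:
        raise GrammarError(f"{rule_file}: expected a non-empty list of rules")

    known = frozenset(TERMINAL_CLASSES) | {
        str(r.get("lhs")) for r in raw_rules if isinstance(r, dict)
    }
    levels: dict[int, list[GrammarRule]] = {}
    for index, raw in enumerate(raw_rules):
        where = f"{rule_file}: rule {index} ({raw.get('lhs', '?')})"
        level = raw.get("level")
        if not isinstance(level, int) or not 1 <= level <= 6:
            raise GrammarError(f"{where}: level must be 1..6")
        lhs = raw.get("lhs")
        if not lhs:
            raise GrammarError(f"{where}: missing lhs")
        if raw.get("flag") == "trailing_acronym" and not allow_trailing_acronym:
            continue
        rhs = tuple(
            _compile_item(item, stop_lists, known, where)
            for item in raw.get("rhs", [])
        )
        if not rhs:
            raise GrammarError(f"{where}: empty rhs")
        if all(item.optional for item in rhs):
            raise GrammarError(f"{where}: every rhs item is optional")
        var_counts: dict[str, int] = {}
        for item in rhs:
            for var in item.agree:
                var_counts[var] = var_counts.get(var, 0) + 1
        for var, count in var_counts.items():
            if count < 2:
                raise GrammarError(
                    f"{where}: agreement variable {var!r} used once, no partner"
                )
        head = int(raw.get("head", 1))
        if not 1 <= head <= len(rhs):
            raise GrammarError(f"{where}: head index {head} out of range")
        rule = GrammarRule(
            level=level, lhs=lhs, rhs=rhs, head=head,
            name=raw.get("name", f"rule{index}"), flag=raw.get("flag"),
        )
        levels.setdefault(level, []).append(rule)
    missing = [lvl for lvl in range(1, 7) if lvl not in levels]
    if missing:
        raise GrammarError(f"{rule_file}: no rules for level(s) {missing}")
    return Cascade(levels=levels, mode=mode)


def load_stop_list(path: str | Path) -> frozenset[str]:
    """One lemma per line; '#' comments and blank lines ignored."""
    lemmas = set()
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if line and not line.startswith("#"):
                lemmas.add(line.lower())
    return frozenset(lemmas)


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def default_cascade(mode: str = "full",
                    allow_trailing_acronym: bool = True) -> Cascade:
    """The shipped six-level grammar with its default stop lists."""
    stop_lists = {
        "nz": load_stop_list(_data_path("stop_nz.txt")),
        "az": load_stop_list(_data_path("stop_az.txt")),
    }
    return compile_cascade(
        _data_path("grammar_default.yaml"),
        stop_lists=stop_lists,
        mode=mode,
        allow_trailing_acronym=allow_trailing_acronym,
    )
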