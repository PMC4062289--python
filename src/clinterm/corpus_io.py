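"""Reading and writing vertically tagged corpora and auxiliary dictionaries.

The corpus format is one token per line::

    surface<TAB>lemma<TAB>pos:feature:feature...

with a blank line marking a sentence boundary.  Tags are positional and
colon-joined; the first field is the word class, the remaining fields are
morphological feature values.  Only the agreement triple {case, gender,
number} matters to the phrase grammar, so features are stored under reserved
keys when recognisable and passed through verbatim otherwise.

Word classes follow the conventional Polish tagset mnemonics: ``subst``
(noun), ``ger`` (gerund), ``adj`` (adjective), ``adja`` (ad-adjectival form
used in hyphenated compounds), ``ppas`` (passive participle), ``adv``
(adverb), ``foreign``/``foreign_subst`` (Latin/English material), the four
nominal abbreviation subtypes ``brev:pun:nw``, ``brev:npun:nw``,
``brev:pun:nphr``, ``brev:npun:nphr`` plus the adjectival ``brev:adjw:pun``
and ``brev:adjw:npun``, ``conj``, ``interp`` (punctuation), ``num`` and
``other``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "TaggedToken",
    "Sentence",
    "AbbreviationDict",
    "CorrectionRule",
    "CorpusFormatError",
    "read_vertical",
    "write_vertical",
    "tokenize_plain",
    "apply_corrections",
    "expand_abbreviations",
    "read_abbreviation_dict",
    "read_correction_rules",
]

#: word classes whose tokens carry the case/gender/number agreement triple
INFLECTING_CLASSES = frozenset({"subst", "ger", "adj", "adja", "ppas"})

#: known case values (Polish positional tagset mnemonics)
CASES = frozenset({"nom", "gen", "dat", "acc", "inst", "loc", "voc"})
GENDERS = frozenset({"m", "m1", "m2", "m3", "f", "n"})
NUMBERS = frozenset({"sg", "pl"})


class CorpusFormatError(ValueError):
    """Raised for malformed vertical-format input, with line diagnostics."""


@dataclass(frozen=True)
class TaggedToken:
    """One corpus token with surface form, lemma and morphological tag."""

    surface: str
    lemma: str
    pos: str
    features: Mapping[str, str] = field(default_factory=dict)
    is_special_char: bool = False
    line: int = -1

    @property
    def case(self) -> str | None:
        return self.features.get("case")

    @property
    def gender(self) -> str | None:
        return self.features.get("gender")

    @property
    def number(self) -> str | None:
        return self.features.get("number")

    def tag_string(self) -> str:
        parts = [self.pos]
        for key in ("case", "gender", "number"):
            if key in self.features:
                parts.append(self.features[key])
        for key, value in self.features.items():
            if key.startswith("x"):
                parts.append(value)
        return ":".join(parts)


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[TaggedToken, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("a sentence must contain at least one token")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


@dataclass(frozen=True)
class AbbreviationDict:
    """Maps abbreviation surfaces (period-insensitive) to full-form lemmas."""

    entries: Mapping[str, str]

    @staticmethod
    def _normalise(surface: str) -> str:
        return surface.rstrip(".").lower()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AbbreviationDict":
        entries: dict[str, str] = {}
        for abbrev, full in pairs:
            if not full:
                raise ValueError(f"empty full form for abbreviation {abbrev!r}")
            entries[cls._normalise(abbrev)] = full.lower()
        return cls(entries=entries)

    def lookup(self, surface: str) -> str | None:
        return self.entries.get(self._normalise(surface))


@dataclass(frozen=True)
class CorrectionRule:
    """Context-free token rewrite: match on surface/lemma/pos, rewrite tag
    and/or lemma.  Rules apply in file order; the first match wins."""

    match_surface: str | None = None
    match_lemma: str | None = None
    match_pos: str | None = None
    set_lemma: str | None = None
    set_pos: str | None = None
    set_features: Mapping[str, str] | None = None

    def matches(self, token: TaggedToken) -> bool:
        if self.match_surface is not None and token.surface != self.match_surface:
            return False
        if self.match_lemma is not None and token.lemma != self.match_lemma:
            return False
        if self.match_pos is not None and token.pos != self.match_pos:
            return False
        return self.match_surface is not None or self.match_lemma is not None \
            or self.match_pos is not None

    def apply(self, token: TaggedToken) -> TaggedToken:
        changes: dict = {}
        if self.set_lemma is not None:
            changes["lemma"] = self.set_lemma.lower()
        if self.set_pos is not None:
            changes["pos"] = self.set_pos
        if self.set_features is not None:
            merged = dict(token.features)
            merged.update(self.set_features)
            changes["features"] = merged
        return replace(token, **changes) if changes else token


def _parse_tag(tag: str) -> tuple[str, dict[str, str]]:
    parts = tag.split(":")
    if parts[0] == "brev":
        # abbreviation subtype is part of the class code, not a feature
        return tag, {}
    pos = parts[0]
    features: dict[str, str] = {}
    extra = 0
    for value in parts[1:]:
        if value in CASES and "case" not in features:
            features["case"] = value
        elif value in GENDERS and "gender" not in features:
            features["gender"] = value
        elif value in NUMBERS and "number" not in features:
            features["number"] = value
        else:
            # unknown feature values are preserved verbatim
            features[f"x{extra}"] = value
            extra += 1
    return pos, features


def _token_from_fields(surface: str, lemma: str, tag: str, line: int) -> TaggedToken:
    pos, features = _parse_tag(tag)
    special = pos == "interp" or (len(surface) == 1 and not surface.isalnum())
    return TaggedToken(
        surface=surface,
        lemma=lemma.lower(),  # lemma comparison is case-insensitive downstream
        pos=pos,
        features=features,
        is_special_char=special,
        line=line,
    )


def read_vertical(source: str | Path | io.TextIOBase) -> list[Sentence]:
    """Read a vertical tagged corpus.

    Blank lines separate sentences; an empty file yields an empty list.
    Raises :class:`CorpusFormatError` naming the offending line for rows that
    do not have exactly three tab-separated fields.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return read_vertical(handle)

    sentences: list[Sentence] = []
    current: list[TaggedToken] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if current:
                sentences.append(Sentence(tuple(current)))
                current = []
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise CorpusFormatError(
                f"line {lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        current.append(_token_from_fields(*fields, line=lineno))
    if current:
        sentences.append(Sentence(tuple(current)))
    return sentences


def write_vertical(sentences: Iterable[Sentence], target: str | Path | io.TextIOBase) -> None:
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as handle:
            write_vertical(sentences, handle)
        return
    first = True
    for sentence in sentences:
        if not first:
            target.write("\n")
        first = False
        for token in sentence:
            target.write(f"{token.surface}\t{token.lemma}\t{token.tag_string()}\n")


_WORD_RE = re.compile(r"[^\W\d_][\w]*|\d+|[^\w\s]|_", re.UNICODE)


def tokenize_plain(text: str) -> list[tuple[str, str]]:
    """Segment raw text into (surface, class) pairs.

    Words may contain digits but never start with one, so ``12mm`` splits
    into a number and a word while ``B12`` stays a single word.  Every
    non-alphanumeric, non-space character is its own special-character token.
    """
    out: list[tuple[str, str]] = []
    for match in _WORD_RE.finditer(text):
        piece = match.group(0)
        if piece[0].isdigit():
            out.append((piece, "number"))
        elif piece[0].isalpha():
            out.append((piece, "word"))
        else:
            out.append((piece, "special"))
    return out


def apply_corrections(
    sentences: Iterable[Sentence], rules: list[CorrectionRule]
) -> tuple[list[Sentence], dict[int, int]]:
    """Rewrite tokens by the first matching rule; returns (sentences, counts)
    where counts maps rule index to number of applications."""
    counts: dict[int, int] = {i: 0 for i in range(len(rules))}
    result: list[Sentence] = []
    for sentence in sentences:
        tokens: list[TaggedToken] = []
        for token in sentence:
            for i, rule in enumerate(rules):
                if rule.matches(token):
                    token = rule.apply(token)
                    counts[i] += 1
                    break
            tokens.append(token)
        result.append(Sentence(tuple(tokens)))
    return result, counts


def expand_abbreviations(
    sentences: Iterable[Sentence], abbrevs: AbbreviationDict
) -> list[Sentence]:
    """Replace the lemma of known abbreviation tokens by the full-form lemma.

    Surfaces are untouched; unmatched abbreviations pass through.  This is
    what lets variant shortenings of the same word collapse to one simplified
    base form downstream.
    """
    result: list[Sentence] = []
    for sentence in sentences:
        tokens: list[TaggedToken] = []
        for token in sentence:
            if token.pos.startswith("brev"):
                full = abbrevs.lookup(token.surface)
                if full is not None:
                    token = replace(token, lemma=full)
            tokens.append(token)
        result.append(Sentence(tuple(tokens)))
    return result


def read_abbreviation_dict(path: str | Path) -> AbbreviationDict:
    """TSV file: abbreviation<TAB>full-form lemma."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            pairs.append((fields[0], fields[1]))
    return AbbreviationDict.from_pairs(pairs)


def read_correction_rules(path: str | Path) -> list[CorrectionRule]:
    """YAML list of {match: {...}, set: {...}} mappings, applied in order."""
    import yaml

    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or []
    rules: list[CorrectionRule] = []
    for i, entry in enumerate(raw):
        try:
            match = entry.get("match", {})
            rewrite = entry.get("set", {})
            rule = CorrectionRule(
                match_surface=match.get("surface"),
                match_lemma=match.get("lemma"),
                match_pos=match.get("pos"),
                set_lemma=rewrite.get("lemma"),
                set_pos=rewrite.get("pos"),
                set_features=rewrite.get("features"),
            )
        except AttributeError as exc:
            raise CorpusFormatError(f"{path}: rule {i}: not a mapping") from exc
        if not any(
            (rule.match_surface, rule.match_lemma, rule.match_pos)
        ):
            raise CorpusFormatError(f"{path}: rule {i}: empty match pattern")
        rules.append(rule)
    return rules
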