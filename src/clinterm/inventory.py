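"""Nested-phrase enumeration and frequency aggregation.

Phrase identity is the *simplified base form*: the sequence of lemmas of
the phrase's tokens.  In an inflectional language the surface (and even the
properly lemmatised nominative) of a nested phrase rarely matches the
containing phrase literally, while the lemma sequence of the nested phrase
is always a contiguous slice of the containing phrase's lemma sequence.
The price is that some semantically distinct phrases merge (number on
genitive modifiers, adjective degree, negation, gerund/participle pairs
sharing an infinitive lemma); these merges are accepted.

A *nested* phrase is every proper sub-span of a maximal phrase that the
cascade itself accepts as a full noun phrase; sub-spans are re-parsed with
the same cascade, so adjective-only fragments can never qualify.  Each
nested occurrence records the containing phrase and the lemma sequences to
its left and right inside it — the raw material for the context-counting
schemes of the ranking stage.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import Sentence, TaggedToken
from .grammar import Cascade, PhraseMatch, parse_sentence

__all__ = [
    "SimplifiedForm",
    "TermRecord",
    "Inventory",
    "simplify",
    "enumerate_nested",
    "aggregate",
    "write_inventory",
    "read_inventory",
]

SimplifiedForm = tuple[str, ...]

#: placeholder for an empty context side
EMPTY = ""


def simplify(match: PhraseMatch) -> SimplifiedForm:
    """Lemma sequence of a phrase, in surface order.

    Special-character tokens (hyphens of compound adjectives) keep their
    surface; everything else contributes its (lower-cased) lemma.
    """
    return match.lemmas


def _simplify_tokens(tokens: Sequence[TaggedToken]) -> SimplifiedForm:
    return tuple(t.surface if t.is_special_char else t.lemma for t in tokens)


@dataclass
class TermRecord:
    """Aggregated counts for one simplified base form.

    ``contexts`` maps (left lemma sequence, right lemma sequence) — the
    material flanking a nested occurrence inside its containing maximal
    phrase — to the number of such occurrences.  The containing phrase's
    own form is recoverable as ``left + form + right``.
    ``ext_contexts`` collects the (lemma, word class) pairs immediately
    adjacent to the term's standalone occurrences in running text; the
    NC-value step consumes them.
    """

    form: SimplifiedForm
    length_tokens: int
    freq_standalone: int = 0
    contexts: Counter = field(default_factory=Counter)
    ext_contexts: Counter = field(default_factory=Counter)
    surface_variants: set = field(default_factory=set)

    @property
    def freq_nested(self) -> int:
        return sum(self.contexts.values())

    @property
    def freq(self) -> int:
        return self.freq_standalone + self.freq_nested

    @property
    def super_forms(self) -> Counter:
        supers: Counter = Counter()
        for (left, right), count in self.contexts.items():
            supers[left + self.form + right] += count
        return supers

    @property
    def left_words(self) -> list[str]:
        """Single lemma immediately left of each nested occurrence (the
        empty marker at a phrase edge); multiset of size freq_nested."""
        out: list[str] = []
        for (left, _right), count in self.contexts.items():
            word = left[-1] if left else EMPTY
            out.extend([word] * count)
        return out

    @property
    def right_words(self) -> list[str]:
        out: list[str] = []
        for (_left, right), count in self.contexts.items():
            word = right[0] if right else EMPTY
            out.extend([word] * count)
        return out


@dataclass
class Inventory:
    records: dict[SimplifiedForm, TermRecord] = field(default_factory=dict)
    corpus_token_count: int = 0
    maximal_occurrences: int = 0

    def record(self, form: SimplifiedForm) -> TermRecord:
        if form not in self.records:
            self.records[form] = TermRecord(form=form, length_tokens=len(form))
        return self.records[form]


def enumerate_nested(match: PhraseMatch, cascade: Cascade) -> list[tuple[int, int]]:
    """All proper sub-spans of a maximal phrase that are noun phrases.

    Spans are absolute token intervals within the sentence.  Each candidate
    slice is re-parsed with the cascade and kept iff it reduces to a single
    full noun phrase, so the grammar itself draws the nested borders.
    """
    start, end = match.span
    length = end - start
    nested: list[tuple[int, int]] = []
    for i in range(length):
        for j in range(i + 1, length + 1):
            if j - i == length:
                continue  # proper sub-spans only
            if cascade.accepts_as_phrase(match.tokens[i:j]):
                nested.append((start + i, start + j))
    return nested


class OverlapError(RuntimeError):
    """Maximal phrases within one sentence overlapped — internal error."""


def aggregate(sentences: Iterable[Sentence], cascade: Cascade) -> Inventory:
    """Parse a corpus and build the full term inventory.

    Every maximal-phrase occurrence increments its record's standalone
    frequency; every noun-phrase sub-span occurrence increments the nested
    frequency of its own record, with the containing phrase's flanking
    lemma sequences stored as the nesting context.  A sub-span occurring at
    several positions of one containing occurrence counts once per
    position.  Sentence-level neighbours of maximal occurrences are stored
    for the NC step.
    """
    inventory = Inventory()
    for sentence in sentences:
        tokens = sentence.tokens
        inventory.corpus_token_count += len(tokens)
        phrases = parse_sentence(sentence, cascade)
        last_end = -1
        for phrase in phrases:
            if phrase.span[0] < last_end:
                raise OverlapError(
                    f"overlapping maximal phrases at {phrase.span}"
                )
            last_end = phrase.span[1]
            inventory.maximal_occurrences += 1
            form = simplify(phrase)
            rec = inventory.record(form)
            rec.freq_standalone += 1
            rec.surface_variants.add(" ".join(t.surface for t in phrase.tokens))
            # sentence context for the NC step
            start, end = phrase.span
            if start > 0:
                left = tokens[start - 1]
                rec.ext_contexts[(left.lemma, left.pos)] += 1
            if end < len(tokens):
                right = tokens[end]
                rec.ext_contexts[(right.lemma, right.pos)] += 1
            # nested occurrences
            lemmas = _simplify_tokens(phrase.tokens)
            for i, j in enumerate_nested(phrase, cascade):
                ri, rj = i - start, j - start
                sub = inventory.record(lemmas[ri:rj])
                sub.contexts[(lemmas[:ri], lemmas[rj:])] += 1
                sub.surface_variants.add(
                    " ".join(t.surface for t in tokens[i:j])
                )
    return inventory


# ---------------------------------------------------------------------------
# TSV interchange

def _encode_contexts(contexts: Counter) -> str:
    payload = [
        [list(left), list(right), count]
        for (left, right), count in sorted(contexts.items())
    ]
    return json.dumps(payload, ensure_ascii=False)


def _decode_contexts(blob: str) -> Counter:
    contexts: Counter = Counter()
    for left, right, count in json.loads(blob):
        contexts[(tuple(left), tuple(right))] = count
    return contexts


def write_inventory(inventory: Inventory, path: str | Path) -> None:
    """Inventory as TSV: one row per simplified form, contexts serialized
    as JSON columns, with corpus-level counts in a header comment."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            f"# corpus_token_count={inventory.corpus_token_count}"
            f"\tmaximal_occurrences={inventory.maximal_occurrences}\n"
        )
        handle.write(
            "form\tlength\tfreq_standalone\tfreq_nested\t"
            "contexts\text_contexts\tsurfaces\n"
        )
        for form in sorted(inventory.records):
            rec = inventory.records[form]
            ext = json.dumps(
                [[lemma, pos, count]
                 for (lemma, pos), count in sorted(rec.ext_contexts.items())],
                ensure_ascii=False,
            )
            handle.write(
                "\t".join(
                    [
                        " ".join(rec.form),
                        str(rec.length_tokens),
                        str(rec.freq_standalone),
                        str(rec.freq_nested),
                        _encode_contexts(rec.contexts),
                        ext,
                        json.dumps(sorted(rec.surface_variants),
                                   ensure_ascii=False),
                    ]
                )
                + "\n"
            )


def read_inventory(path: str | Path) -> Inventory:
    inventory = Inventory()
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().strip()
        if header.startswith("#"):
            for piece in header[1:].split("\t"):
                key, _, value = piece.strip().partition("=")
                if key == "corpus_token_count":
                    inventory.corpus_token_count = int(value)
                elif key == "maximal_occurrences":
                    inventory.maximal_occurrences = int(value)
            handle.readline()  # column header
        for raw in handle:
            if not raw.strip():
                continue
            (form_s, length, standalone, _nested, contexts, ext,
             surfaces) = raw.rstrip("\n").split("\t")
            form = tuple(form_s.split(" "))
            rec = TermRecord(
                form=form,
                length_tokens=int(length),
                freq_standalone=int(standalone),
                contexts=_decode_contexts(contexts),
                surface_variants=set(json.loads(surfaces)),
            )
            for lemma, pos, count in json.loads(ext):
                rec.ext_contexts[(lemma, pos)] = count
            inventory.records[form] = rec
    return inventory
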