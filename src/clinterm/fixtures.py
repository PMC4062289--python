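"""Synthetic tagged corpora with analytically known phrase composition.

Real clinical discharge summaries cannot be shipped, so every stage of the
pipeline is exercised on generated corpora instead.  A fixture is a plan
mapping phrase *templates* — fully tagged token sequences with a declared
maximal-phrase span and declared noun-phrase sub-spans — to occurrence
counts.  The generator realises the plan exactly (one phrase per sentence,
optional sentence-final period, optional non-phrase filler sentences drawn
from a closed vocabulary that can never form a candidate), shuffles
sentence order with a fixed seed, and derives the expected inventory and
C/C₁ scores directly from the plan, independently of the parsing and
ranking code paths.

The built-in template library covers the canonical situations of Polish
nominal terminology: adjective pre/post-modification, genitive chains,
gerund heads, acronym heads, hyphenated compound adjectives, stop-word
prefixes and agreement violations.  Template metadata (which sub-spans are
noun phrases) is hand-derived from the grammar definition, not computed by
it — that independence is what makes the end-to-end oracle meaningful.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .corpus_io import Sentence, TaggedToken, _token_from_fields

__all__ = [
    "TokenSpec",
    "Template",
    "FixtureSpec",
    "GroundTruthRecord",
    "GroundTruth",
    "BUILTIN_TEMPLATES",
    "generate",
    "paper_examples_plan",
    "paper_examples_fixture",
    "expected_c_value",
]

TokenSpec = tuple[str, str, str]  # (surface, lemma, tag)


@dataclass(frozen=True)
class Template:
    """A tagged phrase skeleton with its declared phrase structure.

    ``phrase_span`` is the maximal noun phrase the grammar should find
    (None for negative templates); ``nested`` lists every proper sub-span
    of it that is itself a noun phrase.  Both use template-relative token
    indices.
    """

    name: str
    tokens: tuple[TokenSpec, ...]
    phrase_span: tuple[int, int] | None = None
    nested: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.phrase_span is not None:
            ps, pe = self.phrase_span
            if not (0 <= ps < pe <= len(self.tokens)):
                raise ValueError(f"{self.name}: phrase span out of range")
            for i, j in self.nested:
                if not (ps <= i < j <= pe) or (i, j) == (ps, pe):
                    raise ValueError(
                        f"{self.name}: nested span {(i, j)} not a proper "
                        "sub-span of the phrase"
                    )
        elif self.nested:
            raise ValueError(f"{self.name}: nested spans without a phrase")

    def lemmas(self) -> tuple[str, ...]:
        out = []
        for surface, lemma, tag in self.tokens:
            special = tag == "interp" or (len(surface) == 1 and not surface.isalnum())
            out.append(surface if special else lemma.lower())
        return tuple(out)


@dataclass
class FixtureSpec:
    templates: Mapping[str, Template]
    plan: Mapping[str, int]
    seed: int = 0
    noise: float = 0.0          # filler sentences per planned phrase sentence
    final_period: bool = True

    def __post_init__(self) -> None:
        for name, count in self.plan.items():
            if name not in self.templates:
                raise ValueError(f"plan refers to unknown template {name!r}")
            if count < 0:
                raise ValueError(f"negative count for template {name!r}")


@dataclass
class GroundTruthRecord:
    form: tuple[str, ...]
    freq_standalone: int = 0
    contexts: Counter = field(default_factory=Counter)

    @property
    def freq_nested(self) -> int:
        return sum(self.contexts.values())

    @property
    def freq(self) -> int:
        return self.freq_standalone + self.freq_nested


@dataclass
class GroundTruth:
    records: dict[tuple[str, ...], GroundTruthRecord] = field(default_factory=dict)
    maximal_occurrences: int = 0

    def record(self, form: tuple[str, ...]) -> GroundTruthRecord:
        if form not in self.records:
            self.records[form] = GroundTruthRecord(form=form)
        return self.records[form]


def expected_c_value(
    record: GroundTruthRecord,
    scheme: str = "max_separate",
    unigram_l: float = 0.1,
    zero_rule: bool = True,
) -> float:
    """Direct transcription of the C-value definition over plan-derived
    counts — the independent oracle for the ranking stage."""
    length = len(record.form)
    weight = unigram_l if length == 1 else math.log2(length)
    if scheme == "original":
        r = len(set(record.contexts))
    else:
        left = {l[-1] for (l, _r) in record.contexts if l}
        right = {r[0] for (_l, r) in record.contexts if r}
        if scheme == "grouped_words":
            r = len(left | right)
        elif scheme == "max_separate":
            r = max(len(left), len(right))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    if zero_rule and record.freq_standalone == 0 and r <= 1:
        return 0.0
    if r == 0:
        return weight * record.freq
    return weight * (record.freq - record.freq_nested / r)


# ---------------------------------------------------------------------------
# built-in template library

def _template(name, tokens, span=None, nested=()):
    return Template(
        name=name,
        tokens=tuple(tokens),
        phrase_span=span,
        nested=tuple(nested),
    )


BUILTIN_TEMPLATES: dict[str, Template] = {
    t.name: t
    for t in [
        # 4-token gerund-headed phrase ("hospital treatment information card")
        _template(
            "karta4",
            [
                ("karta", "karta", "subst:nom:f:sg"),
                ("informacyjna", "informacyjny", "adj:nom:f:sg"),
                ("leczenia", "leczyć", "ger:gen:n:sg"),
                ("szpitalnego", "szpitalny", "adj:gen:n:sg"),
            ],
            span=(0, 4),
            nested=[(0, 1), (0, 2), (0, 3), (2, 3), (2, 4)],
        ),
        # the same phrase under a premodifier ("previous ... card")
        _template(
            "karta5",
            [
                ("poprzednia", "poprzedni", "adj:nom:f:sg"),
                ("karta", "karta", "subst:nom:f:sg"),
                ("informacyjna", "informacyjny", "adj:nom:f:sg"),
                ("leczenia", "leczyć", "ger:gen:n:sg"),
                ("szpitalnego", "szpitalny", "adj:gen:n:sg"),
            ],
            span=(0, 5),
            nested=[(0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (1, 5),
                    (3, 4), (3, 5)],
        ),
        # adjective on both sides of the head ("left kidney normal")
        _template(
            "lewa_nerka",
            [
                ("lewa", "lewy", "adj:nom:f:sg"),
                ("nerka", "nerka", "subst:nom:f:sg"),
                ("prawidłowa", "prawidłowy", "adj:nom:f:sg"),
            ],
            span=(0, 3),
            nested=[(0, 2), (1, 2), (1, 3)],
        ),
        # two postmodifiers ("normal gall bladder")
        _template(
            "pecherzyk",
            [
                ("pęcherzyk", "pęcherzyk", "subst:nom:m:sg"),
                ("żółciowy", "żółciowy", "adj:nom:m:sg"),
                ("prawidłowy", "prawidłowy", "adj:nom:m:sg"),
            ],
            span=(0, 3),
            nested=[(0, 1), (0, 2)],
        ),
        # genitive chain ("influenza virus infection", genitive throughout)
        _template(
            "zakazenie",
            [
                ("zakażenia", "zakażenie", "subst:gen:n:sg"),
                ("wirusem", "wirus", "subst:gen:m:sg"),
                ("grypy", "grypa", "subst:gen:f:sg"),
            ],
            span=(0, 3),
            nested=[(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)],
        ),
        # the four nesting contexts of "lymph nodes"
        _template(
            "powiekszenie1",
            [
                ("powiększenie", "powiększenie", "subst:nom:n:sg"),
                ("węzłów", "węzeł", "subst:gen:m:pl"),
                ("chłonnych", "chłonny", "adj:gen:m:pl"),
            ],
            span=(0, 3),
            nested=[(0, 1), (0, 2), (1, 2), (1, 3)],
        ),
        _template(
            "powiekszenie2",
            [
                ("powiększenie", "powiększenie", "subst:nom:n:sg"),
                ("węzłów", "węzeł", "subst:gen:m:pl"),
                ("chłonnych", "chłonny", "adj:gen:m:pl"),
                ("krezkowych", "krezkowy", "adj:gen:m:pl"),
            ],
            span=(0, 4),
            nested=[(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (1, 4)],
        ),
        _template(
            "powiekszenie3",
            [
                ("znaczne", "znaczny", "adj:nom:n:sg"),
                ("powiększenie", "powiększenie", "subst:nom:n:sg"),
                ("węzłów", "węzeł", "subst:gen:m:pl"),
                ("chłonnych", "chłonny", "adj:gen:m:pl"),
            ],
            span=(0, 4),
            nested=[(0, 2), (0, 3), (1, 2), (1, 3), (1, 4), (2, 3), (2, 4)],
        ),
        _template(
            "powiekszenie4",
            [
                ("powiększenie", "powiększenie", "subst:nom:n:sg"),
                ("węzłów", "węzeł", "subst:gen:m:pl"),
                ("chłonnych", "chłonny", "adj:gen:m:pl"),
                ("szyji", "szyja", "subst:gen:f:sg"),
            ],
            span=(0, 4),
            nested=[(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (1, 4), (3, 4)],
        ),
        # agreeing adjective-noun pair ("emergency service")
        _template(
            "ostry_dyzur",
            [
                ("ostry", "ostry", "adj:nom:m:sg"),
                ("dyżur", "dyżur", "subst:nom:m:sg"),
            ],
            span=(0, 2),
            nested=[(1, 2)],
        ),
        # gender clash: the adjective cannot attach under the full grammar
        _template(
            "ostra_dyzur",
            [
                ("ostra", "ostry", "adj:nom:f:sg"),
                ("dyżur", "dyżur", "subst:nom:m:sg"),
            ],
            span=(1, 2),
            nested=[],
        ),
        # stop-word prefix: no phrase may start at the stop noun
        _template(
            "w_trakcie",
            [
                ("w", "w", "prep"),
                ("trakcie", "trakt", "subst:loc:m:sg"),
                ("choroby", "choroba", "subst:gen:f:sg"),
            ],
            span=(2, 3),
            nested=[],
        ),
        # acronym head with genitive complement ("abdominal ultrasound")
        _template(
            "usg_jamy",
            [
                ("USG", "usg", "brev:npun:nw"),
                ("jamy", "jama", "subst:gen:f:sg"),
                ("brzusznej", "brzuszny", "adj:gen:f:sg"),
            ],
            span=(0, 3),
            nested=[(0, 1), (0, 2), (1, 2), (1, 3)],
        ),
        # hyphenated compound adjective; the hyphen is a token of its own
        _template(
            "oddzial_chir",
            [
                ("oddział", "oddział", "subst:nom:m:sg"),
                ("chirurgiczno", "chirurgiczny", "adja"),
                ("-", "-", "interp"),
                ("urazowy", "urazowy", "adj:nom:m:sg"),
            ],
            span=(0, 4),
            nested=[(0, 1)],
        ),
        # plain 2-token phrases used for frequency-scaling scenarios
        _template(
            "pediatria",
            [
                ("pediatria", "pediatria", "subst:nom:f:sg"),
                ("ogólna", "ogólny", "adj:nom:f:sg"),
            ],
            span=(0, 2),
            nested=[(0, 1)],
        ),
        _template(
            "kod",
            [
                ("kod", "kod", "subst:nom:m:sg"),
                ("pacjenta", "pacjent", "subst:gen:m:sg"),
            ],
            span=(0, 2),
            nested=[(0, 1), (1, 2)],
        ),
        _template(
            "zalecenie",
            [
                ("zalecenie", "zalecenie", "subst:nom:n:sg"),
                ("lekarskie", "lekarski", "adj:nom:n:sg"),
            ],
            span=(0, 2),
            nested=[(0, 1)],
        ),
    ]
}

#: closed filler vocabulary — no nominal/adjectival classes, so filler can
#: never create an accidental phrase candidate
_FILLER: tuple[TokenSpec, ...] = (
    ("w", "w", "prep"),
    ("nie", "nie", "qub"),
    ("było", "być", "praet"),
    ("stwierdzono", "stwierdzić", "imps"),
    ("oraz", "oraz", "conj"),
    ("7", "7", "num"),
    (",", ",", "interp"),
)

_PERIOD: TokenSpec = (".", ".", "interp")


def _build_sentence(tokens: Iterable[TokenSpec]) -> Sentence:
    return Sentence(
        tuple(
            _token_from_fields(surface, lemma, tag, line=-1)
            for surface, lemma, tag in tokens
        )
    )


def _ground_truth(spec: FixtureSpec) -> GroundTruth:
    truth = GroundTruth()
    for name, count in sorted(spec.plan.items()):
        if count == 0:
            continue
        template = spec.templates[name]
        if template.phrase_span is None:
            continue
        ps, pe = template.phrase_span
        lemmas = template.lemmas()
        phrase_form = lemmas[ps:pe]
        truth.maximal_occurrences += count
        rec = truth.record(phrase_form)
        rec.freq_standalone += count
        for i, j in template.nested:
            sub = truth.record(lemmas[i:j])
            sub.contexts[(lemmas[ps:i], lemmas[j:pe])] += count
    return truth


def generate(spec: FixtureSpec) -> tuple[list[Sentence], GroundTruth]:
    """Realise a fixture plan as a shuffled tagged corpus plus its
    analytically derived ground truth.  Reproducible for a given seed."""
    rng = random.Random(spec.seed)
    sentences: list[Sentence] = []
    for name, count in sorted(spec.plan.items()):
        template = spec.templates[name]
        tokens = list(template.tokens)
        if spec.final_period:
            tokens.append(_PERIOD)
        for _ in range(count):
            sentences.append(_build_sentence(tokens))
    n_filler = round(spec.noise * len(sentences))
    for _ in range(n_filler):
        length = rng.randint(2, 5)
        filler = [rng.choice(_FILLER) for _ in range(length)] + [_PERIOD]
        sentences.append(_build_sentence(filler))
    rng.shuffle(sentences)
    return sentences, _ground_truth(spec)


def paper_examples_plan() -> FixtureSpec:
    """The canned worked-example corpus: every in-text example phrase, with
    the 1164/1 standalone/nesting split for the 4/5-token card phrases."""
    plan = {
        "karta4": 1164,
        "karta5": 1,
        "lewa_nerka": 1,
        "pecherzyk": 1,
        "zakazenie": 1,
        "powiekszenie1": 1,
        "powiekszenie2": 1,
        "powiekszenie3": 1,
        "powiekszenie4": 1,
        "ostry_dyzur": 1,
        "ostra_dyzur": 1,
        "w_trakcie": 1,
        "usg_jamy": 1,
        "oddzial_chir": 1,
    }
    return FixtureSpec(templates=BUILTIN_TEMPLATES, plan=plan, seed=0)


def paper_examples_fixture() -> tuple[list[Sentence], GroundTruth]:
    return generate(paper_examples_plan())
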