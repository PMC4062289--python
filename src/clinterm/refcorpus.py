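"""Comparison of a domain term list against a general reference corpus.

The reference corpus (e.g. a general-language corpus of the same language)
is processed with the very same pipeline, yielding a form -> C₁ map.  Each
domain term is then annotated as absent from the reference, present, or
present with a *higher* reference score — the last group being the terms a
contrastive filter would demote.  This stage only annotates and reports;
it does not filter, because common phrases in clinical text are mostly
still medical and corpus sizes are incommensurable anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .ranking import RankedTerm

__all__ = ["ReferenceAnnotation", "compare_to_reference", "write_reference_report"]

ABSENT = "absent"
PRESENT = "present"
HIGHER_IN_REFERENCE = "present-with-higher-reference-score"


@dataclass(frozen=True)
class ReferenceAnnotation:
    form: tuple[str, ...]
    status: str
    domain_score: float
    reference_score: float | None

    @property
    def is_multiword(self) -> bool:
        return len(self.form) > 1


def compare_to_reference(
    domain_terms: Sequence[RankedTerm],
    reference: Mapping[tuple, float],
    score_field: str = "c1_value",
) -> tuple[list[ReferenceAnnotation], dict[str, int]]:
    """Annotate domain terms against reference-corpus scores.

    Returns (annotations, summary).  The summary counts the common-term
    set and its higher-in-reference subset, each split into single-word
    and multi-word terms; the splits partition their totals.
    """
    annotations: list[ReferenceAnnotation] = []
    for term in domain_terms:
        form = term.record.form
        domain_score = getattr(term, score_field) or 0.0
        ref_score = reference.get(form)
        if ref_score is None:
            status = ABSENT
        elif ref_score > domain_score:
            status = HIGHER_IN_REFERENCE
        else:
            status = PRESENT
        annotations.append(
            ReferenceAnnotation(
                form=form,
                status=status,
                domain_score=domain_score,
                reference_score=ref_score,
            )
        )
    summary = {
        "common": 0, "common_1word": 0, "common_multiword": 0,
        "higher_in_reference": 0, "higher_1word": 0, "higher_multiword": 0,
    }
    for ann in annotations:
        if ann.status == ABSENT:
            continue
        summary["common"] += 1
        summary["common_multiword" if ann.is_multiword else "common_1word"] += 1
        if ann.status == HIGHER_IN_REFERENCE:
            summary["higher_in_reference"] += 1
            key = "higher_multiword" if ann.is_multiword else "higher_1word"
            summary[key] += 1
    return annotations, summary


def write_reference_report(
    annotations: Sequence[ReferenceAnnotation],
    summary: Mapping[str, int],
    path: str | Path,
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for key, value in summary.items():
            handle.write(f"# {key}={value}\n")
        handle.write("form\tstatus\tdomain_score\treference_score\n")
        for ann in annotations:
            ref = "" if ann.reference_score is None else f"{ann.reference_score:.2f}"
            handle.write(
                f"{' '.join(ann.form)}\t{ann.status}\t"
                f"{ann.domain_score:.2f}\t{ref}\n"
            )
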