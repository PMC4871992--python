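"""Per-eye best documented visual acuity (BDVA) selection over an encounter.

A single ophthalmology note can hold a separate acuity for each eye in at
least eight structured fields: uncorrected, corrected, pinhole, manifest
(pre-dilation) refraction, cycloplegic (post-dilation) refraction,
autorefraction, and near vision with or without correction.  The BDVA for
an eye is the best-ranked category among the *distance*-field entries that
normalized to a Snellen category; near-vision entries are parsed for audit
but never compete, because the output scale is distance Snellen.

Absence is first-class: an eye whose fields hold no mappable distance
acuity gets status ``NO_ACUITY``, never a sentinel category.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from .normalize import (
    AcuityVocabulary,
    NormalizationResult,
    NormalizationStatus,
    normalize,
)
from .scale import AcuityScale, SnellenCategory

DISTANCE_FIELDS: tuple[str, ...] = (
    "uncorrected",
    "corrected",
    "pinhole",
    "manifest_refraction",
    "cycloplegic_refraction",
    "autorefraction",
)
NEAR_FIELDS: tuple[str, ...] = ("near_uncorrected", "near_corrected")
ALL_FIELDS: tuple[str, ...] = DISTANCE_FIELDS + NEAR_FIELDS

EYES: tuple[str, ...] = ("OD", "OS")

#: When two fields tie at the best rank, the reported source field follows
#: this priority (refraction over pinhole over habitual correction).  The
#: BDVA value itself is identical across ties, so this is reporting only.
DEFAULT_FIELD_PRIORITY: tuple[str, ...] = (
    "manifest_refraction",
    "cycloplegic_refraction",
    "pinhole",
    "corrected",
    "uncorrected",
    "autorefraction",
)


class RecordValidationError(ValueError):
    """An entry violates the closed eye/field vocabularies."""


class BdvaStatus(str, Enum):
    FOUND = "FOUND"
    NO_ACUITY = "NO_ACUITY"


@dataclass
class AcuityEntry:
    """One raw acuity observation from a single note field.

    ``source_row`` carries the input-file row number (when read from CSV)
    so validation errors can name the offending row.
    """

    note_id: str
    patient_id: str
    eye: str
    field_name: str
    raw_text: str
    normalization: Optional[NormalizationResult] = None
    source_row: Optional[int] = None

    def __post_init__(self):
        where = f" (row {self.source_row})" if self.source_row is not None else ""
        if self.eye not in EYES:
            raise RecordValidationError(
                f"invalid eye {self.eye!r}{where}: expected one of {EYES}"
            )
        if self.field_name not in ALL_FIELDS:
            raise RecordValidationError(
                f"invalid field_name {self.field_name!r}{where}: "
                f"expected one of {ALL_FIELDS}"
            )

    @property
    def is_distance(self) -> bool:
        return self.field_name in DISTANCE_FIELDS


@dataclass
class EncounterRecord:
    """All acuity entries for one note."""

    note_id: str
    patient_id: str
    entries: list[AcuityEntry] = field(default_factory=list)

    def __post_init__(self):
        for e in self.entries:
            if e.note_id != self.note_id:
                raise RecordValidationError(
                    f"entry note_id {e.note_id!r} != record note_id {self.note_id!r}"
                )

    def entries_for(self, eye: str) -> list[AcuityEntry]:
        return [e for e in self.entries if e.eye == eye]


@dataclass(frozen=True)
class BdvaResult:
    """The selected BDVA for one (note, eye).

    ``n_candidates`` counts the distance entries that normalized to a
    category; the winner's rank is no worse than any of them.
    """

    note_id: str
    eye: str
    status: BdvaStatus
    bdva: Optional[SnellenCategory] = None
    rank: Optional[int] = None
    source_field: Optional[str] = None
    n_candidates: int = 0

    def __post_init__(self):
        found = self.status is BdvaStatus.FOUND
        if found != (self.bdva is not None) or found != (self.n_candidates >= 1):
            raise ValueError("status FOUND must coincide with a selected category")


def tie_break(
    candidates: Sequence[tuple[SnellenCategory, str]],
    field_priority: Sequence[str] = DEFAULT_FIELD_PRIORITY,
) -> tuple[SnellenCategory, str]:
    """Choose the reported source field among equally ranked candidates."""
    if not candidates:
        raise ValueError("tie_break requires at least one candidate")
    order = {name: i for i, name in enumerate(field_priority)}
    return min(candidates, key=lambda cf: order.get(cf[1], len(order)))


def extract_bdva(
    record: EncounterRecord,
    vocab: AcuityVocabulary | None = None,
    field_priority: Sequence[str] = DEFAULT_FIELD_PRIORITY,
) -> tuple[BdvaResult, BdvaResult]:
    """Return the (OD, OS) best documented visual acuities for one note.

    Every entry is normalized (vocabulary first, fallback scan second);
    NEAR, UNMAPPED and EMPTY entries are discarded; among the remaining
    distance-field candidates the best-ranked category wins.  Eyes are
    independent.  Deterministic for a fixed vocabulary.
    """
    vocab = vocab or AcuityVocabulary.default()
    for entry in record.entries:
        if entry.normalization is None:
            entry.normalization = normalize(entry.raw_text, vocab)

    results = []
    for eye in EYES:
        candidates = [
            (e.normalization.category, e.field_name)
            for e in record.entries_for(eye)
            if e.is_distance and e.normalization.category is not None
        ]
        if not candidates:
            results.append(
                BdvaResult(record.note_id, eye, BdvaStatus.NO_ACUITY)
            )
            continue
        best = vocab.scale.best_of([c for c, _ in candidates])
        winner_cat, winner_field = tie_break(
            [(c, f) for c, f in candidates if c.rank == best.rank], field_priority
        )
        results.append(
            BdvaResult(
                note_id=record.note_id,
                eye=eye,
                status=BdvaStatus.FOUND,
                bdva=winner_cat,
                rank=winner_cat.rank,
                source_field=winner_field,
                n_candidates=len(candidates),
            )
        )
    return results[0], results[1]
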