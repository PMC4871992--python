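"""CSV readers/writers and the chart-review-style accuracy evaluator.

The interchange format is long (tidy): one row per observed acuity with
header ``note_id,patient_id,eye,field_name,response_text``.  Duplicate
(note, eye, field) rows are legal — a field can hold several measurements.
Blank responses are kept as EMPTY entries so that "nothing recorded" stays
visible downstream.  A wide-to-long converter is provided for sites whose
exports put one column per (eye, field).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .extract import (
    ALL_FIELDS,
    EYES,
    AcuityEntry,
    BdvaResult,
    BdvaStatus,
    EncounterRecord,
    RecordValidationError,
    extract_bdva,
)
from .normalize import AcuityVocabulary, NormalizationStatus

logger = logging.getLogger("bdva")

ENCOUNTER_COLUMNS = ["note_id", "patient_id", "eye", "field_name", "response_text"]
BDVA_COLUMNS = ["note_id", "eye", "bdva", "rank", "source_field", "n_candidates", "status"]
TRUTH_COLUMNS = ["note_id", "eye", "bdva"]

#: Label used in gold/truth CSVs for an eye with no documented acuity.
NO_ACUITY_LABEL = "NO_ACUITY"


class CorpusFormatError(ValueError):
    """Malformed encounters/gold CSV; message names the offending rows."""


def read_encounters(path: str | Path) -> list[EncounterRecord]:
    """Read a long-format encounters CSV into grouped records.

    Rows are grouped by ``note_id`` (first-appearance order preserved);
    row numbers (header = row 1) are carried on each entry for error
    reporting.  Invalid eye or field values raise with the row named.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(frame.columns) != ENCOUNTER_COLUMNS:
        raise CorpusFormatError(
            f"{path}: expected columns {ENCOUNTER_COLUMNS}, got {list(frame.columns)}"
        )
    problems: list[str] = []
    records: dict[str, EncounterRecord] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            entry = AcuityEntry(
                note_id=row.note_id,
                patient_id=row.patient_id,
                eye=row.eye,
                field_name=row.field_name,
                raw_text=row.response_text,
                source_row=i,
            )
        except RecordValidationError as err:
            problems.append(str(err))
            continue
        rec = records.get(row.note_id)
        if rec is None:
            rec = records[row.note_id] = EncounterRecord(
                note_id=row.note_id, patient_id=row.patient_id, entries=[]
            )
        rec.entries.append(entry)
    if problems:
        raise CorpusFormatError(f"{path}: " + "; ".join(problems))
    return list(records.values())


def write_encounters(records: Iterable[EncounterRecord], path: str | Path) -> None:
    """Write records back to the long CSV dialect ``read_encounters`` reads."""
    rows = [
        {
            "note_id": e.note_id,
            "patient_id": e.patient_id,
            "eye": e.eye,
            "field_name": e.field_name,
            "response_text": e.raw_text,
        }
        for rec in records
        for e in rec.entries
    ]
    pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS).to_csv(path, index=False)


def wide_to_long(frame: pd.DataFrame) -> pd.DataFrame:
    """Convert a wide export (one ``<eye>_<field>`` column per measurement,
    e.g. ``od_corrected``) to the long interchange format.  Empty cells are
    dropped; column order fixes row order."""
    if not {"note_id", "patient_id"}.issubset(frame.columns):
        raise CorpusFormatError("wide input needs note_id and patient_id columns")
    rows = []
    value_cols = [c for c in frame.columns if c not in ("note_id", "patient_id")]
    for col in value_cols:
        eye, _, fname = col.partition("_")
        if eye.upper() not in EYES or fname not in ALL_FIELDS:
            raise CorpusFormatError(f"unrecognized wide column {col!r}")
    for row in frame.itertuples(index=False):
        d = row._asdict()
        for col in value_cols:
            text = str(d[col]) if not pd.isna(d[col]) else ""
            if not text.strip():
                continue
            eye, _, fname = col.partition("_")
            rows.append(
                {
                    "note_id": d["note_id"],
                    "patient_id": d["patient_id"],
                    "eye": eye.upper(),
                    "field_name": fname,
                    "response_text": text,
                }
            )
    return pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)


def run_extraction(
    records: Iterable[EncounterRecord],
    vocab: AcuityVocabulary | None = None,
    field_priority: Sequence[str] | None = None,
) -> tuple[list[BdvaResult], list[AcuityEntry]]:
    """Extract BDVA for every record, logging maintenance-relevant events.

    Every fallback hit and every UNMAPPED response is logged at info level
    with its note id — the operational hook for vocabulary curation.
    Returns the results plus all (now normalized) entries.
    """
    vocab = vocab or AcuityVocabulary.default()
    kwargs = {} if field_priority is None else {"field_priority": tuple(field_priority)}
    results: list[BdvaResult] = []
    entries: list[AcuityEntry] = []
    for rec in records:
        od, os_ = extract_bdva(rec, vocab, **kwargs)
        results.extend((od, os_))
        for e in rec.entries:
            entries.append(e)
            st = e.normalization.status
            if st is NormalizationStatus.FALLBACK_HIT:
                logger.info(
                    "fallback hit: note=%s %s/%s %r -> %s",
                    e.note_id, e.eye, e.field_name, e.raw_text,
                    e.normalization.category.label,
                )
            elif st is NormalizationStatus.UNMAPPED:
                logger.info(
                    "unmapped response: note=%s %s/%s %r",
                    e.note_id, e.eye, e.field_name, e.raw_text,
                )
    return results, entries


def results_frame(results: Iterable[BdvaResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "note_id": r.note_id,
                "eye": r.eye,
                "bdva": r.bdva.label if r.bdva else "",
                "rank": r.rank if r.rank is not None else "",
                "source_field": r.source_field or "",
                "n_candidates": r.n_candidates,
                "status": r.status.value,
            }
        )
    frame = pd.DataFrame(rows, columns=BDVA_COLUMNS)
    return frame.sort_values(["note_id", "eye"], kind="stable").reset_index(drop=True)


def write_bdva(results: Iterable[BdvaResult], path: str | Path) -> None:
    """Write one row per (note, eye), sorted by note then eye (OD first).

    NO_ACUITY rows leave bdva/rank/source_field empty.
    """
    results_frame(results).to_csv(path, index=False)


# -- accuracy evaluation ---------------------------------------------------


@dataclass(frozen=True)
class AccuracyReport:
    """Percentage agreement of algorithm BDVA against a per-eye gold standard,
    mirroring a clinician chart-review audit."""

    n_patients: int
    n_eyes: int
    right_accuracy: float
    left_accuracy: float
    overall_accuracy: float
    discordances: tuple[tuple[str, str, str, str], ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.discordances),
            columns=["note_id", "eye", "algorithm_bdva", "gold_bdva"],
        )


def _result_label(r: BdvaResult) -> str:
    return r.bdva.label if r.bdva is not None else NO_ACUITY_LABEL


def evaluate_accuracy(
    results: Iterable[BdvaResult] | Mapping[tuple[str, str], str],
    gold: pd.DataFrame | str | Path,
) -> AccuracyReport:
    """Compare algorithm BDVAs with gold labels on category labels.

    ``gold`` is a CSV or frame with columns ``note_id,eye,bdva``; an empty
    bdva cell or ``NO_ACUITY`` means the reviewer found no distance acuity.
    Every gold (note, eye) must be present in the algorithm output.
    Accuracy is concordant eyes / evaluated eyes x 100, overall and per eye.
    """
    if isinstance(gold, (str, Path)):
        gold = pd.read_csv(gold, dtype=str, keep_default_na=False)
    if list(gold.columns) != TRUTH_COLUMNS:
        raise CorpusFormatError(
            f"gold standard: expected columns {TRUTH_COLUMNS}, got {list(gold.columns)}"
        )
    if isinstance(results, Mapping):
        predicted = dict(results)
    else:
        predicted = {(r.note_id, r.eye): _result_label(r) for r in results}

    per_eye = {eye: [0, 0] for eye in EYES}  # concordant, total
    discord: list[tuple[str, str, str, str]] = []
    for row in gold.itertuples(index=False):
        if row.eye not in EYES:
            raise CorpusFormatError(f"gold standard: invalid eye {row.eye!r}")
        key = (row.note_id, row.eye)
        if key not in predicted:
            raise CorpusFormatError(
                f"gold (note={row.note_id}, eye={row.eye}) missing from algorithm output"
            )
        gold_label = row.bdva.strip() or NO_ACUITY_LABEL
        algo_label = predicted[key]
        per_eye[row.eye][1] += 1
        if algo_label == gold_label:
            per_eye[row.eye][0] += 1
        else:
            discord.append((row.note_id, row.eye, algo_label, gold_label))

    def pct(conc: int, total: int) -> float:
        return 100.0 * conc / total if total else float("nan")

    n_eyes = per_eye["OD"][1] + per_eye["OS"][1]
    n_conc = per_eye["OD"][0] + per_eye["OS"][0]
    return AccuracyReport(
        n_patients=gold["note_id"].nunique(),
        n_eyes=n_eyes,
        right_accuracy=pct(*per_eye["OD"]),
        left_accuracy=pct(*per_eye["OS"]),
        overall_accuracy=pct(n_conc, n_eyes),
        discordances=tuple(sorted(discord)),
    )
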