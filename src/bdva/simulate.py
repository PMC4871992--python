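"""Synthetic encounter generator with known ground-truth BDVA.

No public corpus of ophthalmology acuity fields exists, so every other
module is exercised against generated notes that emulate the documented
structure of a real clinic's records: 0-7 acuity entries per eye per note,
a little over half of notes carrying more than one entry per eye, a value
distribution dominated by 20/20 and 20/25, free-text annotations appended
to tokens, O-for-zero typos, +/- line modifiers, extra near-vision (Jäger)
entries, and occasional token-free junk.

Decorations are truth-preserving by construction — annotation phrases
never contain a competing acuity token, modifiers strip back to the base
line, and O/0 typos are repaired by canonicalization — so the generator
doubles as an end-to-end oracle: the truth file is the best clean category
planted per eye, computed before any corruption.  A separate adversarial
mode (``p_competing`` > 0) plants a second, competing token inside an
entry's text and recomputes the truth accordingly, to exercise the
best-token rule inside single fields.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from .extract import DISTANCE_FIELDS, EYES, NEAR_FIELDS, AcuityEntry, EncounterRecord
from .io import NO_ACUITY_LABEL, TRUTH_COLUMNS, write_encounters
from .scale import AcuityScale, SnellenCategory

#: Default categorical distribution over planted acuities.  Mass on 20/20
#: (38.7%) and 20/25 (18.9%) follows the frequencies reported for a large
#: clinical corpus; the tail is spread so that ~86% of values are 20/100 or
#: better, with a thin qualitative (CF..NLP) tail.
DEFAULT_ACUITY_WEIGHTS: dict[str, float] = {
    "20/10": 0.015,
    "20/20": 0.387,
    "20/25": 0.189,
    "20/30": 0.095,
    "20/40": 0.065,
    "20/50": 0.045,
    "20/60": 0.025,
    "20/70": 0.015,
    "20/80": 0.011,
    "20/100": 0.015,
    "20/125": 0.040,
    "20/200": 0.050,
    "20/400": 0.025,
    "CF": 0.012,
    "HM": 0.006,
    "LP": 0.003,
    "NLP": 0.002,
}


def phrase_bank() -> tuple[str, ...]:
    """Annotation templates with a ``{tok}`` slot.

    Includes the canonical provider-annotation examples ("20/20 slow",
    "20/60 w/head tilted down", ...) plus further token-free phrases.  No
    template text contains an acuity token, so instantiation never plants a
    competitor.
    """
    return (
        "{tok} slow",
        "after waiting 1 min {tok} in lighted room",
        "{tok} w/head tilted down",
        "{tok} blinking with ointment",
        "{tok} with glasses",
        "{tok} eccentric fixation",
        "pt squinting {tok}",
        "{tok} tearing during exam",
        "{tok} with effort",
    )


#: Token-free texts used for junk (unmappable) entries.  None of these hit
#: the default vocabulary or contain a scannable token.
JUNK_PHRASES: tuple[str, ...] = (
    "poor view",
    "no view",
    "patient declined",
    "eye patched",
    "unable to assess today",
    "will recheck",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults encode the emulated corpus structure.

    All probabilities are per-entry unless noted.  Identical seed + config
    yields an identical corpus (single deterministic stream, no wall-clock
    entropy).
    """

    n_notes: int = 100
    seed: int = 0
    #: per-note probability that both eyes carry >1 entry
    p_multi: float = 0.54
    max_entries_per_eye: int = 7
    acuity_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACUITY_WEIGHTS)
    )
    p_annotation: float = 0.35
    p_o_transposition: float = 0.08
    p_modifier: float = 0.15
    #: per-eye probability of an extra Jäger entry in a near field
    p_near_entry: float = 0.15
    #: per-eye probability of an extra token-free junk entry
    p_unmappable: float = 0.08
    #: per-note probability that an eye has no entry at all (outside multi notes)
    p_no_entry: float = 0.05
    #: adversarial mode: per-entry probability of a planted competing token
    p_competing: float = 0.0

    def validate(self) -> None:
        probs = {
            "p_multi": self.p_multi,
            "p_annotation": self.p_annotation,
            "p_o_transposition": self.p_o_transposition,
            "p_modifier": self.p_modifier,
            "p_near_entry": self.p_near_entry,
            "p_unmappable": self.p_unmappable,
            "p_no_entry": self.p_no_entry,
            "p_competing": self.p_competing,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.n_notes < 0:
            raise ValueError("n_notes must be non-negative")
        if not 2 <= self.max_entries_per_eye:
            raise ValueError("max_entries_per_eye must be at least 2")
        total = sum(self.acuity_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"acuity_weights must sum to 1, got {total}")
        scale = AcuityScale.default()
        for label in self.acuity_weights:
            if label not in scale:
                raise ValueError(f"acuity_weights key {label!r} not on the scale")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth BDVA for one (note, eye): the best clean planted
    category, or NO_ACUITY when nothing mappable was planted."""

    note_id: str
    eye: str
    true_bdva: Optional[SnellenCategory]

    @property
    def label(self) -> str:
        return self.true_bdva.label if self.true_bdva else NO_ACUITY_LABEL


def _render_entry(
    rng: random.Random,
    cat: SnellenCategory,
    cfg: SimulationConfig,
    scale: AcuityScale,
) -> tuple[str, Optional[SnellenCategory]]:
    """Render one planted category as corrupted free text.

    Returns the text plus an optional competing category (adversarial mode
    only) that the truth computation must account for.
    """
    text = cat.label
    if cat.is_numeric and rng.random() < cfg.p_modifier:
        text += rng.choice(["+1", "+2", "-1", "-2"])
    competitor: Optional[SnellenCategory] = None
    if cfg.p_competing and rng.random() < cfg.p_competing:
        competitor = scale[rng.choice(list(cfg.acuity_weights))]
        text = f"{text} was {competitor.label} last visit"
    if rng.random() < cfg.p_annotation:
        text = rng.choice(phrase_bank()).format(tok=text)
    if "0" in text and rng.random() < cfg.p_o_transposition:
        zeros = [i for i, ch in enumerate(text) if ch == "0"]
        i = rng.choice(zeros)
        text = text[:i] + "O" + text[i + 1 :]
    return text, competitor


def generate_corpus(
    config: SimulationConfig,
) -> tuple[list[EncounterRecord], list[TruthRecord]]:
    """Generate encounter records and their ground-truth BDVAs.

    Per note: one Bernoulli(``p_multi``) draw decides whether both eyes get
    2..``max_entries_per_eye`` entries (so the fraction of multi-entry notes
    equals ``p_multi``); otherwise each eye gets one entry, or none with
    probability ``p_no_entry``.  Each entry samples a clean category from
    ``acuity_weights``, and the truth per eye is the best clean category
    (plus any adversarial competitors) before decoration.
    """
    config.validate()
    scale = AcuityScale.default()
    rng = random.Random(config.seed)
    labels = list(config.acuity_weights)
    weights = [config.acuity_weights[l] for l in labels]

    records: list[EncounterRecord] = []
    truths: list[TruthRecord] = []
    for i in range(config.n_notes):
        note_id = f"note{i:06d}"
        patient_id = f"pt{i:06d}"
        rec = EncounterRecord(note_id=note_id, patient_id=patient_id, entries=[])
        multi = rng.random() < config.p_multi
        for eye in EYES:
            if multi:
                hi = min(4, config.max_entries_per_eye)
                n_entries = rng.randint(2, hi)
                if n_entries == hi and rng.random() < 0.1:
                    n_entries = rng.randint(hi, config.max_entries_per_eye)
            else:
                n_entries = 0 if rng.random() < config.p_no_entry else 1
            planted: list[SnellenCategory] = []
            for _ in range(n_entries):
                cat = scale[rng.choices(labels, weights=weights, k=1)[0]]
                text, competitor = _render_entry(rng, cat, config, scale)
                planted.append(cat)
                if competitor is not None:
                    planted.append(competitor)
                rec.entries.append(
                    AcuityEntry(
                        note_id=note_id,
                        patient_id=patient_id,
                        eye=eye,
                        field_name=rng.choice(DISTANCE_FIELDS),
                        raw_text=text,
                    )
                )
            if rng.random() < config.p_near_entry:
                rec.entries.append(
                    AcuityEntry(
                        note_id=note_id,
                        patient_id=patient_id,
                        eye=eye,
                        field_name=rng.choice(NEAR_FIELDS),
                        raw_text=f"J{rng.randint(1, 16)}",
                    )
                )
            if rng.random() < config.p_unmappable:
                rec.entries.append(
                    AcuityEntry(
                        note_id=note_id,
                        patient_id=patient_id,
                        eye=eye,
                        field_name=rng.choice(DISTANCE_FIELDS),
                        raw_text=rng.choice(JUNK_PHRASES),
                    )
                )
            truths.append(
                TruthRecord(
                    note_id=note_id,
                    eye=eye,
                    true_bdva=scale.best_of(planted) if planted else None,
                )
            )
        records.append(rec)
    return records, truths


def truth_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    rows = [
        {"note_id": t.note_id, "eye": t.eye, "bdva": t.label} for t in truths
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_corpus(
    records: list[EncounterRecord],
    truths: list[TruthRecord],
    notes_path: str | Path,
    truth_path: str | Path,
) -> None:
    """Emit the encounters CSV (same dialect ``read_encounters`` accepts)
    and the truth CSV ``note_id,eye,bdva``."""
    write_encounters(records, notes_path)
    truth_frame(truths).to_csv(truth_path, index=False)
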