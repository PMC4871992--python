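# bdva — best documented visual acuity from ophthalmology EHR notes

Visual acuity is the vital sign of ophthalmology, yet in most electronic
health records it lives as *free text* inside structured per-eye fields:
a single encounter can record "20/100" with old glasses, "20/60 w/head
tilted down" through a pinhole, and "20/20 slow" after refraction — for the
same eye. Researchers doing patient-centered outcomes work (cataract
surgery, anti-VEGF response, diabetic retinopathy progression) need one
number per eye per visit.

`bdva` extracts the **best documented visual acuity (BDVA)**: the
best-ranked distance Snellen value recorded anywhere in an encounter's
defined acuity fields, per eye. (BDVA, not BCVA — best *corrected* acuity
is unknowable unless a refraction was actually performed that visit.)

## The algorithm

1. **Canonical scale.** A closed, totally ordered set of 17 categories:
   thirteen Snellen lines 20/10 … 20/400 plus the qualitative categories
   CF (counting fingers), HM (hand motion), LP (light perception), NLP
   (no light perception). Rank 1 = 20/10 is the best; every qualitative
   category ranks worse than every numeric one. Off-list denominators
   (e.g. 20/15) snap to the nearest scale line, ties toward worse vision.
2. **Two-stage normalization.** Each raw response is canonicalized
   (trim, case-fold, collapse whitespace, repair O-for-zero typos such as
   "2O/2O") and looked up in a curated **vocabulary** — an exact map from
   known responses to a scale label, `NEAR` (Jäger / print-size near-vision
   notation) or `UNMAPPED` ("not tested", pinhole "NI", …). The vocabulary
   is the gold standard; only on a miss does the **fallback scan** run,
   string-searching for `20/X` tokens (± line modifiers stripped) and
   qualitative keywords, keeping the best-ranked token found. No fuzzy
   matching, ever — an edit-distance "repair" could silently change a
   clinical value.
3. **Per-eye selection.** Among the distance-field candidates
   (uncorrected, corrected, pinhole, manifest/cycloplegic refraction,
   autorefraction; near-vision fields are parsed but excluded), BDVA(eye) =
   argmin rank. An eye with no mappable distance entry gets an explicit
   `NO_ACUITY` status.

The package also ships an **accuracy evaluator** (percentage agreement
against a per-eye gold standard, chart-review style) and a deterministic
**synthetic-note generator** with known ground truth, so the whole pipeline
is testable without any clinical data.

## Worked example

```python
from bdva import AcuityEntry, EncounterRecord, extract_bdva

visit = EncounterRecord("visit_a", "pt1", [
    AcuityEntry("visit_a", "pt1", "OD", "corrected", "20/100"),
    AcuityEntry("visit_a", "pt1", "OS", "corrected", "20/40"),
    AcuityEntry("visit_a", "pt1", "OD", "manifest_refraction", "20/60"),
    AcuityEntry("visit_a", "pt1", "OS", "manifest_refraction", "20/20"),
])
od, os_ = extract_bdva(visit)
print(od.bdva.label, od.rank, od.source_field)
print(os_.bdva.label, os_.rank, os_.source_field)
```

prints

```
20/60 7 manifest_refraction
20/20 2 manifest_refraction
```

i.e. for the right eye the refraction value 20/60 (rank 7 of 17) beats the
habitual-correction 20/100, and for the left eye 20/20 (rank 2) beats
20/40 — the refraction that day found the eye's true potential.

From the shell, the same pipeline over CSV files:

```bash
bdva simulate --n-notes 500 --seed 7 --output notes.csv --truth truth.csv
bdva extract  --input notes.csv --output bdva.csv --unmapped-report unmapped.csv
bdva evaluate --pred bdva.csv --gold truth.csv
```

The evaluate step on a generated corpus prints `overall accuracy: 100.0%`
— decorations (annotations, typos, modifiers, near-vision and junk
entries) are truth-preserving by construction, so any drop from 100% would
indicate an extraction defect.

Input CSVs are long format, one row per observation:
`note_id,patient_id,eye,field_name,response_text` with `eye` ∈ {OD, OS}
and `field_name` one of the eight structured acuity fields. A
`wide_to_long` converter is provided for one-column-per-(eye, field)
exports.

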