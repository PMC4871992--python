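# Methods

## Problem and model

A single ophthalmology encounter records distance visual acuity per eye in
up to eight structured fields (uncorrected, corrected, pinhole, manifest
refraction, cycloplegic refraction, autorefraction, and near vision with or
without correction), each holding *free text*. The quantity of interest for
research use is the best documented visual acuity (BDVA): the best value
recorded in any defined distance field for that eye in that encounter. BDVA
is deliberately not BCVA — best *corrected* acuity exists only when a
refraction was performed, so the documented optimum is the honest target
when abstracting notes.

The method is rule-based, not statistical: a fixed ordinal scale, an exact
curated vocabulary, a literal token scan, and a minimum over ranks. There
is nothing to fit and no randomness anywhere in extraction; for a fixed
vocabulary the pipeline is a pure function of its input.

## The scale

Seventeen categories: 20/10, 20/20, 20/25, 20/30, 20/40, 20/50, 20/60,
20/70, 20/80, 20/100, 20/125, 20/200, 20/400, then CF, HM, LP, NLP, with
consecutive integer ranks from 1 (best). Choices that were genuinely open:

- **Qualitative order CF < HM < LP < NLP**, all worse than 20/400. This is
  standard clinical semantics (CF is recorded when the largest optotype
  cannot be read; NLP is blindness), adopted here as the package's
  ordering decision.
- **CF/HM at different test distances collapse to one category.** The scale
  has a single CF entry; "CF @ 3ft" and "CF @ 5ft" both map to it.
- **Off-list denominators snap to the nearest on-scale denominator, ties
  toward the worse (larger) side.** So 20/15 → 20/20, 20/150 → 20/125,
  20/63 → 20/60. The tie rule is conservative: a snap never inflates
  vision. Snapping is idempotent on on-scale values.
- The scale ships as a versioned CSV resource (`label,denominator,rank`);
  a site can add 20/15 or metric lines without code changes, and the
  constructor re-validates all ordering invariants on load.

## Normalization

`canonicalize_text` trims, case-folds, collapses internal whitespace, and
repairs the letter O standing in for a zero — but only where the O touches
a digit or a digit-flanked slash ("2O/2O" → "20/20"; "room" is untouched).
The repair iterates to a fixed point so runs like "20/2OO" resolve fully.

The **vocabulary** is an exact map from canonicalized response to a scale
label, `NEAR`, or `UNMAPPED`, and always wins over the token scan: curated
human judgment outranks pattern matching, including adversarial cases where
a curated entry says a text is non-informative even though it contains a
token. A vocabulary *miss* is a distinct signal (not UNMAPPED) so the
caller knows to fall through. The shipped default vocabulary is a
**synthetic stand-in**: the curated tables built at clinical sites are
institution-specific and not public, so the default covers the canonical
labels, common qualitative spellings, Jäger/print-size near entries and
frequent non-informative responses, and sites are expected to grow their
own via the unmapped report (`raw_text,count`, descending), which is the
operational maintenance hook — every fallback hit and unmapped response is
also logged with its note id.

The **fallback scan** searches canonicalized text for:

- `20/<digits>` fractions, with an optional ± line modifier ("20/25+2",
  "20/30−1") stripped to the base line — the scale has no modifier entries,
  so stripping is the only representation-preserving choice; the hyphen is
  read as a modifier, not a range, per clinical convention. Denominators
  pass through the snapping rule.
- Qualitative keywords (cf / count(ing) fingers, hm / hand motion(s),
  lp / light perception, nlp / no light perception), longest phrase first
  so "no light perception" is claimed before "light perception" can match
  inside it.

When a field holds several tokens the **best-ranked token wins** (position
breaks exact-rank ties). This mirrors the encounter-level best-documented
semantics and is checked against a brute-force extract-all-tokens oracle.
A Jäger token (`j<digits>`) with no distance token present is reported as
NEAR rather than UNMAPPED — an auditability refinement so near-vision
entries missing from the vocabulary are still classified; it cannot affect
BDVA because near entries never compete. Fuzzy/edit-distance matching is
deliberately absent.

## Selection

Per eye: normalize every entry, discard NEAR/UNMAPPED/EMPTY, restrict to
distance fields, take the minimum rank. Near-vision fields are parsed and
carried for audit but excluded as candidates because the output scale is
distance Snellen. Absence is a first-class `NO_ACUITY` status, never a
sentinel category, so "notes with acuity present" denominators stay
honest. Unknown eye or field names are hard validation errors naming the
input row — silent inclusion could corrupt BDVA semantics.

When several fields tie at the best rank the *value* is unaffected; the
reported source field follows a fixed priority (manifest refraction >
cycloplegic refraction > pinhole > corrected > uncorrected >
autorefraction), reflecting measurement quality. The priority is
configurable (YAML config) and is reporting convenience only.
Autorefraction is included as a BDVA candidate since it is one of the
eight distance fields; a site that wants it display-only can drop it from
the field set.

## Accuracy evaluation

`evaluate_accuracy` mirrors a chart-review audit: per-eye gold labels
(`note_id,eye,bdva`; empty or `NO_ACUITY` = reviewer found none) are
compared with algorithm output on **category labels**, not ranks, and
right / left / overall percentage agreement plus the discordance list are
reported. Every gold eye must exist in the algorithm output; the result is
invariant to row order.

## Synthetic corpus

The generator emulates the documented structure of a real clinic's corpus,
since no such corpus is public:

| knob | default | emulates |
|---|---|---|
| `p_multi` | 0.54 | fraction of notes with >1 acuity per eye |
| `max_entries_per_eye` | 7 | observed 0–7 range |
| `acuity_weights` | 38.7% 20/20, 18.9% 20/25, ~86% ≤ 20/100 | value distribution |
| `p_annotation` | 0.35 | provider annotations ("20/20 slow", …) |
| `p_o_transposition` | 0.08 | O-for-zero typos |
| `p_modifier` | 0.15 | ± line modifiers |
| `p_near_entry` | 0.15 | extra Jäger entries in near fields |
| `p_unmappable` | 0.08 | token-free junk ("poor view") |
| `p_no_entry` | 0.05 | eyes with nothing recorded |

One `random.Random(seed)` stream drives everything; identical seed and
config give byte-identical output files. A single Bernoulli(`p_multi`)
draw per note gives *both* eyes 2+ entries, so the note-level multi-entry
fraction equals `p_multi` exactly and the binomial check against it is
well-posed. The annotation/junk phrase banks are token-free by
construction (property-tested), modifiers strip back to the planted line,
and O-typos are repaired by canonicalization — so every decoration is
truth-preserving and the generator doubles as an end-to-end oracle: truth
is the best clean category per eye, computed before corruption. An
adversarial mode (`p_competing` > 0) plants a second acuity token inside
an entry's text and recomputes truth over all planted tokens, exercising
the within-field best-token rule.

What the generator does **not** emulate: narrative acuities outside the
structured fields (history-of-present-illness text is out of scope for the
algorithm and was the dominant real-world error source), genuinely novel
response spellings beyond the modeled corruptions, correlated disease
structure between eyes or across visits, and demographics. Passing the
recovery tests therefore shows the pipeline is correct under the modeled
free-text hazards, not that any particular real corpus would be extracted
at a given accuracy — site-specific chart review remains necessary.

## Problem sizes and numerics

The test suite checks ranking equivalence against a brute-force pairwise
oracle on 10,000 random multisets, end-to-end recovery on a 5,000-note
(10,000-eye) decorated corpus, exact planted-discordance arithmetic, token
embedding recovery over 2,000 random annotations, and byte-level
determinism — sizes chosen to give the binomial and enumeration checks
real power while keeping the default suite fast. There is no floating
point anywhere in extraction; accuracy percentages are the only computed
reals, compared exactly (they are ratios of small integers times 100).

## Known limitations

- The default vocabulary is a stand-in; production use requires growing a
  site vocabulary from the unmapped report.
- Only the O/0 transposition is repaired; other misspellings ("20/2o0"
  resolves, "2O/2Q" does not) fall to the token scan or to UNMAPPED.
- Near-vision BDVA (Jäger/print) is recognized and excluded, not ranked.
- No logMAR/ETDRS/metric conversion; the scale is US Snellen feet.
- Pinhole "no improvement" contributes nothing rather than inheriting
  another field's value — there is no principled inheritance rule without
  site-specific review.
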