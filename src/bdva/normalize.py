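"""Free-text acuity normalization: curated vocabulary first, token scan second.

Acuity fields are free text: providers append observations to the measured
value ("20/20 slow", "20/60 w/head tilted down"), mistype the letter O for
a zero ("2O/2O"), add line modifiers ("20/25+2"), or record near-vision
notations (Jäger "J1", print sizes) that are not distance Snellen values.

Normalization is two-stage.  A curated vocabulary — an exact map from a
canonicalized raw string to a scale label, ``NEAR`` or ``UNMAPPED`` — is
consulted first and always wins.  Only on a vocabulary miss does the
fallback token scan run: it searches the text for ``20/X`` fractions and
qualitative keywords, snaps each denominator onto the scale, and keeps the
best-ranked token found.  Fuzzy matching is deliberately not used: an
edit-distance "repair" could silently change a clinical value.
"""

from __future__ import annotations

import csv
import io as _io
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .scale import AcuityScale, SnellenCategory


class NormalizationStatus(str, Enum):
    VOCAB_HIT = "VOCAB_HIT"
    FALLBACK_HIT = "FALLBACK_HIT"
    NEAR = "NEAR"
    UNMAPPED = "UNMAPPED"
    EMPTY = "EMPTY"


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of normalizing one raw response.

    ``category`` is present exactly when the status is VOCAB_HIT or
    FALLBACK_HIT.  ``matched_token`` records the substring that triggered a
    fallback (or near-pattern) hit, for audit.
    """

    status: NormalizationStatus
    category: Optional[SnellenCategory] = None
    matched_token: Optional[str] = None

    def __post_init__(self):
        has_cat = self.category is not None
        expects_cat = self.status in (
            NormalizationStatus.VOCAB_HIT,
            NormalizationStatus.FALLBACK_HIT,
        )
        if has_cat != expects_cat:
            raise ValueError(
                f"status {self.status} inconsistent with category={self.category}"
            )


# Special vocabulary targets that are not scale labels.
NEAR = "NEAR"
UNMAPPED = "UNMAPPED"

_WS = re.compile(r"\s+")
# The letter o standing in for a zero: adjacent to a digit, or adjacent to
# a slash whose far side is a digit (covers "2O/2O", "O/20", "20/4O").
_O_REPAIRS = (
    re.compile(r"(?<=\d)o"),
    re.compile(r"o(?=\d)"),
    re.compile(r"o(?=/\d)"),
    re.compile(r"(?<=\d/)o"),
)


def canonicalize_text(raw: str) -> str:
    """Trim, case-fold, collapse whitespace and repair O-for-zero typos.

    The O/0 repair is applied only where an ``o`` sits against a digit or a
    digit-flanked slash, and is iterated to a fixed point so runs such as
    ``"2oo/2oo"`` resolve fully.  Blank input returns the empty string.
    """
    text = _WS.sub(" ", raw.strip().casefold())
    while True:
        repaired = text
        for pat in _O_REPAIRS:
            repaired = pat.sub("0", repaired)
        if repaired == text:
            return text
        text = repaired


class VocabularyError(ValueError):
    """Invalid vocabulary file: duplicate keys or unknown targets."""


class AcuityVocabulary:
    """Curated exact map from canonicalized raw response to target label.

    Targets are scale labels, ``"NEAR"`` (a near-vision response such as a
    Jäger value) or ``"UNMAPPED"`` (curated as carrying no distance acuity,
    e.g. "not tested").  The vocabulary is the gold standard: when a raw
    string is present here, the fallback scan is never consulted.
    """

    def __init__(self, entries: dict[str, str], scale: AcuityScale | None = None):
        self.scale = scale or AcuityScale.default()
        canon: dict[str, str] = {}
        problems: list[str] = []
        for key, target in entries.items():
            ckey = canonicalize_text(key)
            if ckey in canon:
                problems.append(f"duplicate key after canonicalization: {ckey!r}")
                continue
            if target not in (NEAR, UNMAPPED) and target not in self.scale:
                problems.append(f"invalid target {target!r} for key {ckey!r}")
                continue
            canon[ckey] = target
        if problems:
            raise VocabularyError("; ".join(problems))
        self._entries = canon

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, raw: str) -> bool:
        return canonicalize_text(raw) in self._entries

    @property
    def entries(self) -> dict[str, str]:
        return dict(self._entries)

    @classmethod
    def from_csv(cls, path: str | Path, scale: AcuityScale | None = None):
        """Load a vocabulary CSV with header ``raw_text,target``.

        Validation reports duplicate keys and invalid targets with the
        offending line numbers.
        """
        with open(path, newline="", encoding="utf-8") as fh:
            return cls._from_reader(fh, str(path), scale)

    @classmethod
    def _from_reader(cls, fh, source: str, scale: AcuityScale | None):
        scale = scale or AcuityScale.default()
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["raw_text", "target"]:
            raise VocabularyError(
                f"{source}: expected header ['raw_text', 'target'], got {header}"
            )
        entries: dict[str, str] = {}
        problems: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                problems.append(f"{source}:{lineno}: expected 2 columns, got {len(row)}")
                continue
            key, target = canonicalize_text(row[0]), row[1].strip()
            if key in entries:
                problems.append(f"{source}:{lineno}: duplicate key {key!r}")
                continue
            if target not in (NEAR, UNMAPPED) and target not in scale:
                problems.append(f"{source}:{lineno}: invalid target {target!r}")
                continue
            entries[key] = target
        if problems:
            raise VocabularyError("; ".join(problems))
        return cls(entries, scale)

    @classmethod
    def default(cls, scale: AcuityScale | None = None) -> "AcuityVocabulary":
        """The stand-in vocabulary shipped with the package.

        The original curated table (built from one institution's corpus) is
        not public; this synthetic default covers the canonical labels,
        common qualitative spellings, Jäger/print-size near entries and
        frequent non-informative responses.
        """
        text = (
            resources.files("bdva.data")
            .joinpath("default_vocab.csv")
            .read_text(encoding="utf-8")
        )
        return cls._from_reader(_io.StringIO(text), "packaged vocabulary", scale)

    def lookup(self, raw: str) -> Optional[NormalizationResult]:
        """Exact lookup on canonicalized text; ``None`` on a miss.

        A miss is deliberately distinct from UNMAPPED so the caller knows to
        proceed to the fallback scan.
        """
        target = self._entries.get(canonicalize_text(raw))
        if target is None:
            return None
        if target == NEAR:
            return NormalizationResult(NormalizationStatus.NEAR)
        if target == UNMAPPED:
            return NormalizationResult(NormalizationStatus.UNMAPPED)
        return NormalizationResult(
            NormalizationStatus.VOCAB_HIT, category=self.scale[target]
        )


# -- fallback token scan ---------------------------------------------------

# 20/X with an optional ±line modifier ("20/25+2", "20/30-1", unicode minus
# included) stripped to the base line.
_NUMERIC_TOKEN = re.compile(r"(?<!\d)20\s*/\s*(\d+)(?:\s*[+\-−]\s*\d)?")
_JAGER_TOKEN = re.compile(r"\bj\s*\d+\b")

# Qualitative keywords, longest phrase first so "no light perception" is
# claimed before "light perception" can match inside it.
_QUALITATIVE_TOKENS: tuple[tuple[re.Pattern, str], ...] = (
    (re.compile(r"\bno light perception\b"), "NLP"),
    (re.compile(r"\bnlp\b"), "NLP"),
    (re.compile(r"\blight perception\b"), "LP"),
    (re.compile(r"\blp\b"), "LP"),
    (re.compile(r"\bcount(?:ing)? fingers\b"), "CF"),
    (re.compile(r"\bcf\b"), "CF"),
    (re.compile(r"\bhand motions?\b"), "HM"),
    (re.compile(r"\bhm\b"), "HM"),
)


def _scan_tokens(text: str, scale: AcuityScale) -> list[tuple[SnellenCategory, str, int]]:
    """All acuity tokens in canonicalized text as (category, substring, pos)."""
    found: list[tuple[SnellenCategory, str, int]] = []
    claimed: list[tuple[int, int]] = []

    def free(span: tuple[int, int]) -> bool:
        return all(span[1] <= s or span[0] >= e for s, e in claimed)

    for pat, label in _QUALITATIVE_TOKENS:
        for m in pat.finditer(text):
            if free(m.span()):
                claimed.append(m.span())
                found.append((scale[label], m.group(0), m.start()))
    for m in _NUMERIC_TOKEN.finditer(text):
        if free(m.span()):
            claimed.append(m.span())
            found.append((scale.snap_to_scale(int(m.group(1))), m.group(0), m.start()))
    return found


def fallback_scan(raw: str, scale: AcuityScale | None = None) -> NormalizationResult:
    """String-search for known acuities in text the vocabulary missed.

    Scans the canonicalized text for ``20/X`` fractions (line modifiers
    stripped, denominators snapped onto the scale) and qualitative keywords.
    When several tokens occur in one field the best-ranked one wins,
    matching the encounter-level "best documented" semantics; position in
    the text breaks exact rank ties.  A Jäger token with no distance token
    present is reported as NEAR; otherwise a token-free text is UNMAPPED
    (EMPTY for blank input).
    """
    scale = scale or AcuityScale.default()
    text = canonicalize_text(raw)
    if not text:
        return NormalizationResult(NormalizationStatus.EMPTY)
    tokens = _scan_tokens(text, scale)
    if tokens:
        cat, tok, _ = min(tokens, key=lambda t: (t[0].rank, t[2]))
        return NormalizationResult(
            NormalizationStatus.FALLBACK_HIT, category=cat, matched_token=tok
        )
    near = _JAGER_TOKEN.search(text)
    if near:
        return NormalizationResult(
            NormalizationStatus.NEAR, matched_token=near.group(0)
        )
    return NormalizationResult(NormalizationStatus.UNMAPPED)


def normalize(raw: str, vocab: AcuityVocabulary | None = None) -> NormalizationResult:
    """Normalize one raw response: vocabulary stage, then fallback stage.

    Deterministic for a fixed vocabulary.  Blank input is EMPTY.
    """
    vocab = vocab or AcuityVocabulary.default()
    if not canonicalize_text(raw):
        return NormalizationResult(NormalizationStatus.EMPTY)
    hit = vocab.lookup(raw)
    if hit is not None:
        return hit
    return fallback_scan(raw, vocab.scale)


def unmapped_report(entries: Iterable) -> pd.DataFrame:
    """Tally UNMAPPED raw texts for vocabulary maintenance.

    New free-text responses keep appearing for as long as providers can
    type; this report is the curation hook.  Returns a DataFrame with
    columns ``raw_text`` and ``count``, descending by count, ties broken
    lexicographically.
    """
    counts: dict[str, int] = {}
    for entry in entries:
        result = getattr(entry, "normalization", None)
        if result is not None and result.status is NormalizationStatus.UNMAPPED:
            counts[entry.raw_text] = counts.get(entry.raw_text, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["raw_text", "count"])
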