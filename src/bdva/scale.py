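"""Canonical Snellen acuity scale and its best-to-worst total order.

Distance visual acuity is recorded either as a Snellen fraction ``20/X``
(the patient reads at 20 ft what a normal-sighted eye reads at X ft, so a
larger denominator means worse vision) or, below the range of the chart, as
one of four qualitative categories: CF (counting fingers), HM (hand
motion), LP (light perception) and NLP (no light perception).

The :class:`AcuityScale` fixes a closed, totally ordered category set:
13 numeric steps from 20/10 down to 20/400 followed by CF < HM < LP < NLP,
each with an integer rank where rank 1 is the best vision.  Every
comparison elsewhere in the package — picking the best token inside one
free-text field, or the best documented acuity across an encounter — is a
minimum over these ranks.

The default scale ships as a plain CSV resource (``data/snellen_scale.csv``)
so a site can extend it (for example add 20/15) without code changes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Union


class ScaleMembershipError(KeyError):
    """Raised when a category or label is not part of the scale."""


@dataclass(frozen=True)
class SnellenCategory:
    """One canonical acuity value.

    Parameters
    ----------
    label : str
        Canonical display string, e.g. ``"20/40"`` or ``"CF"``.
    rank : int
        Position in the best-to-worst order; 1 is the best vision.
    denominator : int, optional
        Snellen denominator in feet for numeric categories; ``None`` for
        the qualitative categories.
    """

    label: str
    rank: int
    denominator: int | None = None

    @property
    def is_numeric(self) -> bool:
        return self.denominator is not None

    def __str__(self) -> str:  # pragma: no cover - display convenience
        return self.label


CategoryLike = Union[SnellenCategory, str]


class AcuityScale:
    """Ordered collection of :class:`SnellenCategory`, best first.

    Invariants enforced at construction: unique labels; ranks unique and
    consecutive from 1; numeric categories ordered by denominator; every
    qualitative category ranked worse than every numeric one.
    """

    def __init__(self, categories: Iterable[SnellenCategory]):
        cats = sorted(categories, key=lambda c: c.rank)
        if not cats:
            raise ValueError("scale must contain at least one category")
        if [c.rank for c in cats] != list(range(1, len(cats) + 1)):
            raise ValueError("ranks must be unique and consecutive from 1")
        labels = [c.label for c in cats]
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        numeric = [c for c in cats if c.is_numeric]
        for a, b in zip(numeric, numeric[1:]):
            if not a.denominator < b.denominator:
                raise ValueError(
                    "numeric categories must be ordered by denominator"
                )
        if numeric and any(
            (not c.is_numeric) and c.rank < numeric[-1].rank for c in cats
        ):
            raise ValueError("qualitative categories must rank below numeric ones")
        self._categories: tuple[SnellenCategory, ...] = tuple(cats)
        self._by_label = {c.label: c for c in cats}
        self._by_denominator = {c.denominator: c for c in numeric}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "AcuityScale":
        """Load a scale from a CSV with header ``label,denominator,rank``."""
        with open(path, newline="", encoding="utf-8") as fh:
            return cls._from_reader(csv.DictReader(fh), str(path))

    @classmethod
    def _from_reader(cls, reader: csv.DictReader, source: str) -> "AcuityScale":
        expected = ["label", "denominator", "rank"]
        if reader.fieldnames != expected:
            raise ValueError(
                f"{source}: expected header {expected}, got {reader.fieldnames}"
            )
        cats = []
        for row in reader:
            denom = row["denominator"].strip()
            cats.append(
                SnellenCategory(
                    label=row["label"].strip(),
                    rank=int(row["rank"]),
                    denominator=int(denom) if denom else None,
                )
            )
        return cls(cats)

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "AcuityScale":
        """The canonical 17-category scale shipped with the package."""
        text = (
            resources.files("bdva.data")
            .joinpath("snellen_scale.csv")
            .read_text(encoding="utf-8")
        )
        return cls._from_reader(csv.DictReader(text.splitlines()), "packaged scale")

    # -- access ------------------------------------------------------------

    def __iter__(self) -> Iterator[SnellenCategory]:
        return iter(self._categories)

    def __len__(self) -> int:
        return len(self._categories)

    def __contains__(self, item: CategoryLike) -> bool:
        label = item.label if isinstance(item, SnellenCategory) else item
        return label in self._by_label

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self._categories)

    @property
    def numeric_denominators(self) -> tuple[int, ...]:
        return tuple(sorted(self._by_denominator))

    def __getitem__(self, label: str) -> SnellenCategory:
        try:
            return self._by_label[label]
        except KeyError:
            raise ScaleMembershipError(f"unknown acuity category: {label!r}") from None

    def _resolve(self, category: CategoryLike) -> SnellenCategory:
        if isinstance(category, SnellenCategory):
            if self._by_label.get(category.label) != category:
                raise ScaleMembershipError(
                    f"category {category.label!r} does not belong to this scale"
                )
            return category
        return self[category]

    # -- operations --------------------------------------------------------

    def rank_of(self, category: CategoryLike) -> int:
        """Rank of a scale member (1 = best vision)."""
        return self._resolve(category).rank

    def best_of(self, categories: Iterable[CategoryLike]) -> SnellenCategory:
        """Member of ``categories`` with the best (minimal) rank.

        Duplicates are allowed and the result is invariant under permutation
        and duplication.  An empty collection is an error: callers must
        handle "no acuity recorded" before comparing.
        """
        resolved = [self._resolve(c) for c in categories]
        if not resolved:
            raise ValueError("best_of requires at least one category")
        return min(resolved, key=lambda c: c.rank)

    def snap_to_scale(self, denominator: int) -> SnellenCategory:
        """Map a Snellen denominator onto the scale.

        On-scale denominators return their category unchanged.  Off-list
        denominators (e.g. 20/15 entered at a site using a finer chart)
        snap to the nearest on-scale denominator; a tie is broken toward
        the worse (larger) denominator so a snap never inflates vision.
        """
        if denominator <= 0:
            raise ValueError(f"denominator must be positive, got {denominator}")
        hit = self._by_denominator.get(denominator)
        if hit is not None:
            return hit
        best = min(
            self._by_denominator.values(),
            key=lambda c: (abs(c.denominator - denominator), -c.denominator),
        )
        return best
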