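"""Coding-sheet containers and membership-table builders.

Two raters independently classify ``N_u`` coding units (photographs,
sentences, map pixels, ...) against a shared set of ``N_c`` categories.
This module holds the containers for the two coding-sheet layouts —
one-to-one two-tier sheets (:class:`CrispSheet`) and one-to-many ranked
sheets (:class:`RankedSheet`) — plus the :class:`MembershipTable` matrix
of membership grades that every agreement index consumes, and the
schemes that turn sheets into membership tables:

* :func:`one_hot` — crisp one-to-one coding (each row a single 1);
* :func:`equal_split` — ranked selections with equal weight 1/k;
* :func:`rank_weighted` — ranked selections with descending weights,
  truncated per unit and normalized to sum 1;
* :func:`expand_two_tier` — a D-dimension one-to-one sheet expanded to
  the concatenated second-tier category set, grade 1/D per dimension;
* :func:`membership_table` — pass-through for externally supplied
  grades (e.g. database relevance percentages rescaled to [0, 1]).

Builders emit exact repeated values (the same float for every 1/k or
w_r/Σw) so that downstream level tallies never split by floating noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ROW_SUM_TOL",
    "CodingError",
    "MembershipWarning",
    "CategorySet",
    "DimensionScheme",
    "CrispSheet",
    "RankedSheet",
    "MembershipTable",
    "one_hot",
    "equal_split",
    "rank_weighted",
    "expand_two_tier",
    "first_selection_only",
    "membership_table",
]

#: Tolerance on |row sum - 1| below which a row counts as normalized.
ROW_SUM_TOL = 1e-9


class CodingError(ValueError):
    """Invalid coding data (unknown label, malformed sheet, misalignment)."""


class MembershipWarning(UserWarning):
    """Non-fatal irregularity in membership grades (e.g. row sums above 1)."""


class CategorySet:
    """Ordered, duplicate-free set of category labels.

    The order is fixed and shared by both raters in one analysis, so the
    two raters' membership tables align column-wise.
    """

    __slots__ = ("labels", "_index")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(lab) for lab in labels)
        if len(labels) < 2:
            raise CodingError(f"need at least 2 categories, got {len(labels)}")
        if len(set(labels)) != len(labels):
            seen: set[str] = set()
            dup = next(lab for lab in labels if lab in seen or seen.add(lab))
            raise CodingError(f"duplicate category label {dup!r}")
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise CodingError(f"unknown category label {label!r}") from None

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __getitem__(self, i: int) -> str:
        return self.labels[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CategorySet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"CategorySet({list(self.labels)!r})"


@dataclass(frozen=True)
class DimensionScheme:
    """Two-tier category system: first-tier dimensions, second-tier levels.

    Each dimension (variable) carries an ordered list of level labels whose
    first entry is conventionally the "not present" level (integer code 0 in
    one-to-one sheets). The expanded category set used by fuzzy indices is
    the concatenation of all levels of all dimensions.
    """

    dimensions: tuple[tuple[str, tuple[str, ...]], ...]

    def __init__(self, dimensions: Iterable[tuple[str, Sequence[str]]]):
        dims = tuple((str(name), tuple(str(v) for v in levels))
                     for name, levels in dimensions)
        if not dims:
            raise CodingError("scheme needs at least one dimension")
        names = [name for name, _ in dims]
        if len(set(names)) != len(names):
            raise CodingError("dimension names must be unique")
        for name, levels in dims:
            if len(levels) < 2:
                raise CodingError(f"dimension {name!r} needs >= 2 levels")
            if len(set(levels)) != len(levels):
                raise CodingError(f"dimension {name!r} has duplicate levels")
        object.__setattr__(self, "dimensions", dims)

    @classmethod
    def from_level_counts(cls, names: Sequence[str],
                          counts: Sequence[int]) -> "DimensionScheme":
        """Build a scheme whose levels are the integer codes 0..k-1."""
        if len(names) != len(counts):
            raise CodingError("names and counts differ in length")
        return cls((n, tuple(str(i) for i in range(k)))
                   for n, k in zip(names, counts))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.dimensions)

    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    def n_levels(self, d: int) -> int:
        return len(self.dimensions[d][1])

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(len(levels) for _, levels in self.dimensions)

    @property
    def offsets(self) -> tuple[int, ...]:
        """Starting column of each dimension in the expanded category set."""
        out, pos = [], 0
        for _, levels in self.dimensions:
            out.append(pos)
            pos += len(levels)
        return tuple(out)

    def expanded_categories(self) -> CategorySet:
        """All second-tier levels as primary categories, ``dim:level``."""
        return CategorySet(f"{name}:{lev}"
                           for name, levels in self.dimensions
                           for lev in levels)


@dataclass(frozen=True, eq=False)
class CrispSheet:
    """One-to-one two-tier coding sheet: one integer code per dimension.

    ``codes[i, d]`` is the level index the rater chose for unit *i* on
    dimension *d*; code 0 is the "not present" level.
    """

    unit_ids: tuple[str, ...]
    codes: np.ndarray

    def __init__(self, unit_ids: Iterable[str], codes):
        ids = tuple(str(u) for u in unit_ids)
        if len(set(ids)) != len(ids):
            raise CodingError("duplicate unit ids in crisp sheet")
        arr = np.asarray(codes)
        if not np.issubdtype(arr.dtype, np.integer):
            raise CodingError("crisp codes must be integers")
        if arr.ndim != 2 or arr.shape[0] != len(ids):
            raise CodingError(
                f"codes must be (n_units, n_dimensions), got {arr.shape}")
        if (arr < 0).any():
            raise CodingError("crisp codes must be non-negative")
        object.__setattr__(self, "unit_ids", ids)
        object.__setattr__(self, "codes", arr)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def validate_against(self, scheme: DimensionScheme) -> None:
        if self.codes.shape[1] != scheme.n_dimensions:
            raise CodingError(
                f"sheet has {self.codes.shape[1]} dimensions, "
                f"scheme has {scheme.n_dimensions}")
        for d, (name, levels) in enumerate(scheme.dimensions):
            bad = np.nonzero(self.codes[:, d] >= len(levels))[0]
            if bad.size:
                i = int(bad[0])
                raise CodingError(
                    f"unit {self.unit_ids[i]!r}, dimension {name!r}: "
                    f"code {int(self.codes[i, d])} outside 0..{len(levels) - 1}")


@dataclass(frozen=True, eq=False)
class RankedSheet:
    """One-to-many coding sheet: per unit, an ordered list of categories.

    Rank 1 (list head) is the most salient selection. Categories may not
    repeat within a unit and every unit selects at least one.
    """

    unit_ids: tuple[str, ...]
    selections: tuple[tuple[str, ...], ...]

    def __init__(self, unit_ids: Iterable[str],
                 selections: Iterable[Sequence[str]]):
        ids = tuple(str(u) for u in unit_ids)
        sels = tuple(tuple(str(c) for c in row) for row in selections)
        if len(set(ids)) != len(ids):
            raise CodingError("duplicate unit ids in ranked sheet")
        if len(sels) != len(ids):
            raise CodingError("unit_ids and selections differ in length")
        for uid, row in zip(ids, sels):
            if not row:
                raise CodingError(f"unit {uid!r} has no selections")
            if len(set(row)) != len(row):
                raise CodingError(f"unit {uid!r} repeats a category")
        object.__setattr__(self, "unit_ids", ids)
        object.__setattr__(self, "selections", sels)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def max_selections(self) -> int:
        return max(len(row) for row in self.selections)

    def validate_against(self, categories: CategorySet) -> None:
        for uid, row in zip(self.unit_ids, self.selections):
            for lab in row:
                if lab not in categories:
                    raise CodingError(
                        f"unit {uid!r}: unknown category label {lab!r}")


class MembershipTable:
    """``N_u x N_c`` matrix of membership grades mu_j(u_i) in [0, 1].

    One table per rater; ``values[i, j]`` is the rater's confidence that
    unit *i* belongs to category *j*. ``row_normalized`` records whether
    every row sums to 1 (within :data:`ROW_SUM_TOL`) — true for all
    builders in this module except the raw pass-through.
    """

    __slots__ = ("unit_ids", "categories", "values", "row_normalized")

    def __init__(self, unit_ids: Iterable[str], categories: CategorySet,
                 values, *, validate: bool = True):
        ids = tuple(str(u) for u in unit_ids)
        arr = np.asarray(values, dtype=float)
        if validate:
            if arr.ndim != 2 or arr.shape != (len(ids), len(categories)):
                raise CodingError(
                    f"values must be ({len(ids)}, {len(categories)}), "
                    f"got {arr.shape}")
            if len(set(ids)) != len(ids):
                raise CodingError("duplicate unit ids in membership table")
            if not np.isfinite(arr).all():
                raise CodingError("membership grades must be finite")
            if (arr < 0).any() or (arr > 1).any():
                raise CodingError("membership grades must lie in [0, 1]")
        self.unit_ids = ids
        self.categories = categories
        self.values = arr
        sums = arr.sum(axis=1)
        self.row_normalized = bool(
            np.all(np.abs(sums - 1.0) <= ROW_SUM_TOL))

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def is_one_hot(self) -> bool:
        """True when every row is exactly one 1 and zeros elsewhere."""
        v = self.values
        binary = np.logical_or(v == 0.0, v == 1.0).all()
        return bool(binary and (v.sum(axis=1) == 1.0).all())

    def check_aligned(self, other: "MembershipTable") -> None:
        """Raise unless both tables cover the same units and categories."""
        if self.categories != other.categories:
            raise CodingError("membership tables use different category sets")
        if self.unit_ids != other.unit_ids:
            raise CodingError(
                "membership tables cover different units or unit order")

    def subset(self, indices) -> "MembershipTable":
        """Row subset / resample. Unit ids are kept positional (the original
        id tuple is reused) because resampling with replacement duplicates
        units; pairing across raters is by row position."""
        return MembershipTable(self.unit_ids, self.categories,
                               self.values[indices], validate=False)

    def argmax_labels(self) -> list[str]:
        """Label of the highest-grade category per unit (ties: first)."""
        return [self.categories[j] for j in self.values.argmax(axis=1)]

    def __repr__(self) -> str:
        return (f"<MembershipTable {self.n_units} units x "
                f"{self.n_categories} categories, "
                f"row_normalized={self.row_normalized}>")


def _default_ids(n: int) -> list[str]:
    return [str(i + 1) for i in range(n)]


def one_hot(labels: Sequence[str], categories: CategorySet,
            unit_ids: Sequence[str] | None = None) -> MembershipTable:
    """Crisp one-to-one coding: each row has a single 1 at the chosen label.

    Parameters
    ----------
    labels : per-unit single category labels, in unit order.
    categories : shared category set defining the column order.
    unit_ids : optional identifiers; defaults to "1".."n".
    """
    ids = list(unit_ids) if unit_ids is not None else _default_ids(len(labels))
    if len(ids) != len(labels):
        raise CodingError("unit_ids and labels differ in length")
    values = np.zeros((len(labels), len(categories)))
    for i, (uid, lab) in enumerate(zip(ids, labels)):
        if lab not in categories:
            raise CodingError(f"unit {uid!r}: unknown category label {lab!r}")
        values[i, categories.index(lab)] = 1.0
    return MembershipTable(ids, categories, values)


def equal_split(sheet: RankedSheet, categories: CategorySet) -> MembershipTable:
    """Equal-weight scheme: a unit with k selections gets grade 1/k on each.

    Rank order is ignored; a single selection reduces to :func:`one_hot`.
    """
    sheet.validate_against(categories)
    values = np.zeros((sheet.n_units, len(categories)))
    for i, row in enumerate(sheet.selections):
        grade = 1.0 / len(row)
        for lab in row:
            values[i, categories.index(lab)] = grade
    return MembershipTable(sheet.unit_ids, categories, values)


def rank_weighted(sheet: RankedSheet, categories: CategorySet,
                  weights: Sequence[float]) -> MembershipTable:
    """Descending-weight scheme: rank r gets w_r / sum(w_1..w_k).

    The weight vector is truncated to each unit's selection count k and
    renormalized, so every row sums to 1 and the weighted index stays on
    the same scale as the equal-split one. Constant weights reproduce
    :func:`equal_split` exactly.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise CodingError("weights must be a non-empty 1-d sequence")
    if (w <= 0).any():
        raise CodingError("weights must be strictly positive")
    if (np.diff(w) > 0).any():
        raise CodingError("weights must be non-increasing")
    if w.size < sheet.max_selections:
        raise CodingError(
            f"{w.size} weights for up to {sheet.max_selections} selections")
    sheet.validate_against(categories)
    values = np.zeros((sheet.n_units, len(categories)))
    for i, row in enumerate(sheet.selections):
        trunc = w[: len(row)]
        norm = trunc / trunc.sum()
        for lab, grade in zip(row, norm):
            values[i, categories.index(lab)] = grade
    return MembershipTable(sheet.unit_ids, categories, values)


def expand_two_tier(sheet: CrispSheet,
                    scheme: DimensionScheme) -> MembershipTable:
    """Expand a two-tier one-to-one sheet over the concatenated level set.

    The second-tier levels of all D dimensions (including the "not
    present" level of each) become the primary categories; every unit
    holds grade 1/D on the chosen level of each dimension. With D = 1
    this is :func:`one_hot` over that dimension's levels.
    """
    sheet.validate_against(scheme)
    cats = scheme.expanded_categories()
    offs = scheme.offsets
    d = scheme.n_dimensions
    values = np.zeros((sheet.n_units, len(cats)))
    grade = 1.0 / d
    for j, off in enumerate(offs):
        values[np.arange(sheet.n_units), off + sheet.codes[:, j]] = grade
    return MembershipTable(sheet.unit_ids, cats, values)


def first_selection_only(sheet: RankedSheet) -> list[str]:
    """Rank-1 selection per unit — the "forced single choice" scenario.

    The returned labels feed :func:`one_hot` and the crisp indices,
    answering what agreement would have been under a one-to-one protocol.
    """
    return [row[0] for row in sheet.selections]


def membership_table(unit_ids: Sequence[str], categories: CategorySet,
                     values) -> MembershipTable:
    """Pass-through for externally supplied membership grades.

    Row sums are not constrained (a unit may fully belong to several
    categories); a :class:`MembershipWarning` is recorded when any row
    exceeds sum 1, since some agreement values may then leave [0, 1].
    """
    table = MembershipTable(unit_ids, categories, values)
    sums = table.values.sum(axis=1)
    if (sums > 1.0 + ROW_SUM_TOL).any():
        n_over = int((sums > 1.0 + ROW_SUM_TOL).sum())
        warnings.warn(
            f"{n_over} unit(s) have membership grades summing above 1; "
            "agreement proportions may exceed 1",
            MembershipWarning, stacklevel=2)
    return table
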