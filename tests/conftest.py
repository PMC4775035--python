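"""Shared fixtures: published worked examples and random-table factories."""

from __future__ import annotations

import numpy as np
import pytest

from fuzzykappa import (
    CategorySet,
    CrispSheet,
    DimensionScheme,
    MembershipTable,
    RankedSheet,
    default_categories,
    one_hot,
)

# Two-tier scheme of the Russia photograph study: nine first-tier
# dimensions whose second-tier level counts (incl. "not present") sum to 30.
DIMENSION_NAMES = ("PEOPLE", "NATURE LAND", "PLACE", "SPACE", "TRANS/INF",
                   "ACTIV", "SEASON", "ARCHIT", "HERIT")
LEVEL_COUNTS = (5, 2, 3, 4, 2, 5, 3, 2, 4)

# One coder's published one-to-one sheet fragment (unit id, 9 level codes).
TABLE2_ROWS = [
    ("1001", (2, 0, 1, 2, 0, 1, 2, 0, 0)),
    ("1002", (0, 0, 2, 2, 0, 0, 2, 1, 0)),
    ("1003", (0, 0, 0, 0, 0, 0, 0, 1, 0)),
    ("1004", (3, 0, 1, 1, 0, 1, 2, 0, 2)),
    ("1005", (0, 0, 0, 0, 0, 0, 0, 1, 0)),
    ("1006", (0, 0, 1, 2, 0, 0, 0, 0, 0)),
    ("1007", (2, 0, 1, 1, 0, 1, 2, 1, 0)),
]

# Peru-style one-to-many sheet fragment: ranked category abbreviations.
TABLE3_ROWS = [
    ("63", ("WL", "FL")),
    ("70", ("PP", "TC", "FR")),
    ("71", ("NL", "PP", "OA")),
    ("72", ("A",)),
    ("114", ("NL", "PP", "OA", "TF")),
    ("135", ("DA", "NL")),
]

# 20 short category codes, covering every abbreviation used above.
PERU_LABELS = ("NL", "PP", "AS", "WOL", "TC", "OA", "A", "WL", "AO", "TF",
               "FL", "FR", "DA", "MK", "RE", "SP", "TR", "UR", "VI", "CU")


@pytest.fixture
def example1_scheme() -> DimensionScheme:
    return DimensionScheme.from_level_counts(DIMENSION_NAMES, LEVEL_COUNTS)


@pytest.fixture
def table2_sheet() -> CrispSheet:
    ids = [uid for uid, _ in TABLE2_ROWS]
    codes = np.array([codes for _, codes in TABLE2_ROWS], dtype=int)
    return CrispSheet(ids, codes)


@pytest.fixture
def peru_categories() -> CategorySet:
    return CategorySet(PERU_LABELS)


@pytest.fixture
def table3_sheet() -> RankedSheet:
    return RankedSheet([uid for uid, _ in TABLE3_ROWS],
                       [sel for _, sel in TABLE3_ROWS])


def random_one_hot_pair(rng: np.random.Generator, n_units: int,
                        n_categories: int):
    """Two independent one-hot tables over the same category set."""
    cats = default_categories(n_categories)
    ids = [str(i) for i in range(n_units)]
    make = lambda: one_hot(
        [cats[j] for j in rng.integers(0, n_categories, n_units)], cats, ids)
    return make(), make()


def random_membership_pair(rng: np.random.Generator, n_units: int,
                           n_categories: int, normalized: bool = True):
    """Two random graded tables; rows normalized to sum 1 by default.

    Half-sparse rows with repeated exact levels exercise the level-tally
    path the fuzzy expected agreement depends on.
    """
    cats = default_categories(n_categories)
    ids = [str(i) for i in range(n_units)]

    def make():
        values = np.zeros((n_units, n_categories))
        for i in range(n_units):
            k = int(rng.integers(1, min(4, n_categories) + 1))
            cols = rng.choice(n_categories, size=k, replace=False)
            if rng.random() < 0.5:
                values[i, cols] = 1.0 / k  # exact repeated level
            else:
                raw = rng.random(k) + 0.05
                values[i, cols] = raw / raw.sum() if normalized else \
                    np.clip(raw, 0.0, 1.0)
        return MembershipTable(ids, cats, values)

    return make(), make()


# ---------------------------------------------------------------------------
# Independent brute-force oracles (never share code with the implementation).

def brute_observed_crisp(m1, m2) -> float:
    """Row-by-row match count over units."""
    hits = 0
    for r1, r2 in zip(m1.values, m2.values):
        if list(r1) == list(r2):
            hits += 1
    return hits / len(m1.values)


def brute_expected_crisp(m1, m2) -> float:
    """Sum of products of empirical marginals, category by category."""
    n = len(m1.values)
    total = 0.0
    for j in range(m1.values.shape[1]):
        total += (sum(m1.values[:, j]) / n) * (sum(m2.values[:, j]) / n)
    return total


def _t(name, a, b):
    if name == "min":
        return min(a, b)
    if name == "product":
        return a * b
    return max(0.0, a + b - 1.0)


def brute_fuzzy_observed(m1, m2, tnorm: str) -> float:
    """Plain double loop over units and categories."""
    n, nc = m1.values.shape
    total = 0.0
    for i in range(n):
        for j in range(nc):
            total += _t(tnorm, m1.values[i, j], m2.values[i, j])
    return total / n


def brute_fuzzy_expected(m1, m2, tnorm: str) -> float:
    """Triple loop over categories and both raters' level tallies."""
    n, nc = m1.values.shape
    total = 0.0
    for j in range(nc):
        tally1: dict[float, int] = {}
        tally2: dict[float, int] = {}
        for i in range(n):
            tally1[m1.values[i, j]] = tally1.get(m1.values[i, j], 0) + 1
            tally2[m2.values[i, j]] = tally2.get(m2.values[i, j], 0) + 1
        for v1, c1 in tally1.items():
            for v2, c2 in tally2.items():
                total += (c1 / n) * (c2 / n) * _t(tnorm, v1, v2)
    return total
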