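"""Fuzzy agreement indices for one-to-many (soft) classification.

When raters grade each unit's membership in several categories instead
of picking exactly one, partial overlap between their selections still
carries agreement. The row scalar product of the crisp observed
agreement generalizes to a t-norm ``T`` (a commutative, monotone binary
operation on [0, 1] with identity 1 — the fuzzy intersection):

    P_o = (1/N_u) sum_i sum_j T(mu1_ij, mu2_ij)

Chance agreement generalizes the product of marginals to a sum over each
rater's empirical distribution of membership *levels* per category:

    P_E = sum_j sum_{v1} sum_{v2} P1_j(v1) P2_j(v2) T(v1, v2)

where ``P_r_j(v)`` is the fraction of units in which rater *r* gave
category *j* the grade *v* (level 0 included). On one-hot tables the
levels are {0, 1} and both expressions collapse to the crisp formulas,
so fuzzy kappa equals Cohen's kappa exactly in the one-to-one limit —
for any of the three standard t-norms (min, product, Lukasiewicz).

Fuzzy pi applies the same construction with the two raters' level
distributions pooled, mirroring Scott's pi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .coding import CategorySet, CodingError, MembershipTable, MembershipWarning
from .crisp import KappaResult, kappa_from_agreements

__all__ = [
    "TNorm",
    "T_NORMS",
    "as_tnorm",
    "t_norm",
    "LevelDistribution",
    "level_distribution",
    "pooled_level_distribution",
    "fuzzy_observed",
    "fuzzy_expected",
    "fuzzy_kappa",
    "fuzzy_pi",
    "two_tier_integrated",
]


@dataclass(frozen=True)
class TNorm:
    """Named t-norm: the generalized intersection on membership grades."""

    name: str
    fn: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def __call__(self, a, b):
        return self.fn(a, b)


def _luka(a, b):
    return np.maximum(0.0, np.asarray(a) + np.asarray(b) - 1.0)


#: The three standard candidates; ``min`` is the default, following the
#: recommendation established for fuzzy-kappa work in image classification.
T_NORMS: dict[str, TNorm] = {
    "min": TNorm("min", np.minimum),
    "product": TNorm("product", np.multiply),
    "luka": TNorm("luka", _luka),
}

TNormLike = Union[str, TNorm]


def as_tnorm(spec: TNormLike) -> TNorm:
    if isinstance(spec, TNorm):
        return spec
    try:
        return T_NORMS[spec]
    except KeyError:
        raise CodingError(
            f"unknown t-norm {spec!r}; choose from {sorted(T_NORMS)}") from None


def t_norm(a, b, spec: TNormLike = "min"):
    """Apply a t-norm to grades in [0, 1]; rejects out-of-range input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for x in (a, b):
        if (x < 0).any() or (x > 1).any():
            raise CodingError("t-norm arguments must lie in [0, 1]")
    out = as_tnorm(spec)(a, b)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


@dataclass(frozen=True, eq=False)
class LevelDistribution:
    """Per-category empirical distribution of membership levels.

    For each category *j*, ``levels[j]`` holds the distinct grades
    observed in that column (level 0 always present) and ``probs[j]``
    their frequencies — multiples of 1/N_u summing to 1. For a one-hot
    table this is just {(1, A_j/N_u), (0, 1 - A_j/N_u)}.
    """

    categories: CategorySet
    levels: tuple[np.ndarray, ...]
    probs: tuple[np.ndarray, ...]

    def for_category(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.categories.index(label)
        return self.levels[j], self.probs[j]


def level_distribution(m: MembershipTable) -> LevelDistribution:
    """Tally each column's distinct membership levels and frequencies."""
    n = m.n_units
    levels, probs = [], []
    for j in range(m.n_categories):
        vals, counts = np.unique(m.values[:, j], return_counts=True)
        if vals.size == 0 or vals[0] != 0.0:  # level 0 always listed
            vals = np.concatenate(([0.0], vals))
            counts = np.concatenate(([0], counts))
        levels.append(vals)
        probs.append(counts / n)
    return LevelDistribution(m.categories, tuple(levels), tuple(probs))


def pooled_level_distribution(m1: MembershipTable,
                              m2: MembershipTable) -> LevelDistribution:
    """Average the two raters' level distributions per category (Scott-style)."""
    m1.check_aligned(m2)
    d1 = level_distribution(m1)
    d2 = level_distribution(m2)
    levels, probs = [], []
    for j in range(m1.n_categories):
        union = np.union1d(d1.levels[j], d2.levels[j])
        p = np.zeros_like(union)
        for d in (d1, d2):
            idx = np.searchsorted(union, d.levels[j])
            p[idx] += d.probs[j] / 2.0
        levels.append(union)
        probs.append(p)
    return LevelDistribution(m1.categories, tuple(levels), tuple(probs))


def _warn_if_unnormalized(m1: MembershipTable, m2: MembershipTable,
                          tn: TNorm) -> None:
    if tn.name != "min" and not (m1.row_normalized and m2.row_normalized):
        warnings.warn(
            f"rows are not normalized to sum 1; observed agreement under "
            f"the {tn.name!r} t-norm may exceed 1",
            MembershipWarning, stacklevel=3)


def fuzzy_observed(m1: MembershipTable, m2: MembershipTable,
                   spec: TNormLike = "min") -> float:
    """Mean over units of the summed t-norm of the two raters' grades."""
    m1.check_aligned(m2)
    tn = as_tnorm(spec)
    _warn_if_unnormalized(m1, m2, tn)
    return float(tn(m1.values, m2.values).sum() / m1.n_units)


def _expected_from_distributions(d1: LevelDistribution, d2: LevelDistribution,
                                 tn: TNorm, n_categories: int) -> float:
    total = 0.0
    for j in range(n_categories):
        v1, p1 = d1.levels[j], d1.probs[j]
        v2, p2 = d2.levels[j], d2.probs[j]
        total += float(p1 @ tn(v1[:, None], v2[None, :]) @ p2)
    return total


def fuzzy_expected(m1: MembershipTable, m2: MembershipTable,
                   spec: TNormLike = "min") -> float:
    """Chance agreement over each rater's observed membership levels.

    Sums ``P1_j(v1) P2_j(v2) T(v1, v2)`` over the distinct levels of
    each category column (zero-probability levels contribute nothing, so
    cost is O(N_c * L1 * L2) with small L). Reduces exactly to the crisp
    expected agreement on one-hot input.
    """
    m1.check_aligned(m2)
    tn = as_tnorm(spec)
    return _expected_from_distributions(
        level_distribution(m1), level_distribution(m2), tn, m1.n_categories)


def fuzzy_kappa(m1: MembershipTable, m2: MembershipTable,
                spec: TNormLike = "min") -> KappaResult:
    """Chance-corrected fuzzy agreement with Cohen-style (per-rater) chance."""
    tn = as_tnorm(spec)
    po = fuzzy_observed(m1, m2, tn)
    pe = fuzzy_expected(m1, m2, tn)
    return KappaResult(f"fuzzy_kappa[{tn.name}]", po, pe,
                       kappa_from_agreements(po, pe),
                       m1.n_units, m1.n_categories)


def fuzzy_pi(m1: MembershipTable, m2: MembershipTable,
             spec: TNormLike = "min") -> KappaResult:
    """Chance-corrected fuzzy agreement with pooled (Scott-style) chance.

    Both raters' chance distributions are replaced by the average of
    their level distributions; with identical distributions this equals
    :func:`fuzzy_kappa`, and on one-hot input it equals Scott's pi.
    """
    tn = as_tnorm(spec)
    po = fuzzy_observed(m1, m2, tn)
    pooled = pooled_level_distribution(m1, m2)
    pe = _expected_from_distributions(pooled, pooled, tn, m1.n_categories)
    return KappaResult(f"fuzzy_pi[{tn.name}]", po, pe,
                       kappa_from_agreements(po, pe),
                       m1.n_units, m1.n_categories)


def two_tier_integrated(per_dim_observed, per_dim_expected) -> KappaResult:
    """Integrated index from per-dimension crisp agreements.

    For two-tier data expanded with :func:`~fuzzykappa.coding.expand_two_tier`
    and the ``min`` t-norm, every nonzero grade is 1/D, so fuzzy observed
    (resp. expected) agreement equals the mean of the D per-dimension
    crisp observed (resp. expected) agreements; the integrated kappa is
    the chance correction of those means. This helper applies that
    identity directly to published per-dimension values.
    """
    po_arr = np.asarray(per_dim_observed, dtype=float)
    pe_arr = np.asarray(per_dim_expected, dtype=float)
    if po_arr.shape != pe_arr.shape or po_arr.ndim != 1 or po_arr.size == 0:
        raise CodingError("need matching non-empty per-dimension vectors")
    po = float(po_arr.mean())
    pe = float(pe_arr.mean())
    return KappaResult("fuzzy_kappa[min]", po, pe,
                       kappa_from_agreements(po, pe),
                       0, 0)
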