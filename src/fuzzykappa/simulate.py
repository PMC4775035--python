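"""Seeded simulators of paired coders with known agreement structure.

Validation of an agreement index needs data whose true agreement is
known. The *copy model* provides exactly that for the crisp case: rater
1 draws each unit's category from fixed marginals; rater 2 copies rater
1 with probability ``a`` and otherwise draws independently from the same
marginals. Then, with S = sum_j p_j^2,

    P_o = a + (1 - a) S,   P_E = S,   kappa = (P_o - P_E)/(1 - P_E) = a

so the population Cohen's kappa equals the copy probability exactly —
an exact recovery target for estimator checks.

The ranked-pair model emulates a one-to-many protocol in which each unit
receives a handful of ordered category selections (at most four, with
one to three typically salient): rater 2 copies each of rater 1's
selections independently with probability ``overlap`` and fills the
remainder uniformly from categories not yet on its list, so fuzzy
agreement rises monotonically with ``overlap``.

All generators are pure functions of (model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coding import CategorySet, CodingError, MembershipTable, RankedSheet, one_hot

__all__ = [
    "CrispPairModel",
    "RankedPairModel",
    "default_categories",
    "simulate_crisp_pair",
    "simulate_ranked_pair",
]


def default_categories(n: int) -> CategorySet:
    """Generic labels c1..cn."""
    return CategorySet(f"c{i + 1}" for i in range(n))


@dataclass(frozen=True)
class CrispPairModel:
    """Copy model for two one-to-one coders.

    ``marginals`` is the shared category distribution; ``copy_prob`` is
    the probability rater 2 copies rater 1 on a unit, and equals the
    population Cohen's kappa of the generated pair.
    """

    n_units: int
    marginals: tuple[float, ...]
    copy_prob: float
    seed: int = 0

    def __init__(self, n_units: int, marginals: Sequence[float],
                 copy_prob: float, seed: int = 0):
        p = tuple(float(x) for x in marginals)
        if n_units < 1:
            raise CodingError("n_units must be >= 1")
        if len(p) < 2 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise CodingError(
                "marginals must be >= 2 non-negative probabilities summing to 1")
        if not 0.0 <= copy_prob <= 1.0:
            raise CodingError("copy_prob must lie in [0, 1]")
        object.__setattr__(self, "n_units", int(n_units))
        object.__setattr__(self, "marginals", p)
        object.__setattr__(self, "copy_prob", float(copy_prob))
        object.__setattr__(self, "seed", int(seed))

    @property
    def population_kappa(self) -> float:
        """Closed form: P_o = a + (1-a)S and P_E = S give kappa = a."""
        return self.copy_prob


@dataclass(frozen=True)
class RankedPairModel:
    """Overlap model for two one-to-many coders with ranked selections.

    Rater 1 selects ``k`` categories uniformly without replacement, with
    ``k`` drawn from ``count_probs`` (distribution over 1..K). Rater 2
    copies each of rater 1's selections with probability ``overlap``
    (keeping their rank order) and fills up to the same ``k`` uniformly
    from categories not yet selected; ``rank_shuffle`` optionally
    permutes rater 2's final order.
    """

    n_units: int
    n_categories: int = 20
    count_probs: tuple[float, ...] = (0.30, 0.35, 0.25, 0.10)
    overlap: float = 0.8
    rank_shuffle: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 1:
            raise CodingError("n_units must be >= 1")
        cp = tuple(float(x) for x in self.count_probs)
        if not cp or any(x < 0 for x in cp) or abs(sum(cp) - 1.0) > 1e-9:
            raise CodingError("count_probs must be probabilities summing to 1")
        if len(cp) > self.n_categories:
            raise CodingError(
                f"max selection count {len(cp)} exceeds "
                f"{self.n_categories} categories")
        if not 0.0 <= self.overlap <= 1.0:
            raise CodingError("overlap must lie in [0, 1]")
        object.__setattr__(self, "count_probs", cp)


def simulate_crisp_pair(
        model: CrispPairModel) -> tuple[MembershipTable, MembershipTable]:
    """Generate the copy model's pair of one-hot membership tables."""
    rng = np.random.default_rng(model.seed)
    nc = len(model.marginals)
    cats = default_categories(nc)
    p = np.asarray(model.marginals)
    r1 = rng.choice(nc, size=model.n_units, p=p)
    independent = rng.choice(nc, size=model.n_units, p=p)
    copied = rng.random(model.n_units) < model.copy_prob
    r2 = np.where(copied, r1, independent)
    ids = [str(i + 1) for i in range(model.n_units)]
    m1 = one_hot([cats[j] for j in r1], cats, ids)
    m2 = one_hot([cats[j] for j in r2], cats, ids)
    return m1, m2


def simulate_ranked_pair(
        model: RankedPairModel) -> tuple[RankedSheet, RankedSheet]:
    """Generate the overlap model's pair of ranked coding sheets."""
    rng = np.random.default_rng(model.seed)
    cats = default_categories(model.n_categories)
    counts = 1 + rng.choice(len(model.count_probs), size=model.n_units,
                            p=np.asarray(model.count_probs))
    ids = [str(i + 1) for i in range(model.n_units)]
    sel1: list[tuple[str, ...]] = []
    sel2: list[tuple[str, ...]] = []
    for k in counts:
        picks1 = rng.choice(model.n_categories, size=k, replace=False)
        row1 = tuple(cats[j] for j in picks1)
        keep = [j for j in picks1 if rng.random() < model.overlap]
        pool = [j for j in range(model.n_categories) if j not in keep]
        fill = rng.choice(len(pool), size=k - len(keep), replace=False)
        picks2 = keep + [pool[f] for f in fill]
        if model.rank_shuffle:
            picks2 = [picks2[j] for j in rng.permutation(len(picks2))]
        sel1.append(row1)
        sel2.append(tuple(cats[j] for j in picks2))
    return RankedSheet(ids, sel1), RankedSheet(ids, sel2)
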