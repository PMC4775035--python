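"""Classical one-to-one agreement indices: raw agreement, Cohen's kappa, Scott's pi.

For two raters who each place every coding unit in exactly one category,
chance-corrected agreement is

    kappa = (P_o - P_E) / (1 - P_E)

where ``P_o`` is the observed proportion of identical decisions and
``P_E`` the proportion expected by chance from the raters' marginal
category usage: Cohen's kappa multiplies each rater's own marginals,
Scott's pi squares the pooled marginals. Both are special cases of the
fuzzy indices in :mod:`fuzzykappa.fuzzy`, which reduce to them exactly on
one-hot membership tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coding import CodingError, MembershipTable

__all__ = [
    "KappaResult",
    "kappa_from_agreements",
    "observed_agreement_crisp",
    "expected_agreement_crisp",
    "cohen_kappa",
    "scott_pi",
]

# Expected agreement this close to 1 makes the chance correction 0/0;
# happens only when both raters are constant on one category.
_UNDEFINED_TOL = 1e-12


@dataclass
class KappaResult:
    """Observed/expected agreement and the chance-corrected index.

    ``kappa`` is ``None`` — explicitly undefined, never silently 0 —
    when expected agreement is 1 (both raters constant on the same
    category); ``observed`` stays populated. ``ci`` holds a percentile
    bootstrap interval when one was requested.
    """

    statistic: str
    observed: float
    expected: float
    kappa: float | None
    n_units: int
    n_categories: int
    ci: tuple[float, float] | None = None
    ci_level: float | None = None

    @property
    def defined(self) -> bool:
        return self.kappa is not None

    def __str__(self) -> str:
        k = "undefined" if self.kappa is None else f"{self.kappa:.2f}"
        s = (f"{self.statistic}: P_o={self.observed:.2f} "
             f"P_E={self.expected:.2f} value={k}")
        if self.ci is not None:
            s += f" CI[{self.ci_level:.0%}]=({self.ci[0]:.2f}, {self.ci[1]:.2f})"
        return s


def kappa_from_agreements(observed: float, expected: float) -> float | None:
    """Chance correction (P_o - P_E)/(1 - P_E); None when P_E = 1."""
    if 1.0 - expected <= _UNDEFINED_TOL:
        return None
    return (observed - expected) / (1.0 - expected)


def _check_pair(m1: MembershipTable, m2: MembershipTable,
                require_one_hot: bool) -> None:
    m1.check_aligned(m2)
    if require_one_hot and not (m1.is_one_hot and m2.is_one_hot):
        raise CodingError(
            "crisp indices need one-hot membership tables; "
            "use the fuzzy indices for graded tables")


def observed_agreement_crisp(m1: MembershipTable,
                             m2: MembershipTable) -> float:
    """Proportion of units the raters placed in the same category.

    Computed as the mean row scalar product, which for one-hot rows is
    exactly the fraction of identical rows.
    """
    _check_pair(m1, m2, require_one_hot=True)
    return float(np.einsum("ij,ij->", m1.values, m2.values) / m1.n_units)


def expected_agreement_crisp(m1: MembershipTable,
                             m2: MembershipTable) -> float:
    """Chance agreement from the product of per-rater marginals.

    ``sum_j (A_j/N_u) (B_j/N_u)`` with ``A_j``, ``B_j`` the raters'
    column totals. Categories unused by both raters contribute 0, so the
    value is invariant to padding the category set.
    """
    _check_pair(m1, m2, require_one_hot=True)
    a = m1.values.mean(axis=0)
    b = m2.values.mean(axis=0)
    return float(a @ b)


def cohen_kappa(m1: MembershipTable, m2: MembershipTable) -> KappaResult:
    """Cohen's kappa: chance marginals taken separately per rater."""
    po = observed_agreement_crisp(m1, m2)
    pe = expected_agreement_crisp(m1, m2)
    return KappaResult("cohen_kappa", po, pe, kappa_from_agreements(po, pe),
                       m1.n_units, m1.n_categories)


def scott_pi(m1: MembershipTable, m2: MembershipTable) -> KappaResult:
    """Scott's pi: chance agreement from the pooled joint distribution.

    ``P_E = sum_j p_j^2`` with ``p_j = (A_j + B_j) / (2 N_u)``; when the
    raters' marginals coincide this equals Cohen's kappa exactly.
    """
    po = observed_agreement_crisp(m1, m2)
    pooled = (m1.values.mean(axis=0) + m2.values.mean(axis=0)) / 2.0
    pe = float(pooled @ pooled)
    return KappaResult("scott_pi", po, pe, kappa_from_agreements(po, pe),
                       m1.n_units, m1.n_categories)
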