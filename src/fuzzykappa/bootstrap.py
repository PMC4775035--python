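"""Percentile bootstrap confidence intervals for agreement statistics.

Coding units are the exchangeable entity in every agreement formula, so
resampling draws unit indices with replacement and carries *both*
raters' rows for each drawn unit, preserving the within-unit dependence
the statistic measures. The interval is the empirical quantile range of
the replicate values. Replicates on which the statistic is undefined
(chance agreement 1) are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .coding import CodingError, MembershipTable
from .crisp import KappaResult, cohen_kappa, scott_pi
from .fuzzy import TNormLike, fuzzy_kappa, fuzzy_observed, fuzzy_pi

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "STATISTICS",
    "resolve_statistic",
    "bootstrap_ci",
]

StatFn = Callable[[MembershipTable, MembershipTable], Union[KappaResult, float]]

#: Named statistics usable by name from config files and the CLI.
STATISTICS: dict[str, Callable[..., Union[KappaResult, float]]] = {
    "cohen_kappa": cohen_kappa,
    "scott_pi": scott_pi,
    "fuzzy_kappa": fuzzy_kappa,
    "fuzzy_pi": fuzzy_pi,
    "fuzzy_observed": fuzzy_observed,
}


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings: B replicates, coverage level, seeded stream."""

    replicates: int = 1000
    level: float = 0.95
    seed: int | None = None
    method: str = "percentile"

    def __post_init__(self):
        if self.replicates < 1:
            raise CodingError("replicates must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise CodingError("coverage level must lie in (0, 1)")
        if self.method != "percentile":
            raise CodingError(f"unsupported bootstrap method {self.method!r}")


@dataclass
class BootstrapResult:
    """Point estimate, percentile interval, and the replicate values."""

    point: float | None
    low: float
    high: float
    level: float
    n_replicates: int
    n_undefined: int
    replicates: np.ndarray

    @property
    def interval(self) -> tuple[float, float]:
        return (self.low, self.high)


def resolve_statistic(statistic: Union[str, StatFn],
                      tnorm: TNormLike = "min") -> StatFn:
    """Turn a statistic name (or callable) into ``f(m1, m2) -> value``.

    Fuzzy statistics are bound to the given t-norm; crisp ones ignore it.
    """
    if callable(statistic):
        return statistic
    try:
        fn = STATISTICS[statistic]
    except KeyError:
        raise CodingError(
            f"unknown statistic {statistic!r}; "
            f"choose from {sorted(STATISTICS)}") from None
    if statistic.startswith("fuzzy"):
        return lambda a, b: fn(a, b, tnorm)
    return fn


def _scalar(value: Union[KappaResult, float]) -> float | None:
    if isinstance(value, KappaResult):
        return value.kappa
    return float(value)


def bootstrap_ci(m1: MembershipTable, m2: MembershipTable,
                 statistic: Union[str, StatFn] = "cohen_kappa",
                 config: BootstrapConfig | None = None, *,
                 tnorm: TNormLike = "min") -> BootstrapResult:
    """Percentile bootstrap interval for an agreement statistic.

    Parameters
    ----------
    m1, m2 : aligned membership tables, one per rater.
    statistic : name from :data:`STATISTICS` or a callable returning a
        :class:`~fuzzykappa.crisp.KappaResult` or a float.
    config : replicate count, level and seed; defaults to B=1000 at 95%.
    tnorm : t-norm bound to fuzzy statistics referenced by name.

    The same seed and config reproduce the interval bit-exactly.
    """
    m1.check_aligned(m2)
    if m1.n_units < 2:
        raise CodingError("bootstrap needs at least 2 coding units")
    if config is None:
        config = BootstrapConfig()
    fn = resolve_statistic(statistic, tnorm)
    point = _scalar(fn(m1, m2))

    rng = np.random.default_rng(config.seed)
    n = m1.n_units
    values = np.empty(config.replicates)
    n_undefined = 0
    kept = 0
    for _ in range(config.replicates):
        idx = rng.integers(0, n, n)
        val = _scalar(fn(m1.subset(idx), m2.subset(idx)))
        if val is None:
            n_undefined += 1
            continue
        values[kept] = val
        kept += 1
    if kept == 0:
        raise CodingError(
            "statistic undefined on every bootstrap replicate "
            "(chance agreement 1 throughout)")
    values = values[:kept]
    alpha = (1.0 - config.level) / 2.0
    low, high = np.quantile(values, [alpha, 1.0 - alpha])
    return BootstrapResult(point, float(low), float(high), config.level,
                           kept, n_undefined, values)
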