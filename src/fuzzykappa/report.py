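"""Batch analysis driver: read two raters' sheets, compute indices, report.

``run_analysis`` takes a plain config mapping (YAML-friendly, mirrored by
the CLI flags) and returns a structured report: run metadata plus one row
per index, each with observed agreement, expected agreement, the
chance-corrected value and an optional bootstrap interval.
``format_report`` renders the rows as a fixed-width table (P_o, P_E,
value, CI) with 2-decimal display; the report itself keeps full precision.
"""

from __future__ import annotations

import logging
from typing import Any

from . import __version__
from .bootstrap import BootstrapConfig, BootstrapResult, bootstrap_ci
from .coding import (
    CategorySet,
    CodingError,
    MembershipTable,
    equal_split,
    expand_two_tier,
    first_selection_only,
    one_hot,
    rank_weighted,
)
from .crisp import KappaResult, cohen_kappa
from .fuzzy import fuzzy_kappa, fuzzy_pi
from .sheets import (
    SheetFormat,
    read_categories,
    read_crisp_sheet,
    read_membership_sheet,
    read_ranked_sheet,
    read_scheme,
)

__all__ = ["run_analysis", "format_report"]

logger = logging.getLogger("fuzzykappa")


def _check_unit_sets(ids_a, ids_b) -> None:
    set_a, set_b = set(ids_a), set(ids_b)
    if set_a != set_b:
        only_a = sorted(set_a - set_b)
        only_b = sorted(set_b - set_a)
        raise CodingError(
            "the two sheets cover different units; "
            f"only in first: {only_a}; only in second: {only_b}")


def _reorder(sheet_ids, target_ids, reindex):
    order = {uid: i for i, uid in enumerate(sheet_ids)}
    return [order[uid] for uid in target_ids] if reindex else None


def _row(label: str, result: KappaResult,
         boot: BootstrapResult | None) -> dict[str, Any]:
    row: dict[str, Any] = {
        "label": label,
        "statistic": result.statistic,
        "observed": result.observed,
        "expected": result.expected,
        "value": result.kappa,
        "n_units": result.n_units,
        "n_categories": result.n_categories,
    }
    if boot is not None:
        row["ci_low"] = boot.low
        row["ci_high"] = boot.high
        row["ci_level"] = boot.level
        row["n_undefined_replicates"] = boot.n_undefined
        result.ci = (boot.low, boot.high)
        result.ci_level = boot.level
    return row


def _maybe_boot(m1: MembershipTable, m2: MembershipTable, statistic,
                bootstrap: dict | None, tnorm: str,
                offset: int) -> BootstrapResult | None:
    if not bootstrap or not bootstrap.get("replicates"):
        return None
    seed = bootstrap.get("seed")
    config = BootstrapConfig(
        replicates=int(bootstrap["replicates"]),
        level=float(bootstrap.get("level", 0.95)),
        # each report row gets its own reproducible stream
        seed=None if seed is None else int(seed) + offset,
    )
    return bootstrap_ci(m1, m2, statistic, config, tnorm=tnorm)


def run_analysis(config: dict) -> dict:
    """Run the full two-rater analysis described by a config mapping.

    Required keys: ``files`` (two sheet paths) and ``layout``
    (``one_to_one`` needs ``scheme``; ``one_to_many`` needs
    ``categories``; ``membership`` reads categories from the header).
    Optional: ``tnorm`` (default min), ``weights`` (descending rank
    weights; one_to_many only), ``bootstrap`` mapping with
    ``replicates``/``level``/``seed``, ``delimiter``, ``header``.
    """
    try:
        path_a, path_b = config["files"]
    except (KeyError, ValueError):
        raise CodingError("config must name exactly two sheet files") from None
    layout = config.get("layout", "one_to_many")
    tnorm = config.get("tnorm", "min")
    weights = config.get("weights")
    bootstrap = config.get("bootstrap")
    fmt = SheetFormat(layout=layout,
                      delimiter=config.get("delimiter"),
                      header=bool(config.get("header", True)))

    rows: list[dict[str, Any]] = []

    if layout == "one_to_one":
        if "scheme" not in config:
            raise CodingError("one_to_one layout requires a 'scheme' file")
        scheme = config["scheme"] if not isinstance(config["scheme"], str) \
            else read_scheme(config["scheme"])
        sheet_a = read_crisp_sheet(path_a, scheme, fmt)
        sheet_b = read_crisp_sheet(path_b, scheme, fmt)
        _check_unit_sets(sheet_a.unit_ids, sheet_b.unit_ids)
        order = _reorder(sheet_b.unit_ids, sheet_a.unit_ids,
                         sheet_a.unit_ids != sheet_b.unit_ids)
        codes_b = sheet_b.codes if order is None else sheet_b.codes[order]
        # per-dimension crisp indices, then the integrated fuzzy index
        for d, (name, levels) in enumerate(scheme.dimensions):
            cats = CategorySet(levels)
            ma = one_hot([levels[c] for c in sheet_a.codes[:, d]], cats,
                         sheet_a.unit_ids)
            mb = one_hot([levels[c] for c in codes_b[:, d]], cats,
                         sheet_a.unit_ids)
            res = cohen_kappa(ma, mb)
            rows.append(_row(name, res,
                             _maybe_boot(ma, mb, "cohen_kappa", bootstrap,
                                         tnorm, d)))
        from .coding import CrispSheet
        sheet_b_aligned = CrispSheet(sheet_a.unit_ids, codes_b)
        ma = expand_two_tier(sheet_a, scheme)
        mb = expand_two_tier(sheet_b_aligned, scheme)
        res = fuzzy_kappa(ma, mb, tnorm)
        rows.append(_row("integrated (fuzzy kappa)", res,
                         _maybe_boot(ma, mb, "fuzzy_kappa", bootstrap, tnorm,
                                     scheme.n_dimensions)))
        n_units, n_categories = ma.n_units, ma.n_categories

    elif layout == "one_to_many":
        if "categories" not in config:
            raise CodingError("one_to_many layout requires a 'categories' file")
        cats = config["categories"] if not isinstance(config["categories"], str) \
            else read_categories(config["categories"])
        sheet_a = read_ranked_sheet(path_a, cats, fmt)
        sheet_b = read_ranked_sheet(path_b, cats, fmt)
        _check_unit_sets(sheet_a.unit_ids, sheet_b.unit_ids)
        if sheet_a.unit_ids != sheet_b.unit_ids:
            order = _reorder(sheet_b.unit_ids, sheet_a.unit_ids, True)
            from .coding import RankedSheet
            sheet_b = RankedSheet(sheet_a.unit_ids,
                                  [sheet_b.selections[i] for i in order])
        if weights is not None:
            ma = rank_weighted(sheet_a, cats, weights)
            mb = rank_weighted(sheet_b, cats, weights)
            fuzzy_label = "fuzzy kappa (rank-weighted)"
        else:
            ma = equal_split(sheet_a, cats)
            mb = equal_split(sheet_b, cats)
            fuzzy_label = "fuzzy kappa (equal weights)"
        rows.append(_row(fuzzy_label, fuzzy_kappa(ma, mb, tnorm),
                         _maybe_boot(ma, mb, "fuzzy_kappa", bootstrap, tnorm, 0)))
        rows.append(_row("fuzzy pi", fuzzy_pi(ma, mb, tnorm),
                         _maybe_boot(ma, mb, "fuzzy_pi", bootstrap, tnorm, 1)))
        fa = one_hot(first_selection_only(sheet_a), cats, sheet_a.unit_ids)
        fb = one_hot(first_selection_only(sheet_b), cats, sheet_b.unit_ids)
        rows.append(_row("first selection only (crisp kappa)",
                         cohen_kappa(fa, fb),
                         _maybe_boot(fa, fb, "cohen_kappa", bootstrap, tnorm, 2)))
        n_units, n_categories = ma.n_units, ma.n_categories

    elif layout == "membership":
        cats = (read_categories(config["categories"])
                if isinstance(config.get("categories"), str)
                else config.get("categories"))
        ma = read_membership_sheet(path_a, cats, fmt)
        mb = read_membership_sheet(path_b, ma.categories, fmt)
        _check_unit_sets(ma.unit_ids, mb.unit_ids)
        if ma.unit_ids != mb.unit_ids:
            order = _reorder(mb.unit_ids, ma.unit_ids, True)
            mb = MembershipTable(ma.unit_ids, mb.categories, mb.values[order])
        rows.append(_row("fuzzy kappa", fuzzy_kappa(ma, mb, tnorm),
                         _maybe_boot(ma, mb, "fuzzy_kappa", bootstrap, tnorm, 0)))
        rows.append(_row("fuzzy pi", fuzzy_pi(ma, mb, tnorm),
                         _maybe_boot(ma, mb, "fuzzy_pi", bootstrap, tnorm, 1)))
        n_units, n_categories = ma.n_units, ma.n_categories

    else:
        raise CodingError(f"unknown layout {layout!r}")

    logger.info("analysis: %d units, %d categories, t-norm=%s",
                n_units, n_categories, tnorm)
    logger.info("rater 1 marginals: %s", ma.values.mean(axis=0).round(4))
    logger.info("rater 2 marginals: %s", mb.values.mean(axis=0).round(4))

    return {
        "meta": {
            "package": "fuzzykappa",
            "version": __version__,
            "layout": layout,
            "tnorm": tnorm,
            "weights": None if weights is None else list(weights),
            "n_units": n_units,
            "n_categories": n_categories,
            "bootstrap": bootstrap or None,
        },
        "rows": rows,
    }


def _fmt(x, width=7) -> str:
    if x is None:
        return "undef".rjust(width)
    return f"{x:.2f}".rjust(width)


def format_report(report: dict) -> str:
    """Human-readable fixed-width table mirroring the structured rows."""
    label_w = max(24, max(len(r["label"]) for r in report["rows"]) + 2)
    lines = [
        f"fuzzykappa {report['meta']['version']} — layout "
        f"{report['meta']['layout']}, t-norm {report['meta']['tnorm']}, "
        f"{report['meta']['n_units']} units, "
        f"{report['meta']['n_categories']} categories",
        "",
        "".join(["index".ljust(label_w), "P_o".rjust(7), "P_E".rjust(7),
                 "value".rjust(7)]
                + (["     CI"] if any("ci_low" in r
                                      for r in report["rows"]) else [])),
    ]
    for r in report["rows"]:
        ci = ""
        if "ci_low" in r:
            ci = f"   {r['ci_low']:.2f}–{r['ci_high']:.2f}"
        lines.append("".join([
            r["label"].ljust(label_w), _fmt(r["observed"]),
            _fmt(r["expected"]), _fmt(r["value"]), ci]))
    return "\n".join(lines)
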