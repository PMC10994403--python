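"""Design-weighted coverage estimation and disaggregated summary tables.

Point estimates are Hájek ratios (sum w*y / sum w).  Variances use Taylor
linearization with the enumeration area as the primary sampling unit and
urban/rural residence as the stratum, under the with-replacement
approximation — the standard default for two-stage cluster surveys.
Confidence intervals are Wald intervals on the logit scale so they respect
[0, 1]; degenerate all-0/all-1 groups fall back to a one-sided exact
(Clopper-Pearson) bound on the unweighted count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist, norm

from .geodata import CATEGORY_LEVELS, METHODS, WomanRecord, categorize_distance

__all__ = [
    "WeightedEstimate",
    "weighted_proportion",
    "background_table",
    "method_mix_table",
    "distance_summary_table",
    "coverage_disparity",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding for printed-table comparability."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class WeightedEstimate:
    """A weighted proportion with its design-based 95% interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n_unweighted: int
    n_weighted: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.estimate + 1e-12
                and self.estimate <= self.ci_high + 1e-12 and self.ci_high <= 1.0):
            raise ValueError(f"interval out of order: {self}")


def _taylor_se(records: Sequence[WomanRecord], y: np.ndarray, w: np.ndarray, p_hat: float) -> float:
    """Linearized SE of the ratio estimator, EA = PSU, residence = stratum."""
    z = w * (y - p_hat)  # linearized scores
    strata: dict[str, dict[str, float]] = {}
    for rec, zi in zip(records, z):
        strata.setdefault(rec.residence, {}).setdefault(rec.ea_id, 0.0)
        strata[rec.residence][rec.ea_id] += zi
    var = 0.0
    for totals in strata.values():
        t = np.array(list(totals.values()))
        nh = len(t)
        if nh >= 2:
            var += nh / (nh - 1) * float(np.sum((t - t.mean()) ** 2))
    return math.sqrt(var) / float(w.sum())


def weighted_proportion(
    records: Sequence[WomanRecord],
    indicator: Callable[[WomanRecord], bool] = lambda w: w.uses_modern,
    alpha: float = 0.05,
) -> WeightedEstimate:
    """Design-weighted proportion of records satisfying the indicator."""
    if not records:
        raise ValueError("empty group")
    w = np.array([r.weight for r in records])
    y = np.array([1.0 if indicator(r) else 0.0 for r in records])
    p_hat = float((w * y).sum() / w.sum())
    n = len(records)
    zq = norm.ppf(1 - alpha / 2)
    if p_hat <= 0.0 or p_hat >= 1.0:
        # all-0 / all-1: one-sided exact bound on the unweighted count
        k = int(y.sum())
        if k == 0:
            return WeightedEstimate(0.0, 0.0, float(beta_dist.ppf(1 - alpha, 1, n)),
                                    n, float(w.sum()))
        return WeightedEstimate(1.0, float(beta_dist.ppf(alpha, n, 1)), 1.0,
                                n, float(w.sum()))
    se = _taylor_se(records, y, w, p_hat)
    if se == 0.0:
        return WeightedEstimate(p_hat, p_hat, p_hat, n, float(w.sum()))
    logit = math.log(p_hat / (1 - p_hat))
    se_logit = se / (p_hat * (1 - p_hat))
    lo = 1.0 / (1.0 + math.exp(-(logit - zq * se_logit)))
    hi = 1.0 / (1.0 + math.exp(-(logit + zq * se_logit)))
    return WeightedEstimate(p_hat, lo, hi, n, float(w.sum()))


_TABLE_FACTORS = [
    "age_group", "education", "marital", "religion", "wealth", "parity",
    "sdp_distance", "media", "ever_pregnant", "partner_discussion",
    "partner_feeling", "fertility_intention", "residence", "region",
]


def _level_of(rec: WomanRecord, factor: str) -> str:
    if factor == "sdp_distance":
        if rec.sdp_distance_km is None:
            raise ValueError(f"record {rec.woman_id}: sdp_distance_km unset")
        return categorize_distance(rec.sdp_distance_km)
    return getattr(rec, factor)


def _levels_of(factor: str, records: Sequence[WomanRecord]) -> list[str]:
    if factor in CATEGORY_LEVELS:
        return list(CATEGORY_LEVELS[factor])
    if factor == "sdp_distance":
        return ["le2km", "2to6km", "gt6km"]
    return sorted({getattr(r, factor) for r in records})


def background_table(
    records: Sequence[WomanRecord], factors: Sequence[str] | None = None
) -> pd.DataFrame:
    """Weighted background-characteristics table: per factor level, the
    unweighted n, weighted n (scaled to the total sample size), and weighted
    percent of the total."""
    if not records:
        raise ValueError("no records")
    factors = list(factors) if factors is not None else list(_TABLE_FACTORS)
    w = np.array([r.weight for r in records])
    scale = len(records) / w.sum()  # normalize weighted n to the sample size
    rows = []
    for factor in factors:
        for level in _levels_of(factor, records):
            mask = np.array([_level_of(r, factor) == level for r in records])
            rows.append({
                "factor": factor,
                "level": level,
                "n_unweighted": int(mask.sum()),
                "n_weighted": float((w[mask]).sum() * scale),
                "percent_weighted": float(w[mask].sum() / w.sum() * 100.0),
            })
    return pd.DataFrame(rows)


def method_mix_table(
    records: Sequence[WomanRecord], by: str | None = None
) -> pd.DataFrame:
    """Coverage and method mix, overall and by subgroup.

    Each row gives the weighted percent of in-need women in the level using
    any modern method and using each specific method, so the method shares
    partition the coverage.
    """
    if not records:
        raise ValueError("no records")
    groups: list[tuple[str, str, list[WomanRecord]]]
    groups = [("total", "total", list(records))]
    if by is not None:
        for level in _levels_of(by, records):
            sub = [r for r in records if _level_of(r, by) == level]
            if not sub:
                import logging

                logging.getLogger(__name__).warning(
                    "method_mix_table: level %s=%r empty, row omitted", by, level
                )
                continue
            groups.append((by, level, sub))
    rows = []
    for factor, level, sub in groups:
        w = np.array([r.weight for r in sub])
        tot = w.sum()
        cov = float(w[[r.uses_modern for r in sub]].sum() / tot * 100.0)
        row = {"factor": factor, "level": level, "n_unweighted": len(sub),
               "mcp_percent": cov}
        for meth in METHODS:
            row[f"{meth}_percent"] = float(
                w[[r.method == meth for r in sub]].sum() / tot * 100.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def distance_summary_table(
    records: Sequence[WomanRecord], by: str = "region", weighted: bool = False
) -> pd.DataFrame:
    """Nearest-SDP distance summaries and category percentages per subgroup.

    Unweighted by default (descriptive); set ``weighted`` for design-weighted
    means and percentages.
    """
    if any(r.sdp_distance_km is None for r in records):
        raise ValueError("sdp_distance_km unset on some records")
    levels = _levels_of(by, records) + ["total"]
    rows = []
    for level in levels:
        sub = records if level == "total" else [
            r for r in records if _level_of(r, by) == level
        ]
        if not sub:
            continue
        d = np.array([r.sdp_distance_km for r in sub])
        w = np.array([r.weight for r in sub]) if weighted else np.ones(len(sub))
        cats = np.array([categorize_distance(x) for x in d])
        row = {
            by: level,
            "n": len(sub),
            "mean": float((w * d).sum() / w.sum()),
            "median": float(np.median(d)),
            "sd": float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
            "min": float(d.min()),
            "max": float(d.max()),
        }
        for cat in ("le2km", "2to6km", "gt6km"):
            row[f"pct_{cat}"] = float(w[cats == cat].sum() / w.sum() * 100.0)
        rows.append(row)
    return pd.DataFrame(rows)


def coverage_disparity(
    records: Sequence[WomanRecord],
    factor: str,
    advantaged: str,
    disadvantaged: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Coverage gap between two subgroups, absolute and relative.

    Reports the absolute difference in percentage points and the relative
    difference 100*(p1 - p2)/p2, each with a seeded EA-level bootstrap
    interval (resampling whole clusters preserves the design structure).
    """
    for level in (advantaged, disadvantaged):
        if not any(_level_of(r, factor) == level for r in records):
            raise ValueError(f"level {factor}={level!r} not present")

    def gaps(recs: Sequence[WomanRecord]) -> tuple[float, float] | None:
        g1 = [r for r in recs if _level_of(r, factor) == advantaged]
        g2 = [r for r in recs if _level_of(r, factor) == disadvantaged]
        if not g1 or not g2:
            return None
        p1 = weighted_proportion(g1).estimate
        p2 = weighted_proportion(g2).estimate
        absolute = (p1 - p2) * 100.0
        relative = 100.0 * (p1 - p2) / p2 if p2 > 0 else math.inf
        return absolute, relative

    point = gaps(records)
    assert point is not None
    rng = np.random.default_rng(seed)
    ea_ids = sorted({r.ea_id for r in records})
    by_ea = {e: [r for r in records if r.ea_id == e] for e in ea_ids}
    abs_bs, rel_bs = [], []
    for _ in range(n_boot):
        sample_eas = rng.choice(len(ea_ids), size=len(ea_ids), replace=True)
        recs = [r for i in sample_eas for r in by_ea[ea_ids[i]]]
        g = gaps(recs)
        if g is not None and math.isfinite(g[1]):
            abs_bs.append(g[0])
            rel_bs.append(g[1])
    return {
        "factor": factor,
        "comparison": f"{advantaged} vs {disadvantaged}",
        "absolute_pp": point[0],
        "absolute_ci": (float(np.quantile(abs_bs, 0.025)), float(np.quantile(abs_bs, 0.975))),
        "relative_percent": point[1],
        "relative_ci": (float(np.quantile(rel_bs, 0.025)), float(np.quantile(rel_bs, 0.975))),
        "n_boot_effective": len(abs_bs),
    }
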