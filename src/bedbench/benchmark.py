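"""Counterfactual bed-need projection, gap classification and rollup.

For each unit the fitted model yields two projections on the reciprocal
scale: an *unadjusted* one at the unit's own CMH composite, and an
*adjusted* (counterfactual) one with the composite — and its square and
cube — replaced by the optimal-scenario value c*. The 95% interval is built
on the transformed scale (t quantile with the model's residual df) and
mapped back through the reciprocal, which swaps the endpoints.

A unit is then classified by where its actual bed rate falls relative to
the adjusted interval: below the lower bound (under-provided), inside it
(commensurate with need), or above the upper bound (over-provided).
Boundary ties count as inside — the interval is closed.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cmh_index import ScenarioValue
from .data_model import StateRecord
from .exceptions import NonPhysicalIntervalError, ValidationError
from .regression import FittedModel, design_row, predict_with_se
from .transform import back_transform_interval, back_transform_point

__all__ = [
    "GapCategory",
    "BenchmarkEstimate",
    "SummaryRow",
    "project_unit",
    "classify_gap",
    "aggregate",
    "gap_census",
    "estimates_to_frame",
]

logger = logging.getLogger(__name__)


class GapCategory(str, enum.Enum):
    """Trichotomous comparison of actual provision to the interval of need."""

    UNDER_PROVIDED = "UNDER_PROVIDED"  # actual < lower bound
    WITHIN = "WITHIN"  # lower <= actual <= upper
    OVER_PROVIDED = "OVER_PROVIDED"  # actual > upper bound

    def printed_label(self) -> str:
        return {
            GapCategory.UNDER_PROVIDED: "Actual < Needed",
            GapCategory.WITHIN: "Actual = Needed (w/95%)",
            GapCategory.OVER_PROVIDED: "Actual > Needed",
        }[self]


@dataclass
class BenchmarkEstimate:
    """Per-unit actual rate, projections, 95% interval and gap category."""

    name: str
    actual: float
    unadjusted: float
    adjusted: float
    ci_low: float
    ci_high: float
    category: GapCategory
    division: str | None = None
    region: str | None = None
    population: float | None = None
    non_physical: bool = False  # transformed bound <= 0; interval right-open


@dataclass
class SummaryRow:
    """Grouped weighted/unweighted means of the benchmark columns."""

    group: str
    n: int
    weighted: dict
    unweighted: dict
    category: GapCategory


def classify_gap(actual: float, lo: float, hi: float) -> GapCategory:
    """Compare an actual rate with a 95% interval of need (closed interval)."""
    if lo >= hi:
        raise ValidationError(f"interval bounds out of order: ({lo}, {hi})")
    if actual < lo:
        return GapCategory.UNDER_PROVIDED
    if actual > hi:
        return GapCategory.OVER_PROVIDED
    return GapCategory.WITHIN


def project_unit(
    model: FittedModel,
    record: StateRecord,
    composite: float,
    scenario: ScenarioValue | None = None,
    interval: str = "confidence",
    alpha: float = 0.05,
) -> BenchmarkEstimate:
    """Project one unit's needed bed rate, with and without the scenario.

    The coefficient signs are used as estimated; the reciprocal
    back-transform alone handles the direction reversal.
    """
    x_own = design_row(record.disability_pct, composite, record.married_pct, record.life_expectancy)
    c_star = scenario.value if scenario is not None else composite
    x_adj = design_row(record.disability_pct, c_star, record.married_pct, record.life_expectancy)

    fit_own, _ = predict_with_se(model, x_own, interval=interval)
    fit_adj, se_adj = predict_with_se(model, x_adj, interval=interval)

    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, model.df_resid))
    lo_prime = fit_adj - tcrit * se_adj
    hi_prime = fit_adj + tcrit * se_adj

    non_physical = False
    try:
        unadjusted = back_transform_point(fit_own)
    except NonPhysicalIntervalError:
        unadjusted, non_physical = np.nan, True
    try:
        adjusted = back_transform_point(fit_adj)
    except NonPhysicalIntervalError:
        adjusted, non_physical = np.nan, True

    if hi_prime <= 0:
        lo, hi, non_physical = np.nan, np.nan, True
    else:
        try:
            lo, hi = back_transform_interval(lo_prime, hi_prime)
        except NonPhysicalIntervalError:
            # right-open on the rate scale: only the lower rate bound exists
            lo, hi, non_physical = 1.0 / hi_prime, np.inf, True

    if np.isfinite(lo) and (np.isfinite(hi) or hi == np.inf) and lo < hi:
        category = classify_gap(record.bed_rate, lo, hi)
    else:
        category = GapCategory.WITHIN  # degenerate; flagged non-physical

    return BenchmarkEstimate(
        name=record.name,
        actual=record.bed_rate,
        unadjusted=unadjusted,
        adjusted=adjusted,
        ci_low=lo,
        ci_high=hi,
        category=category,
        division=record.division,
        region=record.region,
        population=record.population,
        non_physical=non_physical,
    )


_COLS = ("actual", "unadjusted", "adjusted", "ci_low", "ci_high")


def estimates_to_frame(estimates: list[BenchmarkEstimate]) -> pd.DataFrame:
    """Benchmark estimates as a DataFrame mirroring the published column order."""
    return pd.DataFrame(
        {
            "state": [e.name for e in estimates],
            "actual": [e.actual for e in estimates],
            "unadjusted": [e.unadjusted for e in estimates],
            "adjusted": [e.adjusted for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "category": [e.category.value for e in estimates],
            "label": [e.category.printed_label() for e in estimates],
            "division": [e.division for e in estimates],
            "region": [e.region for e in estimates],
            "non_physical": [e.non_physical for e in estimates],
        }
    )


def _group_key(estimate: BenchmarkEstimate, group_by: str | None) -> str:
    if group_by is None or group_by == "none":
        return "Total"
    if group_by == "division":
        return estimate.division or "(no division)"
    if group_by == "region":
        return estimate.region or "(no region)"
    raise ValidationError(f"group_by must be none|division|region, got {group_by!r}")


def aggregate(
    estimates: list[BenchmarkEstimate],
    weights=None,
    group_by: str | None = None,
) -> list[SummaryRow]:
    """Weighted and unweighted group means of the benchmark columns.

    ``weights=None`` uses equal weights, so both mean sets coincide. The
    group's gap category comes from classifying the weighted mean actual
    against the weighted mean interval. Empty groups are omitted with a
    logged warning.
    """
    if not estimates:
        raise ValidationError("cannot aggregate an empty estimate list")
    if weights is None:
        w = np.ones(len(estimates))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(estimates):
            raise ValidationError("weights must align with estimates")

    frame = estimates_to_frame(estimates)
    frame["_w"] = w
    frame["_key"] = [_group_key(e, group_by) for e in estimates]

    keys: list[str]
    if group_by in (None, "none"):
        keys = ["Total"]
    elif group_by == "division":
        keys = list(dict.fromkeys(frame["_key"]))
    else:
        keys = list(dict.fromkeys(frame["_key"]))

    rows = []
    for key in keys:
        grp = frame[frame["_key"] == key]
        if grp.empty or grp["_w"].sum() <= 0:
            msg = f"group {key!r} is empty or has zero weight; omitted"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        gw = grp["_w"].to_numpy()
        weighted = {c: float(np.sum(gw * grp[c].to_numpy()) / gw.sum()) for c in _COLS}
        unweighted = {c: float(grp[c].mean()) for c in _COLS}
        category = classify_gap(weighted["actual"], weighted["ci_low"], weighted["ci_high"])
        rows.append(
            SummaryRow(group=key, n=len(grp), weighted=weighted, unweighted=unweighted, category=category)
        )
    return rows


def estimates_from_published(fixture, region_map: pd.DataFrame | None = None) -> list[BenchmarkEstimate]:
    """Rebuild benchmark estimates from a published-style table.

    Takes the printed actual rate, both model estimates and the interval
    bounds at face value, but *recomputes* every gap category from
    (actual, ci_low, ci_high) — printed labels are never trusted.
    """
    from .data_model import census_region_map  # local import to avoid cycle at module load

    frame = fixture.frame if hasattr(fixture, "frame") else pd.DataFrame(fixture)
    if region_map is None:
        region_map = census_region_map()
    regions = region_map.set_index("state")
    estimates = []
    for _, row in frame.iterrows():
        division = regions["division"].get(row["state"])
        region = regions["region"].get(row["state"])
        estimates.append(
            BenchmarkEstimate(
                name=row["state"],
                actual=float(row["actual"]),
                unadjusted=float(row["unadjusted"]),
                adjusted=float(row["adjusted"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
                category=classify_gap(float(row["actual"]), float(row["ci_low"]), float(row["ci_high"])),
                division=division,
                region=region,
            )
        )
    return estimates


def gap_census(estimates: list[BenchmarkEstimate]) -> dict:
    """Counts (and shares) of units per gap category; counts sum to n."""
    if not estimates:
        raise ValidationError("gap census needs at least one estimate")
    counts = {cat.value: 0 for cat in GapCategory}
    for e in estimates:
        counts[e.category.value] += 1
    n = len(estimates)
    return {
        "counts": counts,
        "shares": {k: v / n for k, v in counts.items()},
        "n": n,
    }
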