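"""Community-mental-health (CMH) composite index and the optimal-CMH scenario.

The composite is the arithmetic mean of three z-standardized per-100,000
service rates: outpatient clients, residential beds and day programs.
Standardization is deliberately *unweighted* across units even though
aggregate reporting elsewhere in the pipeline is population-weighted — the
index describes each unit's service mix relative to its peers, and weighting
enters only at the reporting stage.

The counterfactual scenario value c* is the mean composite of the top
decile of units (five states when n = 50): the level of community services
the what-if projection assumes every unit could reach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import StateTable
from .exceptions import AlignmentError, DegenerateDispersionError, ValidationError

__all__ = ["CmhComposite", "ScenarioValue", "zscore", "composite", "optimal_scenario", "build_composite"]


@dataclass(frozen=True)
class CmhComposite:
    """Per-unit z-scores of the three service rates and their mean."""

    z_outpatient: pd.Series
    z_residential: pd.Series
    z_dayprog: pd.Series
    index: pd.Series  # arithmetic mean of the three z-scores


@dataclass(frozen=True)
class ScenarioValue:
    """Counterfactual CMH index value c* and the top fraction that defines it."""

    value: float
    fraction: float
    k: int  # number of top units averaged


def zscore(values) -> pd.Series:
    """Standardize to unweighted mean 0 and sample SD 1 (denominator n - 1)."""
    s = pd.Series(np.asarray(values, dtype=float))
    if len(s) < 2:
        raise ValidationError("z-standardization needs at least 2 values")
    sd = s.std(ddof=1)
    if not sd > 0:
        raise DegenerateDispersionError(
            "cannot z-standardize a vector with zero dispersion"
        )
    return (s - s.mean()) / sd


def composite(z_out, z_res, z_day) -> pd.Series:
    """Elementwise mean of three aligned z-score vectors."""
    a, b, c = (pd.Series(np.asarray(v, dtype=float)) for v in (z_out, z_res, z_day))
    if not (len(a) == len(b) == len(c)):
        raise AlignmentError(
            f"z-score vectors must align: lengths {len(a)}, {len(b)}, {len(c)}"
        )
    return (a + b + c) / 3.0


def build_composite(table: StateTable) -> CmhComposite:
    """Standardize the three service-rate columns of a table and average them."""
    frame = table.to_frame()
    z_out = zscore(frame["outpatient_rate"])
    z_res = zscore(frame["residential_rate"])
    z_day = zscore(frame["dayprog_rate"])
    idx = composite(z_out, z_res, z_day)
    idx.index = frame["name"]
    return CmhComposite(z_outpatient=z_out, z_residential=z_res, z_dayprog=z_day, index=idx)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def optimal_scenario(composites, fraction: float = 0.10) -> ScenarioValue:
    """Mean composite of the top ``fraction`` of units (c*).

    ``k = round(fraction * n)`` with half rounded away from zero; ties at
    the k-th rank are broken by taking exactly k items after a stable
    descending sort. ``fraction = 1.0`` returns the overall unweighted mean.
    """
    vals = np.asarray(pd.Series(composites), dtype=float)
    if vals.size == 0:
        raise ValidationError("cannot build a scenario from an empty composite vector")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must lie in (0, 1], got {fraction}")
    k = _round_half_away(fraction * vals.size)
    if k < 1:
        raise ValidationError(
            f"fraction {fraction} of {vals.size} units selects no top unit"
        )
    top = np.sort(vals, kind="stable")[::-1][:k]
    return ScenarioValue(value=float(top.mean()), fraction=float(fraction), k=k)
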