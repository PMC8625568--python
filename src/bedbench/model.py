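"""Model/Results interface tying the pipeline together.

:class:`BedNeedModel` is constructed from a state table (or CSV /
DataFrame) and holds the analysis options; :meth:`BedNeedModel.fit`
standardizes the CMH service rates into the composite index, reciprocal-
transforms the bed rates, fits the population-weighted eight-term model
and derives the optimal-CMH scenario value. The returned
:class:`BedNeedResults` carries the coefficient estimates with their
uncertainties, fit diagnostics, and the downstream products: per-unit
counterfactual projections with 95% intervals, gap classification, grouped
rollups and a text summary.

Typical use::

    model = BedNeedModel.from_csv("states.csv")
    res = model.fit()
    print(res.summary())
    bench = res.benchmark_frame()      # per-unit projections + categories
    census = res.gap_census()          # counts per gap category
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import benchmark as _benchmark
from .cmh_index import build_composite, optimal_scenario
from .data_model import StateTable, read_state_table
from .regression import build_design, fit_statistics, fit_wls, population_weights
from .transform import moment_diagnostics

__all__ = ["BedNeedModel", "BedNeedResults"]


class BedNeedModel:
    """Psychiatric bed-need benchmark model for a table of geographic units.

    Parameters
    ----------
    table
        A validated :class:`~bedbench.data_model.StateTable`.
    scenario_fraction
        Top fraction of units whose mean CMH composite defines the
        counterfactual scenario value c* (default 0.10 — the top decile,
        five states out of 50).
    interval
        ``'confidence'`` (mean response, the default — the benchmark is an
        estimate of systematic need) or ``'prediction'`` (adds one unit of
        residual variance).
    weighted
        Weight the fit and the aggregate means by population share
        (default True).
    alpha
        Interval level (default 0.05 for 95% intervals).
    """

    def __init__(
        self,
        table: StateTable,
        scenario_fraction: float = 0.10,
        interval: str = "confidence",
        weighted: bool = True,
        alpha: float = 0.05,
    ):
        self.table = table
        self.scenario_fraction = scenario_fraction
        self.interval = interval
        self.weighted = weighted
        self.alpha = alpha

    @classmethod
    def from_csv(cls, path, schema=None, vintage: str = "2018", **kwargs) -> "BedNeedModel":
        return cls(read_state_table(path, schema=schema, vintage=vintage), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, vintage: str = "2018", **kwargs) -> "BedNeedModel":
        return cls(StateTable.from_frame(frame, vintage=vintage), **kwargs)

    def fit(self) -> "BedNeedResults":
        composites = build_composite(self.table)
        X, y_prime = build_design(self.table, composites)
        weights = (
            population_weights([r.population for r in self.table]) if self.weighted else None
        )
        fitted = fit_wls(X, y_prime, weights=weights)
        scenario = optimal_scenario(composites.index, fraction=self.scenario_fraction)
        return BedNeedResults(self, fitted, composites, scenario, y_prime)


class BedNeedResults:
    """Results of a fitted bed-need model."""

    def __init__(self, model, fitted_model, composites, scenario, y_prime):
        self.model = model
        self.fitted_model = fitted_model
        self.composites = composites
        self.scenario = scenario
        self.y_prime = y_prime
        self._estimates = None

    # -- statsmodels-flavoured accessors ---------------------------------
    @property
    def params(self) -> pd.Series:
        return self.fitted_model.params

    @property
    def bse(self) -> pd.Series:
        return self.fitted_model.bse

    @property
    def tvalues(self) -> pd.Series:
        return self.fitted_model.tvalues

    @property
    def pvalues(self) -> pd.Series:
        return self.fitted_model.pvalues

    @property
    def rsquared(self) -> float:
        return self.fitted_model.rsquared

    @property
    def rsquared_adj(self) -> float:
        return self.fitted_model.rsquared_adj

    def outcome_diagnostics(self):
        """Corrected skewness/kurtosis of the reciprocal-scale outcome."""
        return moment_diagnostics(self.y_prime.to_numpy())

    # -- projections ------------------------------------------------------
    def project(self, scenario=None) -> list:
        """Per-unit benchmark estimates under the optimal-CMH scenario."""
        scenario = scenario if scenario is not None else self.scenario
        estimates = []
        comp = self.composites.index
        for record in self.model.table:
            estimates.append(
                _benchmark.project_unit(
                    self.fitted_model,
                    record,
                    float(comp.loc[record.name]),
                    scenario=scenario,
                    interval=self.model.interval,
                    alpha=self.model.alpha,
                )
            )
        return estimates

    def _cached_estimates(self):
        if self._estimates is None:
            self._estimates = self.project()
        return self._estimates

    def benchmark_frame(self) -> pd.DataFrame:
        """Benchmark table mirroring the published per-state column order."""
        return _benchmark.estimates_to_frame(self._cached_estimates())

    def aggregate(self, group_by=None) -> list:
        weights = (
            [r.population for r in self.model.table] if self.model.weighted else None
        )
        return _benchmark.aggregate(self._cached_estimates(), weights=weights, group_by=group_by)

    def summary_rows_frame(self, group_by=None) -> pd.DataFrame:
        rows = self.aggregate(group_by=group_by)
        recs = []
        for r in rows:
            rec = {"group": r.group, "n": r.n, "category": r.category.value}
            rec.update({f"w_{k}": v for k, v in r.weighted.items()})
            rec.update({f"u_{k}": v for k, v in r.unweighted.items()})
            recs.append(rec)
        return pd.DataFrame(recs)

    def gap_census(self) -> dict:
        return _benchmark.gap_census(self._cached_estimates())

    # -- reports ----------------------------------------------------------
    def fit_report(self) -> dict:
        """JSON-ready fit report: coefficient block plus equation statistics."""
        fm = self.fitted_model
        coef = {
            term: {
                "b": float(fm.params[term]),
                "se": float(fm.bse[term]),
                "t": float(fm.tvalues[term]) if np.isfinite(fm.tvalues[term]) else None,
                "p": float(fm.pvalues[term]) if np.isfinite(fm.pvalues[term]) else None,
                "beta": None if pd.isna(fm.std_betas[term]) else float(fm.std_betas[term]),
                "partial_r": None if pd.isna(fm.partial_r[term]) else float(fm.partial_r[term]),
            }
            for term in fm.exog_names
        }
        diag = self.outcome_diagnostics()
        stats_block = fit_statistics(fm)
        stats_block = {
            k: (None if isinstance(v, float) and not np.isfinite(v) else v)
            for k, v in stats_block.items()
        }
        return {
            "n": fm.nobs,
            "weighted": self.model.weighted,
            "interval": self.model.interval,
            "scenario": {
                "fraction": self.scenario.fraction,
                "k": self.scenario.k,
                "cmh_star": self.scenario.value,
            },
            "coefficients": coef,
            "equation_statistics": stats_block,
            "outcome_diagnostics": {
                "skewness": diag.skewness,
                "se_skewness": diag.se_skewness,
                "kurtosis": diag.kurtosis,
                "se_kurtosis": diag.se_kurtosis,
            },
        }

    def summary(self) -> str:
        """Human-readable fit summary (coefficients + equation statistics)."""
        fm = self.fitted_model
        lines = []
        lines.append("Psychiatric bed-need benchmark model")
        lines.append("=" * 64)
        lines.append(
            f"Units: {fm.nobs}    outcome: 1 / (beds per 100,000)    "
            f"weights: {'population' if self.model.weighted else 'equal'}"
        )
        lines.append(
            f"Scenario: top {self.scenario.fraction:.0%} of units (k = {self.scenario.k}), "
            f"c* = {self.scenario.value:.4f}"
        )
        lines.append("-" * 64)
        lines.append(fm.summary_frame().to_string(float_format=lambda v: f"{v: .5g}"))
        lines.append("-" * 64)
        st = fit_statistics(fm)
        lines.append(
            f"R2 = {st['r_squared']:.4f}   adj R2 = {st['adj_r_squared']:.4f}   "
            f"F({st['df_model']}, {st['df_resid']}) = {st['f']:.4g}   p = {st['p']:.4g}"
        )
        lines.append(
            f"mean Cook distance = {st['mean_cooks_distance']:.4g}   "
            f"unexplained share (1 - adj R2) = {st['unexplained_share']:.3f}"
        )
        lines.append(
            "Note: negative coefficients represent positive associations with the"
        )
        lines.append("bed rate (reciprocal outcome) and vice versa.")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.fit_report(), fh, indent=2)
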