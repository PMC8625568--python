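"""Population-weighted polynomial least squares on the reciprocal-rate scale.

The design has eight terms: intercept, disability proportion d and d^2, the
CMH composite c with c^2 and c^3, percent married m, and life expectancy l.
The outcome is the reciprocal bed rate y' = 1/(beds per 100,000), so a
*negative* coefficient corresponds to a *positive* association with the bed
rate itself.

Units are weighted by relative population share; weights are normalized to
sum to n so degrees-of-freedom accounting matches the unweighted
convention (frequency-weight behaviour). Fitting is delegated to
statsmodels WLS; this module adds the design construction, the fit-report
statistics (standardized betas, partial correlations, mean Cook distance)
and mean-response / prediction standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cmh_index import CmhComposite
from .data_model import StateTable
from .exceptions import (
    AlignmentError,
    SingularDesignError,
    UndefinedStatisticError,
    ValidationError,
)
from .transform import inverse_transform

__all__ = [
    "TERMS",
    "FittedModel",
    "design_row",
    "build_design",
    "population_weights",
    "fit_wls",
    "fit_statistics",
    "predict_with_se",
]

#: The eight design terms, in canonical order.
TERMS = (
    "const",
    "disability",
    "disability_sq",
    "cmh",
    "cmh_sq",
    "cmh_cu",
    "married",
    "life_expectancy",
)


def design_row(disability: float, cmh: float, married: float, life_expectancy: float) -> pd.Series:
    """One design row; the polynomial terms are exact powers of their bases."""
    return pd.Series(
        {
            "const": 1.0,
            "disability": disability,
            "disability_sq": disability**2,
            "cmh": cmh,
            "cmh_sq": cmh**2,
            "cmh_cu": cmh**3,
            "married": married,
            "life_expectancy": life_expectancy,
        },
        index=list(TERMS),
        dtype=float,
    )


def build_design(table: StateTable, composites) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix and reciprocal outcome for a state table.

    ``composites`` is the per-unit CMH index, either a plain vector aligned
    with the table order or a :class:`~bedbench.cmh_index.CmhComposite`.
    """
    if isinstance(composites, CmhComposite):
        composites = composites.index  # the composite Series
    c = np.asarray(pd.Series(composites), dtype=float)
    frame = table.to_frame()
    if len(c) != len(frame):
        raise AlignmentError(
            f"composites (len {len(c)}) must align with table (len {len(frame)})"
        )
    X = pd.DataFrame(
        [
            design_row(row.disability_pct, c[i], row.married_pct, row.life_expectancy)
            for i, row in enumerate(frame.itertuples())
        ],
        index=frame["name"],
    )
    y_prime = pd.Series(inverse_transform(frame["bed_rate"].to_numpy()), index=frame["name"], name="y_prime")
    return X, y_prime


def population_weights(populations) -> np.ndarray:
    """Weights proportional to population share, normalized to sum to n."""
    p = np.asarray(populations, dtype=float)
    if np.any(p < 0):
        raise ValidationError("populations must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValidationError("total population must be positive")
    return p * (len(p) / total)


@dataclass
class FittedModel:
    """A fitted weighted least-squares model on the reciprocal-rate scale."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    std_betas: pd.Series
    partial_r: pd.Series
    scale: float  # residual variance s^2 = RSS_w / (n - 8)
    xtwx_inv: np.ndarray  # (X'WX)^{-1}
    nobs: int
    df_model: int  # number of non-intercept terms (7)
    df_resid: int
    rsquared: float
    rsquared_adj: float
    fvalue: float
    f_pvalue: float
    weights: np.ndarray
    resid: pd.Series
    fittedvalues: pd.Series
    mean_cooks_distance: float
    mean_std_resid: float
    exog_names: tuple = field(default=TERMS)

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient block of the fit report."""
        return pd.DataFrame(
            {
                "b": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "beta": self.std_betas,
                "partial_r": self.partial_r,
            }
        )


def _check_rank(Xw: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(Xw)
    if rank >= Xw.shape[1]:
        return
    # name columns that lie (numerically) in the span of the others
    collinear = []
    for j in range(Xw.shape[1]):
        others = np.delete(Xw, j, axis=1)
        proj, *_ = np.linalg.lstsq(others, Xw[:, j], rcond=None)
        resid = Xw[:, j] - others @ proj
        norm = np.linalg.norm(Xw[:, j])
        if np.linalg.norm(resid) <= 1e-8 * max(norm, 1.0):
            collinear.append(names[j])
    raise SingularDesignError(
        f"design matrix is rank deficient (rank {rank} < {Xw.shape[1]}); "
        f"collinear columns: {collinear}",
        collinear_columns=collinear,
    )


def _weighted_sd(x: np.ndarray, w: np.ndarray) -> float:
    # frequency-weight convention with weights summing to n
    wsum = w.sum()
    mean = np.sum(w * x) / wsum
    return float(np.sqrt(np.sum(w * (x - mean) ** 2) / (wsum - 1.0)))


def fit_wls(X, y_prime, weights=None) -> FittedModel:
    """Fit the eight-term model by weighted least squares.

    ``weights=None`` means equal weights (ordinary least squares). Weights
    are rescaled to sum to n, so doubling all weights changes nothing.
    """
    X = pd.DataFrame(X)
    y = pd.Series(y_prime)
    n, p_total = X.shape
    if len(y) != n:
        raise AlignmentError(f"outcome (len {len(y)}) must align with design ({n} rows)")
    if n <= p_total:
        raise ValidationError(
            f"need more units than design terms: n = {n}, terms = {p_total}"
        )
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != n:
            raise AlignmentError("weights must align with the design rows")
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        if np.count_nonzero(w) < p_total:
            raise ValidationError(
                f"need at least {p_total} strictly positive weights"
            )
        w = w * (n / w.sum())

    Xv = X.to_numpy(dtype=float)
    sw = np.sqrt(w)
    _check_rank(Xv * sw[:, None], list(X.columns))

    res = sm.WLS(y.to_numpy(dtype=float), Xv, weights=w).fit()

    params = pd.Series(res.params, index=X.columns)
    fitted = pd.Series(Xv @ res.params, index=y.index)
    resid = y.astype(float) - fitted
    df_resid = n - p_total
    rss = float(np.sum(w * resid.to_numpy() ** 2))
    scale = rss / df_resid

    ybar_w = float(np.sum(w * y.to_numpy()) / w.sum())
    tss = float(np.sum(w * (y.to_numpy() - ybar_w) ** 2))
    # relative guard: a numerically constant outcome has tss at rounding level
    if tss <= 1e-14 * max(float(np.sum(w * y.to_numpy() ** 2)), np.finfo(float).tiny):
        raise UndefinedStatisticError("outcome has zero weighted variance; R^2 undefined")
    rsq = 1.0 - rss / tss
    df_model = p_total - 1
    rsq_adj = 1.0 - (1.0 - rsq) * (n - 1) / df_resid
    if rss == 0.0 or rsq >= 1.0:  # numerically perfect fit
        fvalue, f_pvalue = np.inf, 0.0
    else:
        fvalue = (rsq / df_model) / ((1.0 - rsq) / df_resid)
        f_pvalue = float(stats.f.sf(fvalue, df_model, df_resid))

    xtwx_inv = np.asarray(res.normalized_cov_params)
    bse = pd.Series(np.sqrt(np.maximum(scale * np.diag(xtwx_inv), 0.0)), index=X.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = params / bse
    pvals = pd.Series(2.0 * stats.t.sf(np.abs(tvals.to_numpy()), df_resid), index=X.columns)

    sd_y = _weighted_sd(y.to_numpy(), w)
    betas, partials = {}, {}
    for col in X.columns:
        if np.allclose(Xv[:, list(X.columns).index(col)], Xv[0, list(X.columns).index(col)]):
            betas[col] = np.nan  # constant column (intercept)
            partials[col] = np.nan
            continue
        sd_x = _weighted_sd(X[col].to_numpy(dtype=float), w)
        betas[col] = params[col] * sd_x / sd_y if sd_y > 0 else np.nan
        t = tvals[col]
        partials[col] = float(t / np.sqrt(t * t + df_resid)) if np.isfinite(t) else np.nan

    # mean Cook distance and mean standardized residual on the whitened design
    Xw = Xv * sw[:, None]
    h = np.einsum("ij,jk,ik->i", Xw, xtwx_inv, Xw)
    ew = sw * resid.to_numpy()
    if scale > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            r_int = ew / np.sqrt(scale * (1.0 - h))
            cooks = r_int**2 * h / (p_total * (1.0 - h))
        mean_cooks = float(np.nanmean(cooks))
        mean_std_resid = float(np.nanmean(ew / np.sqrt(scale)))
    else:
        mean_cooks = 0.0
        mean_std_resid = 0.0

    return FittedModel(
        params=params,
        bse=bse,
        tvalues=pd.Series(tvals, index=X.columns),
        pvalues=pvals,
        std_betas=pd.Series(betas),
        partial_r=pd.Series(partials),
        scale=scale,
        xtwx_inv=xtwx_inv,
        nobs=n,
        df_model=df_model,
        df_resid=df_resid,
        rsquared=rsq,
        rsquared_adj=rsq_adj,
        fvalue=fvalue,
        f_pvalue=f_pvalue,
        weights=w,
        resid=resid,
        fittedvalues=fitted,
        mean_cooks_distance=mean_cooks,
        mean_std_resid=mean_std_resid,
        exog_names=tuple(X.columns),
    )


def fit_statistics(model: FittedModel) -> dict:
    """Equation-level statistics of a fitted model."""
    return {
        "r": float(np.sqrt(max(model.rsquared, 0.0))),
        "r_squared": model.rsquared,
        "adj_r_squared": model.rsquared_adj,
        "f": model.fvalue,
        "p": model.f_pvalue,
        "df_model": model.df_model,
        "df_resid": model.df_resid,
        "mean_cooks_distance": model.mean_cooks_distance,
        "mean_standardized_residual": model.mean_std_resid,
        "unexplained_share": 1.0 - model.rsquared_adj,
    }


def predict_with_se(model: FittedModel, x, interval: str = "confidence") -> tuple[float, float]:
    """Fitted value x'B and its standard error on the transformed scale.

    ``interval='confidence'`` returns the SE of the mean response,
    sqrt(s^2 x'(X'WX)^{-1} x); ``'prediction'`` adds one unit of residual
    variance, sqrt(s^2 (1 + x'(X'WX)^{-1} x)).
    """
    xv = np.asarray(pd.Series(x).reindex(model.exog_names) if hasattr(x, "index") else x, dtype=float)
    if xv.shape != (len(model.exog_names),):
        raise ValidationError(
            f"design row must have {len(model.exog_names)} terms, got shape {xv.shape}"
        )
    if np.any(np.isnan(xv)):
        raise ValidationError("design row has missing terms")
    fitted = float(xv @ model.params.to_numpy())
    leverage = float(xv @ model.xtwx_inv @ xv)
    if interval == "confidence":
        se = float(np.sqrt(model.scale * leverage))
    elif interval == "prediction":
        se = float(np.sqrt(model.scale * (1.0 + leverage)))
    else:
        raise ValidationError(f"interval must be 'confidence' or 'prediction', got {interval!r}")
    return fitted, se
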