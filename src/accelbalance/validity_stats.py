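"""Repeated-measures validity statistics for paired EI (or EE) estimates.

Each participant contributes one or more measurement occasions, so all
mean statistics come from null (intercept-only) linear mixed models with
a random participant intercept, fitted by REML: the fixed intercept is
the mean bias / MAE / MAPE accounting for repeat testing, and p-values
across the metric x method family are adjusted by the Benjamini-Hochberg
false-discovery-rate step-up.

Agreement is summarised with repeated-measures Bland-Altman statistics:
limits of agreement ``mean bias ± 1.96 * SD`` where SD is the total SD of
the random effects, sqrt(between² + residual²), plus a mixed model of
bias on the criterion (fixed slope, random participant intercept) whose
slope, marginal R² and conditional R² quantify systematic error.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

LOA_Z = 1.96


@dataclasses.dataclass
class MixedFit:
    """A null random-intercept fit: mean, uncertainty, variance partition."""

    intercept: float
    se: float
    sd_between: float
    sd_resid: float
    p_raw: float
    p_fdr: float | None
    n_participants: int
    n_occasions: int


@dataclasses.dataclass
class ValiditySummary:
    """Per-method agreement summary versus the criterion."""

    method: str
    mean_bias: float
    mae: float
    mape: float
    loa_low: float
    loa_high: float
    ba_slope: float  # nan when the criterion is constant
    r2_marginal: float
    r2_conditional: float


def occasion_errors(
    predicted: np.ndarray,
    criterion: np.ndarray,
    participant: np.ndarray,
    occasion: np.ndarray | None = None,
    method: str = "",
) -> pd.DataFrame:
    """Per-occasion error metrics against the criterion.

    bias = predicted − criterion; abs_error = |bias|;
    pct_error = abs_error / criterion × 100 (criterion must be > 0).
    """
    predicted = np.asarray(predicted, dtype=float)
    criterion = np.asarray(criterion, dtype=float)
    participant = np.asarray(participant)
    if not (len(predicted) == len(criterion) == len(participant)):
        raise ValueError("predicted, criterion and participant must align")
    if np.any(criterion <= 0):
        raise ValueError("criterion values must be positive")
    bias = predicted - criterion
    abs_error = np.abs(bias)
    return pd.DataFrame(
        {
            "participant": participant,
            "occasion": occasion if occasion is not None else np.arange(len(bias)),
            "method": method,
            "predicted": predicted,
            "criterion": criterion,
            "bias": bias,
            "abs_error": abs_error,
            "pct_error": abs_error / criterion * 100.0,
        }
    )


def _fit_mixedlm(y: np.ndarray, exog: np.ndarray, groups: np.ndarray):
    """REML fit with a conjugate-gradient pass followed by a tight BFGS
    refinement; the refinement brings interior solutions to the precision
    of the closed-form balanced-design estimator."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups)
        last_exc: Exception | None = None
        for first in ("cg", "powell"):
            try:
                res = model.fit(reml=True, method=first, maxiter=2000)
                return model.fit(reml=True, method="bfgs", gtol=1e-13,
                                 maxiter=2000, start_params=res.params_object)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        raise last_exc


def _moment_null_fit(values: np.ndarray, participant: np.ndarray) -> MixedFit:
    """Method-of-moments one-way variance-component fit (ANOVA estimator).

    Closed-form fallback for designs the iterative REML fit cannot handle
    (tiny cohorts, zero within-participant variance).  On balanced data
    with MSB > MSW it coincides with REML.
    """
    df = pd.DataFrame({"y": values, "g": participant})
    k = df["g"].nunique()
    n_total = len(df)
    sizes = df.groupby("g").size().to_numpy(dtype=float)
    means = df.groupby("g")["y"].mean().to_numpy()
    grand = float(np.average(means, weights=sizes))

    if n_total > k:
        ssw = float(((df["y"] - df.groupby("g")["y"].transform("mean")) ** 2).sum())
        msw = ssw / (n_total - k)
    else:
        msw = 0.0  # one occasion per participant: no within variance observable
    msb = float((sizes * (means - grand) ** 2).sum() / (k - 1))
    n0 = (n_total - (sizes**2).sum() / n_total) / (k - 1)
    var_b = max((msb - msw) / n0, 0.0) if n0 > 0 else 0.0

    weights = 1.0 / (var_b + msw / sizes) if (var_b > 0 or msw > 0) else np.ones(k)
    mean_gls = float(np.average(means, weights=weights))
    se = float(1.0 / np.sqrt(weights.sum())) if (var_b > 0 or msw > 0) else 0.0
    p = float(2.0 * scipy.stats.norm.sf(abs(mean_gls / se))) if se > 0 else float("nan")
    return MixedFit(
        intercept=mean_gls, se=se, sd_between=float(np.sqrt(var_b)),
        sd_resid=float(np.sqrt(msw)), p_raw=p, p_fdr=None,
        n_participants=int(k), n_occasions=int(n_total),
    )


def fit_null_random_intercept(
    values: np.ndarray, participant: np.ndarray
) -> MixedFit:
    """REML fit of an intercept-only model with a random participant
    intercept.

    Returns the grand mean (fixed intercept), its SE, the
    between-participant and residual SDs, and a two-sided p-value for the
    mean via the large-sample normal approximation on mean/SE.
    """
    values = np.asarray(values, dtype=float)
    participant = np.asarray(participant)
    uniq = pd.unique(participant)
    if len(uniq) < 2:
        raise ValueError("need at least 2 participants for a random intercept")
    n = len(values)
    if np.ptp(values) == 0.0:
        # degenerate: no variance to partition
        return MixedFit(
            intercept=float(values[0]), se=0.0, sd_between=0.0, sd_resid=0.0,
            p_raw=float("nan"), p_fdr=None,
            n_participants=len(uniq), n_occasions=n,
        )
    counts = pd.Series(participant).groupby(pd.Series(participant)).size()
    within = pd.DataFrame({"y": values, "g": participant}).groupby("g")["y"]
    degenerate_within = (counts.max() == counts.min() == 1) or within.var().fillna(0).max() == 0
    if not degenerate_within:
        try:
            res = _fit_mixedlm(values, np.ones((n, 1)), participant)
            intercept = float(res.fe_params[0])
            se = float(res.bse_fe[0])
            sd_between = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
            sd_resid = float(np.sqrt(max(res.scale, 0.0)))
            if np.isfinite(intercept) and np.isfinite(se) and se > 0:
                p = float(2.0 * scipy.stats.norm.sf(abs(intercept / se)))
                return MixedFit(
                    intercept=intercept, se=se, sd_between=sd_between,
                    sd_resid=sd_resid, p_raw=p, p_fdr=None,
                    n_participants=len(uniq), n_occasions=n,
                )
        except (np.linalg.LinAlgError, ValueError):
            pass
    return _moment_null_fit(values, participant)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bland_altman_rm(errors: pd.DataFrame, method: str | None = None) -> ValiditySummary:
    """Repeated-measures Bland-Altman summary from an occasion-error table.

    ``errors`` must carry participant, bias, abs_error, pct_error and
    criterion columns (as produced by :func:`occasion_errors`).

    * mean bias / MAE / MAPE are the intercepts of null random-intercept
      fits of the three metrics;
    * limits of agreement are mean bias ± 1.96 × sqrt(sd_between² +
      sd_resid²) from the bias fit — the total SD, so the limits bound
      individual occasions rather than participant means;
    * the slope model regresses bias on the criterion (fixed effect) with
      a random participant intercept; marginal R² is the fixed-effect
      fitted-value variance over the total variance, conditional R² adds
      the between-participant variance to the numerator.

    A constant criterion leaves the slope undefined; it is returned as
    NaN with a warning.
    """
    bias_fit = fit_null_random_intercept(errors["bias"].to_numpy(),
                                         errors["participant"].to_numpy())
    mae_fit = fit_null_random_intercept(errors["abs_error"].to_numpy(),
                                        errors["participant"].to_numpy())
    mape_fit = fit_null_random_intercept(errors["pct_error"].to_numpy(),
                                         errors["participant"].to_numpy())
    sd_total = float(np.hypot(bias_fit.sd_between, bias_fit.sd_resid))
    loa_low = bias_fit.intercept - LOA_Z * sd_total
    loa_high = bias_fit.intercept + LOA_Z * sd_total

    criterion = errors["criterion"].to_numpy(dtype=float)
    bias = errors["bias"].to_numpy(dtype=float)
    groups = errors["participant"].to_numpy()
    if np.ptp(criterion) == 0.0:
        warnings.warn("criterion is constant; Bland-Altman slope undefined")
        slope, r2m, r2c = float("nan"), 0.0, 0.0
        if np.ptp(bias) > 0:
            fit = fit_null_random_intercept(bias, groups)
            denom = fit.sd_between**2 + fit.sd_resid**2
            r2c = fit.sd_between**2 / denom if denom > 0 else 0.0
    else:
        exog = np.column_stack([np.ones(len(bias)), criterion])
        if np.ptp(bias) <= 1e-9 * max(1.0, float(np.abs(bias).max())):
            slope, r2m, r2c = 0.0, 0.0, 0.0
        else:
            try:
                res = _fit_mixedlm(bias, exog, groups)
                fe = np.asarray(res.fe_params)
                var_between = float(np.asarray(res.cov_re)[0, 0])
                var_resid = float(res.scale)
                if not (np.all(np.isfinite(fe)) and np.isfinite(var_between)):
                    raise ValueError("non-finite mixed-model estimates")
            except (np.linalg.LinAlgError, ValueError):
                # closed-form fallback: OLS slope, residual variance split by
                # the one-way moment estimator on the OLS residuals
                fe, *_ = np.linalg.lstsq(exog, bias, rcond=None)
                resid_fit = _moment_null_fit(bias - exog @ fe, groups)
                var_between = resid_fit.sd_between**2
                var_resid = resid_fit.sd_resid**2
            slope = float(fe[1])
            var_fixed = float(np.var(exog @ fe))
            denom = var_fixed + var_between + var_resid
            r2m = var_fixed / denom if denom > 0 else 0.0
            r2c = (var_fixed + var_between) / denom if denom > 0 else 0.0

    name = method if method is not None else str(errors["method"].iloc[0])
    return ValiditySummary(
        method=name,
        mean_bias=bias_fit.intercept,
        mae=mae_fit.intercept,
        mape=mape_fit.intercept,
        loa_low=loa_low,
        loa_high=loa_high,
        ba_slope=slope,
        r2_marginal=r2m,
        r2_conditional=r2c,
    )


def run_validity_suite(
    estimates: pd.DataFrame, criterion: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full validity analysis for a table of EI estimates.

    Parameters
    ----------
    estimates : DataFrame with columns participant, occasion, method, ei
    criterion : DataFrame with columns participant, occasion, criterion_ei

    Returns
    -------
    (summaries, fits) : one ValiditySummary row per method, and one
    MixedFit row per method x metric with FDR-adjusted p-values over the
    whole family of fitted mean models.
    """
    merged = estimates.merge(criterion, on=["participant", "occasion"], how="inner")
    if merged.empty:
        raise ValueError("no overlapping participant-occasions")

    fits: list[dict] = []
    summaries: list[ValiditySummary] = []
    for method, grp in merged.groupby("method", sort=True):
        err = occasion_errors(
            grp["ei"].to_numpy(),
            grp["criterion_ei"].to_numpy(),
            grp["participant"].to_numpy(),
            grp["occasion"].to_numpy(),
            method=str(method),
        )
        summaries.append(bland_altman_rm(err, method=str(method)))
        for metric in ("bias", "abs_error", "pct_error"):
            fit = fit_null_random_intercept(err[metric].to_numpy(),
                                            err["participant"].to_numpy())
            fits.append({"method": method, "metric": metric,
                         **dataclasses.asdict(fit)})

    fits_df = pd.DataFrame(fits)
    p = fits_df["p_raw"].to_numpy()
    ok = np.isfinite(p)
    adj = np.full(len(p), np.nan)
    if ok.any():
        adj[ok] = fdr_adjust(p[ok])
    fits_df["p_fdr"] = adj

    summaries_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    return summaries_df, fits_df
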