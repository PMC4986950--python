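"""Ensemble LASSO attribution of FS - FSL prediction differences.

The response is the per-site difference in predicted flame height between
the structure-only (FS) and fully specified (FSL) treatments. Twelve
continuous predictors represent the three model mechanisms — donor
flammability (delta donor flame height, FS donor flame height), receiver
ignitability (mean IC under FSL) and overstorey sheltering (LAI sums and
deltas) — plus exogenous and structural covariates (wind, DFMC, slope,
vertical continuity, surface fine fuel).

An L1-penalised linear model is fitted over a descending penalty path with
the penalty chosen by random k-fold cross-validation under either the
minimum-error ("min") rule or the one-standard-error ("1se") rule. Because
fold allocation is random, secondary predictors come and go between runs;
the ensemble repeats the fit under many fold allocations and reports each
predictor's inclusion frequency and coefficient statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .domain import SiteStructure, WeatherRecord
from .treatments import PredictionRecord

__all__ = [
    "PREDICTORS",
    "RESPONSE",
    "build_predictors",
    "vertical_continuity",
    "lasso_cv_fit",
    "LassoFit",
    "ensemble",
]

PREDICTORS = (
    "delta_donor_fh",
    "donor_fh_fs",
    "mean_ic_fsl",
    "sum_lai_fs",
    "delta_sum_lai",
    "canopy_lai_fs",
    "delta_canopy_lai",
    "wind_velocity",
    "dfmc",
    "slope",
    "vertical_continuity",
    "surface_fine_fuel",
)

RESPONSE = "fs_minus_fsl_flame_height"


def vertical_continuity(site: SiteStructure) -> float:
    """Vertical fuel continuity of a stand.

    The negated sum of the air gaps between successive occupied strata
    (crown base of the upper minus crown top of the lower, floored at 0),
    so larger values mean a more continuous fuel ladder. Zero for one or no
    strata. A provisional structural covariate.
    """
    present = site.present()
    gaps = 0.0
    for lower, upper in zip(present, present[1:]):
        gaps += max(0.0, upper.crown_base_centre_height - lower.crown_height)
    return -gaps


def _donor_fh(record: PredictionRecord, site: SiteStructure) -> float:
    """Donor flame height for a site: the tallest donor flame below the
    highest receiver stratum (the surface counts as a donor)."""
    present = site.present()
    if not present:
        return float(record.donor_flame_heights.get("surface", 0.0))
    top = present[-1].stratum
    values = [
        v
        for k, v in record.donor_flame_heights.items()
        if k == "surface" or k != top.value
    ]
    return float(max(values, default=0.0))


def build_predictors(
    fs_records: Sequence[PredictionRecord],
    fsl_records: Sequence[PredictionRecord],
    sites: Mapping[str, SiteStructure],
    weather: Mapping[str, WeatherRecord],
) -> pd.DataFrame:
    """Assemble the predictor matrix plus response, one row per site.

    Deltas are FS value minus FSL value, except ``delta_canopy_lai`` which
    is canopy LAI in FSL minus canopy LAI in FS (matching its definition).
    """
    fs_by_site = {r.site_id: r for r in fs_records}
    fsl_by_site = {r.site_id: r for r in fsl_records}
    if set(fs_by_site) != set(fsl_by_site):
        raise ValueError("FS and FSL records cover different site sets")
    rows = []
    for sid in sorted(fs_by_site):
        fs, fsl = fs_by_site[sid], fsl_by_site[sid]
        site, wx = sites[sid], weather[sid]
        rows.append(
            {
                "site_id": sid,
                "delta_donor_fh": _donor_fh(fs, site) - _donor_fh(fsl, site),
                "donor_fh_fs": _donor_fh(fs, site),
                "mean_ic_fsl": fsl.mean_ic,
                "sum_lai_fs": fs.sum_lai,
                "delta_sum_lai": fs.sum_lai - fsl.sum_lai,
                "canopy_lai_fs": fs.canopy_lai,
                "delta_canopy_lai": fsl.canopy_lai - fs.canopy_lai,
                "wind_velocity": wx.wind_velocity,
                "dfmc": wx.dfmc,
                "slope": wx.slope,
                "vertical_continuity": vertical_continuity(site),
                "surface_fine_fuel": site.surface_fuel_load,
                RESPONSE: fs.predicted_flame_height - fsl.predicted_flame_height,
            }
        )
    df = pd.DataFrame(rows)
    if df[list(PREDICTORS) + [RESPONSE]].isna().any().any():
        raise ValueError("predictor matrix contains missing cells")
    return df


@dataclass(frozen=True)
class LassoFit:
    """One selected model: coefficients on the original predictor scale."""

    coefficients: np.ndarray  # aligned with PREDICTORS
    intercept: float
    alpha: float
    rule: str


def _alpha_path(Xs: np.ndarray, yc: np.ndarray, n_alphas: int = 100, ratio: float = 1e-3):
    n = Xs.shape[0]
    alpha_max = float(np.max(np.abs(Xs.T @ yc)) / n)
    if alpha_max <= 0:
        return None
    return np.geomspace(alpha_max, alpha_max * ratio, n_alphas)


def lasso_cv_fit(
    matrix: pd.DataFrame,
    k: int = 10,
    rule: str = "min",
    seed: int | None = None,
) -> LassoFit:
    """L1-penalised fit with the penalty chosen by k-fold cross-validation.

    Predictors are standardised (mean 0, sd 1) before fitting; reported
    coefficients are back-transformed to the original predictor scale.
    ``rule='min'`` takes the penalty minimising cross-validated error;
    ``rule='1se'`` takes the most parsimonious model (largest penalty)
    whose error is within one standard error of that minimum. Fold
    allocation is random from ``seed``. A constant response yields the
    all-zero model.
    """
    if rule not in ("min", "1se"):
        raise ValueError(f"unknown rule {rule!r}")
    X = matrix[list(PREDICTORS)].to_numpy(float)
    y = matrix[RESPONSE].to_numpy(float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n <= k:
        raise ValueError("need more sites than folds")
    x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Xs = (X - x_mean) / x_sd
    y_mean = y.mean()
    yc = y - y_mean
    alphas = _alpha_path(Xs, yc)
    if alphas is None or np.allclose(yc, 0.0):
        return LassoFit(np.zeros(len(PREDICTORS)), float(y_mean), 0.0, rule)

    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    mse = np.empty((k, alphas.size))
    for i, (train, test) in enumerate(folds.split(Xs)):
        _, coefs, _ = lasso_path(Xs[train], yc[train], alphas=alphas)
        pred = Xs[test] @ coefs  # (n_test, n_alphas)
        resid = pred - yc[test][:, None]
        mse[i] = np.mean(resid ** 2, axis=0)
    cv_mean = mse.mean(axis=0)
    cv_se = mse.std(axis=0, ddof=1) / np.sqrt(k)
    i_min = int(np.argmin(cv_mean))
    if rule == "min":
        i_sel = i_min
    else:
        threshold = cv_mean[i_min] + cv_se[i_min]
        # alphas descend, so the first qualifying index is the largest penalty
        i_sel = int(np.nonzero(cv_mean <= threshold)[0][0])
    alpha = float(alphas[i_sel])
    _, coefs_full, _ = lasso_path(Xs, yc, alphas=alphas[: i_sel + 1])
    beta_std = coefs_full[:, -1]
    beta = beta_std / x_sd
    intercept = float(y_mean - beta @ x_mean)
    return LassoFit(beta, intercept, alpha, rule)


def ensemble(
    matrix: pd.DataFrame,
    n_runs: int = 1000,
    k: int = 10,
    rule: str = "min",
    base_seed: int = 0,
) -> pd.DataFrame:
    """Repeat the cross-validated LASSO under ``n_runs`` independent random
    fold allocations and summarise each predictor.

    Returns a frame with one row per predictor: ``n_included`` (runs in
    which its coefficient was nonzero), and the mean, 2.5% and 97.5%
    quantiles of its coefficient over the runs that included it, on the
    original predictor scale. Reproducible bit-for-bit from ``base_seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    coefs = np.empty((n_runs, len(PREDICTORS)))
    for i, seed in enumerate(seeds):
        coefs[i] = lasso_cv_fit(matrix, k=k, rule=rule, seed=int(seed)).coefficients
    rows = []
    for j, name in enumerate(PREDICTORS):
        included = coefs[:, j][coefs[:, j] != 0.0]
        rows.append(
            {
                "predictor": name,
                "n_included": int(included.size),
                "mean_coef": float(included.mean()) if included.size else 0.0,
                "q2.5": float(np.quantile(included, 0.025)) if included.size else 0.0,
                "q97.5": float(np.quantile(included, 0.975)) if included.size else 0.0,
            }
        )
    return pd.DataFrame(rows)
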