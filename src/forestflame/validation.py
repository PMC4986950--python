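"""Error statistics against observed flame-height intervals.

Field observations bound the true flame height between the height of
combustion (below) and the scorch height or base of the next unconsumed
stratum (above), with a median point estimate. Signed and absolute errors
are measured against the median; a prediction is *correct* when it falls
inside the interval (bounds inclusive). PCP is the proportion of correct
predictions over all sites and PCP1 the same over sites whose observed
flame reached at least 1 m. Treatments are compared with paired t-tests on
per-site absolute errors or correctness indicators.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .domain import ObservedFlameInterval, ValidationError

__all__ = [
    "build_validation_table",
    "error_metrics",
    "pcp",
    "paired_comparison",
    "reference_metrics",
]

LARGE_FLAME_M = 1.0


def build_validation_table(
    predictions: pd.DataFrame,
    observations: Iterable[ObservedFlameInterval] | pd.DataFrame,
) -> pd.DataFrame:
    """Join predictions (site_id, treatment, predicted_m) with observed
    intervals and derive per-row error columns.

    ``observations`` may be ObservedFlameInterval records or a frame with
    columns (site_id, lower_m, median_m, upper_m).
    """
    if isinstance(observations, pd.DataFrame):
        obs = observations.copy()
    else:
        obs = pd.DataFrame(
            [
                {"site_id": o.site_id, "lower_m": o.lower, "median_m": o.median, "upper_m": o.upper}
                for o in observations
            ]
        )
    required = {"site_id", "lower_m", "median_m", "upper_m"}
    if not required.issubset(obs.columns):
        raise ValidationError(f"observations need columns {sorted(required)}")
    merged = predictions.merge(obs, on="site_id", how="inner", validate="m:1")
    if merged.empty:
        raise ValidationError("no overlapping sites between predictions and observations")
    merged["signed_error_m"] = merged["predicted_m"] - merged["median_m"]
    merged["abs_error_m"] = merged["signed_error_m"].abs()
    merged["correct"] = (merged["predicted_m"] >= merged["lower_m"]) & (
        merged["predicted_m"] <= merged["upper_m"]
    )
    merged["large_flame"] = merged["median_m"] >= LARGE_FLAME_M
    return merged


def _subset(table: pd.DataFrame, treatment: str) -> pd.DataFrame:
    sub = table[table["treatment"] == treatment]
    if sub.empty:
        raise ValidationError(f"no rows for treatment {treatment!r}")
    return sub


def error_metrics(table: pd.DataFrame, treatment: str) -> dict[str, float]:
    """Mean signed error (ME), mean absolute error (MAE) and the standard
    error of each mean, for one treatment."""
    sub = _subset(table, treatment)
    err = sub["signed_error_m"].to_numpy(float)
    n = err.size
    sem = lambda x: float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return {
        "me": float(err.mean()),
        "mae": float(np.abs(err).mean()),
        "se_me": sem(err),
        "se_mae": sem(np.abs(err)),
        "n": int(n),
    }


def pcp(table: pd.DataFrame, treatment: str, min_height: float | None = None) -> float:
    """Proportion of predictions falling inside the observed interval.

    ``min_height`` restricts to sites whose observed (median) flame height
    is at least that tall; pass 1.0 for PCP over large flames.
    """
    sub = _subset(table, treatment)
    if min_height is not None:
        sub = sub[sub["median_m"] >= min_height]
        if sub.empty:
            raise ValidationError(f"no sites with observed flames >= {min_height} m")
    return float(sub["correct"].mean())


def paired_comparison(
    table: pd.DataFrame, treatment_a: str, treatment_b: str, metric: str = "ae"
) -> dict[str, float]:
    """Paired t-test between two treatments on per-site absolute error
    (``metric='ae'``) or 0/1 correctness (``metric='correct'``).

    A zero-variance difference with nonzero mean is a degenerate pairing;
    its p-value is reported as 0.0 with ``degenerate=True``.
    """
    col = {"ae": "abs_error_m", "correct": "correct"}.get(metric)
    if col is None:
        raise ValueError(f"unknown metric {metric!r}")
    a = _subset(table, treatment_a).sort_values("site_id")
    b = _subset(table, treatment_b).sort_values("site_id")
    if list(a["site_id"]) != list(b["site_id"]):
        raise ValidationError("treatments cover different site sets")
    x = a[col].to_numpy(float)
    y = b[col].to_numpy(float)
    diff = x - y
    n = diff.size
    if n < 2:
        raise ValidationError("paired test needs at least two sites")
    if np.allclose(diff, diff[0]):
        degenerate = True
        t = 0.0 if diff[0] == 0 else math.copysign(math.inf, diff[0])
        p = 1.0 if diff[0] == 0 else 0.0
    else:
        degenerate = False
        res = sps.ttest_rel(x, y)
        t, p = float(res.statistic), float(res.pvalue)
    return {"t": t, "df": n - 1, "p": p, "degenerate": degenerate}


def reference_metrics(obs_pred: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Recompute the headline validation statistics from a deposited table
    of observed and predicted flame heights.

    ``obs_pred`` must carry one row per site with columns ``site_id``,
    ``lower_m``, ``median_m``, ``upper_m`` and one ``pred_<treatment>_m``
    column per treatment. Returns, per treatment: ME, MAE (with standard
    errors), PCP, PCP1, the count of sites with observed flames >= 1 m and
    the mean observed flame height. Pure arithmetic; no simulation is run.
    """
    treatments = [c[5:-2] for c in obs_pred.columns if c.startswith("pred_") and c.endswith("_m")]
    if not treatments:
        raise ValidationError("no pred_<treatment>_m columns found")
    long = pd.concat(
        [
            pd.DataFrame(
                {
                    "site_id": obs_pred["site_id"],
                    "treatment": trt,
                    "predicted_m": obs_pred[f"pred_{trt}_m"],
                }
            )
            for trt in treatments
        ],
        ignore_index=True,
    )
    table = build_validation_table(long, obs_pred[["site_id", "lower_m", "median_m", "upper_m"]])
    out: dict[str, dict[str, float]] = {}
    for trt in treatments:
        metrics = error_metrics(table, trt)
        metrics["pcp"] = pcp(table, trt)
        metrics["pcp1"] = pcp(table, trt, min_height=LARGE_FLAME_M)
        out[trt] = metrics
    first = table[table["treatment"] == treatments[0]]
    out["observed"] = {
        "n_sites": int(len(first)),
        "n_large": int(first["large_flame"].sum()),
        "mean_observed_m": float(first["median_m"].mean()),
    }
    return out
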