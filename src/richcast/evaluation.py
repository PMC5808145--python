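"""Forecast verification: RMSE, interval coverage, Gaussian deviance,
horizon curves, skill against a baseline, and the exact MSE decomposition.

All metrics operate on Gaussian forecasts (DataFrames with site_id, year,
mean, sd) joined against an observed richness panel on (site_id, year).
Deviance is -2 x the Gaussian log-likelihood; reported values are
per-forecast means.  The squared-error decomposition splits each model's
MSE into a site-level-mean component (consistent over/under-prediction of
a site) and an annual-fluctuation component (failure to track year-to-year
changes); the two add to the pooled MSE exactly because the within-site
cross term cancels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ErrorDecomposition",
    "joined",
    "rmse",
    "coverage",
    "mean_deviance",
    "skill_vs_baseline",
    "decompose_mse",
    "metrics_by_horizon",
    "metrics_table",
]

log = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-6


@dataclass
class ErrorDecomposition:
    site_component: float
    annual_component: float
    total: float

    def __post_init__(self) -> None:
        if self.total > 0 and abs(
            self.site_component + self.annual_component - self.total
        ) > 1e-9 * max(self.total, 1.0):
            raise ValueError("decomposition components do not add to the total")


def joined(forecasts: pd.DataFrame, observed: pd.DataFrame) -> pd.DataFrame:
    """Inner-join forecasts with observations on (site_id, year).

    Unmatched rows are dropped (count logged).  Raises on an empty join.
    """
    merged = forecasts.merge(
        observed[["site_id", "year", "richness"]], on=["site_id", "year"], how="inner"
    )
    dropped = len(forecasts) - len(merged)
    if dropped:
        log.info("dropped %d forecast rows without matching observations", dropped)
    if merged.empty:
        raise ValueError("no overlap between forecasts and observations")
    return merged


def rmse(forecasts: pd.DataFrame, observed: pd.DataFrame) -> float:
    m = joined(forecasts, observed)
    return float(np.sqrt(np.mean((m["mean"] - m["richness"]) ** 2)))


def coverage(
    forecasts: pd.DataFrame, observed: pd.DataFrame, level: float = 0.95
) -> float:
    """Fraction of observations inside the central Gaussian interval.

    Zero-SD forecasts count as covered only when the observation equals
    the forecast mean exactly.
    """
    m = joined(forecasts, observed)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * m["sd"].to_numpy(dtype=float)
    err = np.abs(m["richness"].to_numpy(dtype=float) - m["mean"].to_numpy(dtype=float))
    return float(np.mean(err <= half))


def mean_deviance(forecasts: pd.DataFrame, observed: pd.DataFrame) -> float:
    """Mean Gaussian deviance: log(2 pi sd^2) + (y - mean)^2 / sd^2 per row.

    A variance floor guards sd = 0 rows (logged when triggered); truly
    degenerate all-zero SDs indicate the caller should supply a variance.
    """
    m = joined(forecasts, observed)
    sd = m["sd"].to_numpy(dtype=float)
    if np.any(sd**2 < VARIANCE_FLOOR):
        n_floored = int(np.sum(sd**2 < VARIANCE_FLOOR))
        log.info("variance floor %g applied to %d rows", VARIANCE_FLOOR, n_floored)
    var = np.maximum(sd**2, VARIANCE_FLOOR)
    dev = np.log(2.0 * math.pi * var) + (m["richness"] - m["mean"]) ** 2 / var
    return float(dev.mean())


def skill_vs_baseline(
    model_forecasts: pd.DataFrame,
    baseline_forecasts: pd.DataFrame,
    observed: pd.DataFrame,
) -> pd.DataFrame:
    """Per-forecast model-minus-baseline differences in |error| and deviance.

    Both forecast sets must cover identical (site_id, year) keys; the same
    forecast is compared on the same observation.  Returns one row per
    forecast with columns d_abs_error and d_deviance (positive = model
    worse than baseline) plus the observation key.
    """
    mk = set(map(tuple, model_forecasts[["site_id", "year"]].itertuples(index=False)))
    bk = set(map(tuple, baseline_forecasts[["site_id", "year"]].itertuples(index=False)))
    if mk != bk:
        offenders = sorted(mk.symmetric_difference(bk))[:5]
        raise ValueError(f"forecast key mismatch, e.g. {offenders}")
    m = joined(model_forecasts, observed).set_index(["site_id", "year"]).sort_index()
    b = joined(baseline_forecasts, observed).set_index(["site_id", "year"]).sort_index()

    def _dev(frame):
        var = np.maximum(frame["sd"].to_numpy(dtype=float) ** 2, VARIANCE_FLOOR)
        return np.log(2.0 * math.pi * var) + (
            frame["richness"] - frame["mean"]
        ) ** 2 / var

    out = pd.DataFrame(index=m.index)
    out["d_abs_error"] = (m["mean"] - m["richness"]).abs() - (
        b["mean"] - b["richness"]
    ).abs()
    out["d_deviance"] = _dev(m).to_numpy() - _dev(b).to_numpy()
    return out.reset_index()


def decompose_mse(forecasts: pd.DataFrame, observed: pd.DataFrame) -> ErrorDecomposition:
    """Split MSE into site-level-mean and annual-fluctuation components.

    Per site s with per-site test means ybar_s, pbar_s:
    site term (pbar_s - ybar_s)^2; annual term mean_t ((p - pbar_s) -
    (y - ybar_s))^2.  Sites are weighted by their year counts so the two
    components add to the pooled MSE exactly.
    """
    m = joined(forecasts, observed)
    site_terms = []
    annual_terms = []
    weights = []
    for _, grp in m.groupby("site_id"):
        p = grp["mean"].to_numpy(dtype=float)
        y = grp["richness"].to_numpy(dtype=float)
        pb, yb = p.mean(), y.mean()
        site_terms.append((pb - yb) ** 2)
        annual_terms.append(np.mean(((p - pb) - (y - yb)) ** 2))
        weights.append(len(grp))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    site = float(np.dot(w, site_terms))
    annual = float(np.dot(w, annual_terms))
    return ErrorDecomposition(site_component=site, annual_component=annual,
                              total=site + annual)


def _pooled_metrics(forecasts, observed, level=0.95) -> dict:
    return {
        "rmse": rmse(forecasts, observed),
        "coverage95": coverage(forecasts, observed, level=level),
        "mean_deviance": mean_deviance(forecasts, observed),
        "n": len(joined(forecasts, observed)),
    }


def metrics_by_horizon(
    forecasts: pd.DataFrame, observed: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """RMSE / coverage / deviance within each forecast-horizon stratum.

    Forecasts must carry a ``horizon`` column (years past the training
    end).  Empty strata are skipped with a log entry.
    """
    if "horizon" not in forecasts.columns:
        raise ValueError("forecasts need a horizon column")
    rows = []
    for h, grp in forecasts.groupby("horizon"):
        try:
            rec = _pooled_metrics(grp, observed, level=level)
        except ValueError:
            log.info("horizon %s has no matching observations; skipped", h)
            continue
        rec["horizon"] = int(h)
        rows.append(rec)
    return pd.DataFrame(rows)[["horizon", "rmse", "coverage95", "mean_deviance", "n"]]


def metrics_table(
    forecast_sets: dict[tuple, pd.DataFrame],
    observed: pd.DataFrame,
    level: float = 0.95,
    by_horizon: bool = False,
) -> pd.DataFrame:
    """Metrics per (model, corrected) forecast set, pooled or per horizon."""
    rows = []
    for (model, corrected), fc in forecast_sets.items():
        if by_horizon:
            sub = metrics_by_horizon(fc, observed, level=level)
            sub.insert(0, "model", model)
            sub.insert(1, "corrected", corrected)
            rows.append(sub)
        else:
            rec = _pooled_metrics(fc, observed, level=level)
            rec.update(model=model, corrected=corrected, horizon="pooled")
            rows.append(pd.DataFrame([rec]))
    out = pd.concat(rows, ignore_index=True)
    cols = ["model", "corrected", "horizon", "rmse", "coverage95", "mean_deviance", "n"]
    return out[cols]
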