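"""Single-site richness forecasters: average, naive, and auto-ARIMA.

Each model is fit to one site's yearly richness series and emits a Gaussian
predictive distribution per future year.  The "average" model treats the
series as uncorrelated noise around a site constant (y_t = mu + eps_t), so
its intervals have constant width in the horizon.  The "naive" model is a
random walk, ARIMA(0,1,0) (y_t = y_{t-1} + eps_t), whose point forecast is
the last observation and whose interval width grows as sqrt(h).  The
auto-ARIMA selects (p, d, q) and an intercept/drift term by AICc through a
stepwise Hyndman-Khandakar search with the differencing order chosen by a
KPSS unit-root test; no seasonal component (yearly data).

Observer-corrected runs fit one model per posterior draw and pool the per-
draw Gaussian summaries by the law of total variance:
Var = Var(draw means) + E[draw variances].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import kpss
from statsmodels.tsa.statespace.sarimax import SARIMAX

__all__ = [
    "AverageFit",
    "NaiveFit",
    "ArimaFit",
    "fit_average",
    "forecast_average",
    "fit_naive",
    "forecast_naive",
    "select_arima",
    "forecast_arima",
    "combine_draw_forecasts",
]

log = logging.getLogger(__name__)


@dataclass
class AverageFit:
    mu: float
    sigma: float

    def forecast(self, h: int) -> tuple[np.ndarray, np.ndarray]:
        return np.full(h, self.mu), np.full(h, self.sigma)


@dataclass
class NaiveFit:
    last_value: float
    sigma_step: float

    def forecast(self, h: int) -> tuple[np.ndarray, np.ndarray]:
        hs = np.arange(1, h + 1)
        return np.full(h, self.last_value), self.sigma_step * np.sqrt(hs)


@dataclass
class ArimaFit:
    order: tuple[int, int, int]
    with_intercept: bool
    params: np.ndarray
    sigma: float            # innovation SD
    aicc: float
    _res: object = field(repr=False, default=None)

    def forecast(self, h: int) -> tuple[np.ndarray, np.ndarray]:
        fc = self._res.get_forecast(h)
        return np.asarray(fc.predicted_mean), np.asarray(fc.se_mean)


def fit_average(series, sigma: float | None = None) -> AverageFit:
    """Site mean and SD; ``sigma`` overrides the sample SD (e.g. with the
    observer model's residual SD in corrected mode)."""
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise ValueError("average model needs at least 2 observations")
    return AverageFit(mu=float(y.mean()),
                      sigma=float(y.std(ddof=1)) if sigma is None else float(sigma))


def forecast_average(fit: AverageFit, h: int) -> tuple[np.ndarray, np.ndarray]:
    return fit.forecast(h)


def fit_naive(series, years=None) -> NaiveFit:
    """Random-walk fit: last value + SD of first differences.

    If ``years`` is given, differences are taken only across consecutive
    observed years; interior gaps are flagged.  With fewer than 2 usable
    differences the step SD is set to 0 with a warning.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise ValueError("naive model needs at least 2 observations")
    if years is not None:
        yr = np.asarray(years)
        consec = np.diff(yr) == 1
        if not consec.all():
            warnings.warn(
                f"series has {np.count_nonzero(~consec)} gap(s); differences "
                "taken only across consecutive years",
                stacklevel=2,
            )
        diffs = np.diff(y)[consec]
    else:
        diffs = np.diff(y)
    if diffs.size < 2:
        warnings.warn("fewer than 2 consecutive differences; step SD set to 0",
                      stacklevel=2)
        sigma_step = 0.0
    else:
        sigma_step = float(diffs.std(ddof=1))
    return NaiveFit(last_value=float(y[-1]), sigma_step=sigma_step)


def forecast_naive(fit: NaiveFit, h: int) -> tuple[np.ndarray, np.ndarray]:
    return fit.forecast(h)


def _kpss_d(y: np.ndarray, max_d: int) -> int:
    """Differencing order: difference until KPSS stops rejecting stationarity."""
    d = 0
    x = y.copy()
    while d < max_d:
        nlags = int(4 * (x.size / 100.0) ** 0.25)  # the "short" lag convention
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", InterpolationWarning)
            try:
                _, pvalue, *_ = kpss(x, regression="c", nlags=nlags)
            except (ValueError, OverflowError):
                break
        if pvalue >= 0.05:
            break
        x = np.diff(x)
        d += 1
    return d


def _aicc_fit(y: np.ndarray, p: int, d: int, q: int, intercept: bool):
    """Fit one candidate; return (aicc, results) or None on failure."""
    trend = "c" if intercept else "n"
    n = y.size - d
    k = p + q + (1 if intercept else 0) + 1  # + innovation variance
    if n - k - 1 <= 0:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = SARIMAX(y, order=(p, d, q), trend=trend,
                            enforce_stationarity=True, enforce_invertibility=True)
            res = model.fit(disp=False)
        if not np.isfinite(res.aic):
            return None
    except (np.linalg.LinAlgError, ValueError) as exc:
        log.info("ARIMA(%d,%d,%d) intercept=%s failed: %s", p, d, q, intercept, exc)
        return None
    aicc = res.aic + 2.0 * k * (k + 1) / (n - k - 1)
    return aicc, res


def select_arima(series, max_p: int = 5, max_q: int = 5, max_d: int = 2):
    """Stepwise AICc order selection (Hyndman-Khandakar recipe).

    Starts from (2,d,2), (0,d,0), (1,d,0) and (0,d,1), then explores the
    p/q/intercept neighborhood of the incumbent until no candidate improves
    AICc.  Non-convergent candidates are skipped.  Series shorter than 10
    observations fall back to the average model with a warning.  The search
    is deterministic given the series.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 10:
        warnings.warn("series too short for ARIMA selection; using average model",
                      stacklevel=2)
        return fit_average(y)
    d = _kpss_d(y, max_d)

    cache: dict[tuple, object] = {}

    def evaluate(p: int, q: int, intercept: bool):
        key = (p, q, intercept)
        if key not in cache:
            cache[key] = _aicc_fit(y, p, d, q, intercept)
        return cache[key]

    start = [(2, 2, True), (0, 0, True), (1, 0, True), (0, 1, True)]
    best_key, best = None, None
    for p, q, c in start:
        if p > max_p or q > max_q:
            continue
        out = evaluate(p, q, c)
        if out is not None and (best is None or out[0] < best[0]):
            best_key, best = (p, q, c), out
    if best is None:
        warnings.warn("no ARIMA candidate converged; using average model",
                      stacklevel=2)
        return fit_average(y)

    improved = True
    while improved:
        improved = False
        p0, q0, c0 = best_key
        neighbors = [
            (p0 + 1, q0, c0), (p0 - 1, q0, c0),
            (p0, q0 + 1, c0), (p0, q0 - 1, c0),
            (p0 + 1, q0 + 1, c0), (p0 - 1, q0 - 1, c0),
            (p0, q0, not c0),
        ]
        for p, q, c in neighbors:
            if not (0 <= p <= max_p and 0 <= q <= max_q):
                continue
            out = evaluate(p, q, c)
            if out is not None and out[0] < best[0] - 1e-10:
                best_key, best = (p, q, c), out
                improved = True
                break

    p, q, c = best_key
    aicc, res = best
    return ArimaFit(
        order=(p, d, q),
        with_intercept=c,
        params=np.asarray(res.params),
        sigma=float(np.sqrt(res.params[-1])),
        aicc=float(aicc),
        _res=res,
    )


def forecast_arima(fit, h: int) -> tuple[np.ndarray, np.ndarray]:
    """Forecast from an ArimaFit (or an AverageFit fallback)."""
    return fit.forecast(h)


def combine_draw_forecasts(draws) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-draw Gaussian forecasts by the law of total variance.

    ``draws`` is a sequence of (mean, variance) pairs (scalars or aligned
    arrays).  Returns (mean, variance) with mean the average of draw means
    and variance the unbiased variance of draw means plus the average of
    draw variances.  A single draw contributes no between-draw variance.
    """
    if len(draws) == 0:
        raise ValueError("need at least one draw")
    means = np.stack([np.asarray(m, dtype=float) for m, _ in draws])
    variances = np.stack([np.asarray(v, dtype=float) for _, v in draws])
    mean = means.mean(axis=0)
    between = means.var(axis=0, ddof=1) if means.shape[0] > 1 else np.zeros_like(mean)
    return mean, between + variances.mean(axis=0)
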