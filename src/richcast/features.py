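"""Environmental predictors, completeness filtering, and train/test split.

Bioclim summaries are computed over the 12 months leading up to the annual
survey (July of the previous calendar year through June of the survey year),
not the calendar year.  Quarters are the 10 non-wrapping 3-month windows of
that July-June sequence; ties between equally wet/dry/warm quarters are
broken by the earliest window.  BIO15 uses a (1 + mean) denominator so
zero-precipitation inputs stay finite.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "MissingMonthError",
    "compute_bioclim",
    "seasonal_ndvi",
    "bioclim_table",
    "filter_complete_sites",
    "split_train_test",
]

BIOCLIM_COLUMNS = ["bio2", "bio3", "bio5", "bio8", "bio9", "bio15", "bio16", "bio18"]


class MissingMonthError(ValueError):
    """A required month is absent from a monthly series."""


def _july_june_window(survey_year: int) -> list[tuple[int, int]]:
    """(year, month) keys for July(year-1) .. June(year)."""
    return [(survey_year - 1, m) for m in range(7, 13)] + [
        (survey_year, m) for m in range(1, 7)
    ]


def compute_bioclim(weather: pd.DataFrame, survey_year: int) -> dict[str, float]:
    """Eight bioclim variables for one site's survey year.

    Parameters
    ----------
    weather : DataFrame with columns year, month, tmax, tmin, prec
        Monthly series for a single site.  All 12 months of the July-June
        window preceding ``survey_year`` must be present.

    Returns
    -------
    dict with keys bio2 (mean diurnal range, degC), bio3 (isothermality, %),
    bio5 (max temperature of the warmest month, degC), bio8/bio9 (mean
    temperature of the wettest/driest quarter, degC), bio15 (precipitation
    seasonality, %), bio16 (precipitation of the wettest quarter, mm),
    bio18 (precipitation of the warmest quarter, mm).
    """
    idx = weather.set_index(["year", "month"])
    window = _july_june_window(survey_year)
    for key in window:
        if key not in idx.index:
            raise MissingMonthError(
                f"missing month {key[0]}-{key[1]:02d} for survey year {survey_year}"
            )
    sub = idx.loc[window]
    tmax = sub["tmax"].to_numpy(dtype=float)
    tmin = sub["tmin"].to_numpy(dtype=float)
    prec = sub["prec"].to_numpy(dtype=float)
    tmid = (tmax + tmin) / 2.0

    bio2 = float(np.mean(tmax - tmin))
    bio5 = float(np.max(tmax))
    trange = bio5 - float(np.min(tmin))
    bio3 = 100.0 * bio2 / trange if trange > 0 else 100.0

    # 10 rolling 3-month windows within July..June (no wrap).
    q_prec = np.array([prec[i:i + 3].sum() for i in range(10)])
    q_temp = np.array([tmid[i:i + 3].mean() for i in range(10)])
    wettest = int(np.argmax(q_prec))            # argmax -> earliest tie wins
    driest = int(np.argmin(q_prec))
    warmest = int(np.argmax(q_temp))

    bio8 = float(q_temp[wettest])
    bio9 = float(q_temp[driest])
    bio15 = 100.0 * float(np.std(prec, ddof=0)) / (1.0 + float(np.mean(prec)))
    bio16 = float(q_prec[wettest])
    bio18 = float(q_prec[warmest])

    return {
        "bio2": bio2, "bio3": bio3, "bio5": bio5, "bio8": bio8,
        "bio9": bio9, "bio15": bio15, "bio16": bio16, "bio18": bio18,
    }


def seasonal_ndvi(monthly_ndvi: pd.DataFrame, survey_year: int) -> tuple[float, float]:
    """Summer (Apr/May/Jun) and winter (Dec prior year, Jan, Feb) NDVI means.

    ``monthly_ndvi`` has columns year, month, ndvi for one site.
    """
    idx = monthly_ndvi.set_index(["year", "month"])["ndvi"]
    summer_keys = [(survey_year, m) for m in (4, 5, 6)]
    winter_keys = [(survey_year - 1, 12), (survey_year, 1), (survey_year, 2)]
    for key in summer_keys + winter_keys:
        if key not in idx.index:
            raise MissingMonthError(
                f"missing NDVI month {key[0]}-{key[1]:02d} for survey year {survey_year}"
            )
    summer = float(np.mean([idx[k] for k in summer_keys]))
    winter = float(np.mean([idx[k] for k in winter_keys]))
    return summer, winter


def bioclim_table(
    weather: pd.DataFrame,
    survey_years,
    ndvi: pd.DataFrame | None = None,
    elevation: pd.Series | None = None,
) -> pd.DataFrame:
    """Site-year covariate table from multi-site monthly weather.

    ``weather`` has columns site_id, year, month, tmax, tmin, prec.
    Optional per-site monthly ``ndvi`` (site_id, year, month, ndvi) adds
    ndvi_summer/ndvi_winter; optional ``elevation`` (Series indexed by
    site_id, metres) adds a site-constant elevation column.
    """
    rows = []
    for site, grp in weather.groupby("site_id", sort=True):
        ngrp = ndvi[ndvi["site_id"] == site] if ndvi is not None else None
        for year in survey_years:
            rec = {"site_id": site, "year": int(year)}
            rec.update(compute_bioclim(grp, int(year)))
            if ngrp is not None:
                rec["ndvi_summer"], rec["ndvi_winter"] = seasonal_ndvi(ngrp, int(year))
            if elevation is not None:
                rec["elevation"] = float(elevation[site])
            rows.append(rec)
    return pd.DataFrame(rows)


def filter_complete_sites(
    panel: pd.DataFrame, training_years, min_fraction: float = 0.7
) -> pd.DataFrame:
    """Keep sites observed in at least ``min_fraction`` of the training years.

    The threshold is ``ceil(min_fraction * len(training_years))`` observed
    training years (e.g. 22 training years at 0.7 -> 16 observations).
    Records of retained sites outside the training period are untouched.
    Returns an empty panel (with a warning, not an error) if nothing
    survives.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    years = set(int(y) for y in training_years)
    threshold = math.ceil(min_fraction * len(years))
    in_train = panel[panel["year"].isin(years)]
    counts = in_train.groupby("site_id")["year"].nunique()
    keep = set(counts.index[counts >= threshold])
    out = panel[panel["site_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        import warnings

        warnings.warn("completeness filter removed every site", stacklevel=2)
    return out


def split_train_test(panel: pd.DataFrame, split_year: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a panel into training (year <= split_year) and test (year > split_year)."""
    train = panel[panel["year"] <= split_year].reset_index(drop=True)
    test = panel[panel["year"] > split_year].reset_index(drop=True)
    return train, test
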