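"""End-to-end hindcast experiment: simulate/load -> filter & split ->
fit observer model -> forecast (6 models x corrected/uncorrected) ->
evaluate -> report.

The experiment mirrors a hindcasting design: models are trained on the
years up to ``split_year`` and evaluated on the later years, with the
environmental conditions of the test period taken as known (optionally
replaced by training-period climatology to mimic true forecasting).  No
stage ever reads test-period richness during fitting.

Forecasts are collected into an archive table (site_id, year, model,
corrected, horizon, mean, sd, lo68, hi68, lo95, hi95) with a metadata
block, so hindcasts can be re-evaluated later against newly supplied
observations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import evaluation, env_models, features, observer, site_models, synth
from .synth import SimConfig

__all__ = [
    "ExperimentConfig",
    "ForecastArchive",
    "read_richness_panel",
    "write_forecast_archive",
    "read_forecast_archive",
    "run_experiment",
]

log = logging.getLogger(__name__)

ALL_MODELS = ("average", "naive", "auto_arima", "gbm", "stacked_sdm", "jsdm")
SINGLE_SITE_MODELS = ("average", "naive", "auto_arima")
COMMUNITY_MODELS = ("stacked_sdm", "jsdm")

_Z68 = float(stats.norm.ppf(0.5 + 0.68 / 2.0))
_Z95 = float(stats.norm.ppf(0.5 + 0.95 / 2.0))

ARCHIVE_VERSION = "1"


@dataclass
class ExperimentConfig:
    """Configuration for one hindcast experiment.

    Either ``sim`` (an embedded generator configuration) or
    ``panel_path``/``covariates_path`` (and ``community_path`` for the
    community models) must be provided.  ``n_draws`` is the number of
    observer-posterior draws; ``model_draws`` (default: same) is how many
    of them downstream models are re-fit on in corrected mode.
    """

    sim: SimConfig | None = None
    panel_path: str | None = None
    covariates_path: str | None = None
    community_path: str | None = None
    split_year: int = 2003
    min_fraction: float = 0.7
    models: tuple = ("average", "naive")
    n_draws: int = 100
    model_draws: int | None = None
    warmup: int = 1000
    n_trees: int = 100
    n_latent: int = 2
    gbm_max_trees: int = 500
    jsdm_samples: int = 1000
    use_climatology: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.models) - set(ALL_MODELS)
        if bad:
            raise ValueError(f"unknown models requested: {sorted(bad)}")
        if self.sim is None and self.panel_path is None:
            raise ValueError("either sim or panel_path must be given")
        if (
            any(m in COMMUNITY_MODELS for m in self.models)
            and self.sim is None
            and self.community_path is None
        ):
            raise ValueError("community models requested without community inputs")
        if any(m in ("gbm", *COMMUNITY_MODELS) for m in self.models) and (
            self.sim is None and self.covariates_path is None
        ):
            raise ValueError("environmental models requested without covariates")


@dataclass
class ForecastArchive:
    """Forecast table plus the metadata needed to assess it later."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    REQUIRED = ["site_id", "year", "model", "corrected", "horizon",
                "mean", "sd", "lo68", "hi68", "lo95", "hi95"]

    def validate(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"archive missing columns {missing}")
        f = self.frame
        if (f["sd"] < 0).any():
            raise ValueError("archive contains negative sd")
        if ((f["hi68"] < f["lo68"]) | (f["hi95"] < f["lo95"])).any():
            raise ValueError("archive contains inverted intervals")
        for key in ("config_hash", "seed", "version", "train_end"):
            if key not in self.metadata:
                raise ValueError(f"archive metadata missing {key}")


def read_richness_panel(path) -> pd.DataFrame:
    """Read a richness panel CSV with schema validation.

    Requires columns site_id, year, observer_id, richness; rejects
    duplicate (site_id, year) keys naming the offenders and unparseable
    year/richness values with their line numbers.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["site_id", "year", "observer_id", "richness"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"panel file missing columns {missing}")
    for col, caster in (("year", int), ("richness", float)):
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"unparseable {col} value {frame[col][bad.idxmax()]!r} "
                             f"on line {line}")
        frame[col] = parsed.astype(caster)
    dup = frame.duplicated(["site_id", "year"], keep=False)
    if dup.any():
        keys = frame.loc[dup, ["site_id", "year"]].drop_duplicates()
        raise ValueError(
            "duplicate (site_id, year) keys: "
            + ", ".join(f"({r.site_id}, {r.year})" for r in keys.itertuples())
        )
    if (frame["richness"] < 0).any():
        raise ValueError("negative richness values present")
    return frame[required]


def _gaussian_rows(site, years, split_year, mean, sd, model, corrected):
    return pd.DataFrame({
        "site_id": site,
        "year": list(years),
        "model": model,
        "corrected": corrected,
        "horizon": [int(y) - split_year for y in years],
        "mean": np.asarray(mean, dtype=float),
        "sd": np.asarray(sd, dtype=float),
    })


def _series_for_site(train, site):
    grp = train[train["site_id"] == site].sort_values("year")
    return grp["richness"].to_numpy(dtype=float), grp["year"].to_numpy()


class _TestObserverEffects:
    """Observer-effect adjustment for corrected-mode test forecasts.

    A corrected model predicts the richness a typical observer would
    record; the actual test-year observation still carries that year's
    observer effect.  For observers already seen in training the draw's
    effect is added back to the forecast mean; observers unseen in
    training (or unsurveyed site-years) get effect 0 with sigma_obs^2
    added to the predictive variance.
    """

    def __init__(self, panel: pd.DataFrame, post, split_year: int):
        test = panel[panel["year"] > split_year]
        self._who = {
            (r.site_id, r.year): r.observer_id for r in test.itertuples()
        }
        self._post = post
        self._known = set(post.observer_effects.columns)

    def for_keys(self, keys) -> tuple[np.ndarray, np.ndarray]:
        """(n_draws, n_keys) mean adjustment and (n_draws, n_keys) variance
        adjustment for a sequence of (site_id, year) keys."""
        post = self._post
        n = len(keys)
        eff = np.zeros((post.n_draws, n))
        var = np.zeros((post.n_draws, n))
        sig2 = post.sigma_obs**2
        for i, key in enumerate(keys):
            o = self._who.get(key)
            if o is not None and o in self._known:
                eff[:, i] = post.observer_effects[o].to_numpy()
            else:
                var[:, i] = sig2
        return eff, var


def _forecast_single_site(model, config, train, post, sites, test_years, obs_adj):
    """Forecast one single-site model for all sites, both correction modes."""
    split = config.split_year
    h = len(test_years)
    n_fit_draws = config.model_draws or config.n_draws
    out = {False: [], True: []}

    corrected_panels = None
    if model in ("naive", "auto_arima"):
        idx = np.linspace(0, post.n_draws - 1, n_fit_draws).astype(int)
        sub = observer.ObserverPosterior(
            mu=post.mu[idx],
            site_effects=post.site_effects.iloc[idx].reset_index(drop=True),
            observer_effects=post.observer_effects.iloc[idx].reset_index(drop=True),
            sigma_site=post.sigma_site[idx],
            sigma_obs=post.sigma_obs[idx],
            sigma_resid=post.sigma_resid[idx],
        )
        corrected_panels = observer.corrected_richness_draws(train, sub)

    for site in sites:
        y, yrs = _series_for_site(train, site)
        keys = [(site, int(yr)) for yr in test_years]
        eff, var_add = obs_adj.for_keys(keys)   # (n_draws, h) each
        if model == "average":
            fit = site_models.fit_average(y)
            mean, sd = fit.forecast(h)
            out[False].append(_gaussian_rows(site, test_years, split, mean, sd,
                                             model, False))
            # corrected: the observer model's site-level expectation plus
            # the test observer's effect draw
            mu_d = post.mu + post.site_effects[site].to_numpy()
            draws = [
                (mu_d[d] + eff[d], post.sigma_resid[d] ** 2 + var_add[d])
                for d in range(post.n_draws)
            ]
            cmean, cvar = site_models.combine_draw_forecasts(draws)
            out[True].append(_gaussian_rows(site, test_years, split, cmean,
                                            np.sqrt(cvar), model, True))
        else:
            if model == "naive":
                fit = site_models.fit_naive(y, yrs)
            else:
                fit = site_models.select_arima(y)
            mean, sd = fit.forecast(h)
            out[False].append(_gaussian_rows(site, test_years, split, mean, sd,
                                             model, False))
            draws = []
            for j, panel_d in enumerate(corrected_panels):
                d = idx[j]
                yd, yrd = _series_for_site(panel_d, site)
                if model == "naive":
                    fd = site_models.fit_naive(yd, yrd)
                else:
                    fd = site_models.select_arima(yd)
                md, sdd = fd.forecast(h)
                draws.append((md + eff[d], sdd**2 + var_add[d]))
            cmean, cvar = site_models.combine_draw_forecasts(draws)
            out[True].append(_gaussian_rows(site, test_years, split, cmean,
                                            np.sqrt(cvar), model, True))
    return {k: pd.concat(v, ignore_index=True) for k, v in out.items()}


def _test_covariates(covariates, sites, test_years, config, train_years):
    cov = covariates[covariates["site_id"].isin(sites)]
    test_cov = cov[cov["year"].isin(test_years)].copy()
    if config.use_climatology:
        # replace test-year covariates with training-period site means
        clim = (
            cov[cov["year"].isin(train_years)]
            .drop(columns="year")
            .groupby("site_id", as_index=False)
            .mean()
        )
        keys = test_cov[["site_id", "year"]]
        test_cov = keys.merge(clim, on="site_id", how="left")
    return test_cov


def _forecast_environmental(model, config, train, post, covariates, community,
                            sites, test_years, rng, obs_adj):
    split = config.split_year
    train_keys = train[["site_id", "year"]]
    cov_train = train_keys.merge(covariates, on=["site_id", "year"], how="left")
    if cov_train.isna().any().any():
        raise KeyError("covariates missing for some training site-years")
    train_years = sorted(set(train["year"]))
    test_cov = _test_covariates(covariates, sites, test_years, config, train_years)
    out = {}
    n_fit_draws = config.model_draws or config.n_draws

    if model == "gbm":
        spec = env_models.GbmSpec(max_trees=config.gbm_max_trees)
        y = train["richness"].to_numpy(dtype=float)
        fit = env_models.fit_richness_gbm(
            cov_train, y, spec, seed=int(rng.integers(2**31 - 1))
        )
        mean, sd = fit.predict(test_cov)
        out[False] = _env_frame(test_cov, split, mean, sd, model, False)
        eff = observer._observer_effect_matrix(train, post)
        test_keys = list(map(tuple, test_cov[["site_id", "year"]].itertuples(index=False)))
        adj_eff, adj_var = obs_adj.for_keys(test_keys)
        idx = np.linspace(0, post.n_draws - 1, n_fit_draws).astype(int)
        draws = []
        for d in idx:
            fit_d = env_models.fit_richness_gbm(
                cov_train, y - eff[d], spec, seed=int(rng.integers(2**31 - 1))
            )
            m_d, s_d = fit_d.predict(test_cov)
            draws.append((m_d + adj_eff[d], s_d**2 + adj_var[d]))
        cmean, cvar = site_models.combine_draw_forecasts(draws)
        out[True] = _env_frame(test_cov, split, cmean, np.sqrt(cvar), model, True)
        return out

    comm_train = community[community["year"] <= split]
    comm_train = comm_train[comm_train["site_id"].isin(sites)]
    if model == "stacked_sdm":
        sdm = env_models.fit_stacked_sdm(
            comm_train, cov_train, observer_draws=None,
            n_trees=config.n_trees, seed=int(rng.integers(2**31 - 1)),
        )
        fc = env_models.predict_stacked_richness(sdm, test_cov)
        out[False] = _env_frame(test_cov, split, fc["mean"], fc["sd"], model, False)
        # align observer-effect draws to the community site-year rows
        keys = comm_train.pivot_table(index=["site_id", "year"], columns="species_id",
                                      values="detected").index.to_frame(index=False)
        keys["observer_id"] = keys.merge(
            train[["site_id", "year", "observer_id"]], on=["site_id", "year"],
            how="left",
        )["observer_id"]
        eff = observer._observer_effect_matrix(keys, post)
        cov_rows = keys[["site_id", "year"]].merge(
            covariates, on=["site_id", "year"], how="left"
        )
        sdm_c = env_models.fit_stacked_sdm(
            comm_train, cov_rows, observer_draws=eff,
            n_trees=config.n_trees, seed=int(rng.integers(2**31 - 1)),
        )
        test_keys = list(map(tuple, test_cov[["site_id", "year"]].itertuples(index=False)))
        adj_eff, _ = obs_adj.for_keys(test_keys)
        fc = env_models.predict_stacked_richness(
            sdm_c, test_cov, observer_effect=adj_eff.mean(axis=0)
        )
        out[True] = _env_frame(test_cov, split, fc["mean"], fc["sd"], model, True)
        return out

    if model == "jsdm":
        seed_j = int(rng.integers(2**31 - 1))
        fit = env_models.fit_jsdm(
            comm_train, cov_train, n_latent=config.n_latent, seed=seed_j
        )
        fc = env_models.predict_jsdm_richness(
            fit, test_cov, n_samples=config.jsdm_samples, seed=seed_j + 1
        )
        out[False] = _env_frame(test_cov, split, fc["mean"], fc["sd"], model, False)
        keys = comm_train.pivot_table(index=["site_id", "year"], columns="species_id",
                                      values="detected").index.to_frame(index=False)
        keys["observer_id"] = keys.merge(
            train[["site_id", "year", "observer_id"]], on=["site_id", "year"],
            how="left",
        )["observer_id"]
        eff_mean = observer.posterior_mean_observer_effects(keys, post)
        cov_rows = keys[["site_id", "year"]].merge(
            covariates, on=["site_id", "year"], how="left"
        )
        fit_c = env_models.fit_jsdm(
            comm_train, cov_rows, observer_effect=eff_mean,
            n_latent=config.n_latent, seed=seed_j + 2,
        )
        test_keys = list(map(tuple, test_cov[["site_id", "year"]].itertuples(index=False)))
        adj_eff, _ = obs_adj.for_keys(test_keys)
        fc = env_models.predict_jsdm_richness(
            fit_c, test_cov, n_samples=config.jsdm_samples, seed=seed_j + 3,
            observer_effect=adj_eff.mean(axis=0),
        )
        out[True] = _env_frame(test_cov, split, fc["mean"], fc["sd"], model, True)
        return out

    raise ValueError(f"unknown environmental model {model}")


def _env_frame(test_cov, split, mean, sd, model, corrected):
    return pd.DataFrame({
        "site_id": test_cov["site_id"].to_numpy(),
        "year": test_cov["year"].to_numpy(),
        "model": model,
        "corrected": corrected,
        "horizon": test_cov["year"].to_numpy() - split,
        "mean": np.asarray(mean, dtype=float),
        "sd": np.asarray(sd, dtype=float),
    })


def _config_hash(config: ExperimentConfig) -> str:
    def _clean(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: _clean(v) for k, v in asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [_clean(v) for v in obj]
        return obj

    payload = json.dumps(_clean(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig):
    """Run the full hindcast experiment.

    Returns (archive, metrics, decompositions, report_text).  Every
    requested model is evaluated with and without observer correction;
    correction modes share seeds so before/after comparisons are matched.
    """
    rng = np.random.default_rng(config.seed)

    # ---- stage: inputs
    if config.sim is not None:
        panel, _ = synth.simulate_richness_panel(config.sim)
        covariates = synth.simulate_covariates(config.sim)
        community = None
        if any(m in COMMUNITY_MODELS for m in config.models):
            community, panel = synth.simulate_community_panel(config.sim, covariates)
    else:
        panel = read_richness_panel(config.panel_path)
        covariates = (
            pd.read_csv(config.covariates_path) if config.covariates_path else None
        )
        community = (
            pd.read_csv(config.community_path) if config.community_path else None
        )
    years = sorted(set(panel["year"]))
    if not years[0] <= config.split_year < years[-1]:
        raise ValueError("split_year outside the data span")

    # ---- stage: filter & split
    train_years = [y for y in years if y <= config.split_year]
    n_before = panel["site_id"].nunique()
    panel = features.filter_complete_sites(panel, train_years, config.min_fraction)
    n_after = panel["site_id"].nunique()
    log.info("completeness filter kept %d of %d sites", n_after, n_before)
    train, test = features.split_train_test(panel, config.split_year)
    sites = sorted(set(train["site_id"]))
    test_years = [y for y in years if y > config.split_year]

    # ---- stage: observer model
    post = observer.fit_observer_model(
        train, n_draws=config.n_draws,
        seed=int(rng.integers(2**31 - 1)), warmup=config.warmup,
    )
    partition = observer.variance_partition(post)
    log.info("variance partition: site %.3f obs %.3f resid %.3f",
             partition.frac_site, partition.frac_obs, partition.frac_resid)

    # ---- stage: forecasts
    obs_adj = _TestObserverEffects(panel, post, config.split_year)
    forecast_sets: dict[tuple, pd.DataFrame] = {}
    for model in config.models:
        if model in SINGLE_SITE_MODELS:
            fcs = _forecast_single_site(model, config, train, post, sites,
                                        test_years, obs_adj)
        else:
            fcs = _forecast_environmental(
                model, config, train, post, covariates, community,
                sites, test_years, rng, obs_adj,
            )
        for corrected, frame in fcs.items():
            forecast_sets[(model, corrected)] = frame

    frame = pd.concat(forecast_sets.values(), ignore_index=True)
    frame["lo68"] = frame["mean"] - _Z68 * frame["sd"]
    frame["hi68"] = frame["mean"] + _Z68 * frame["sd"]
    frame["lo95"] = frame["mean"] - _Z95 * frame["sd"]
    frame["hi95"] = frame["mean"] + _Z95 * frame["sd"]
    archive = ForecastArchive(
        frame=frame,
        metadata={
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": ARCHIVE_VERSION,
            "train_end": config.split_year,
        },
    )
    archive.validate()

    # ---- stage: evaluation
    metrics = evaluation.metrics_table(forecast_sets, test)
    horizon_metrics = evaluation.metrics_table(forecast_sets, test, by_horizon=True)
    decompositions = {
        key: evaluation.decompose_mse(fc, test) for key, fc in forecast_sets.items()
    }
    skills = {}
    if ("average", False) in forecast_sets:
        base = forecast_sets[("average", False)]
        for key, fc in forecast_sets.items():
            skills[key] = evaluation.skill_vs_baseline(fc, base, test)

    report_lines = [
        f"hindcast experiment ({len(sites)} sites, split at {config.split_year})",
        f"variance partition: site {partition.frac_site:.1%}, "
        f"observer {partition.frac_obs:.1%}, residual {partition.frac_resid:.1%} "
        f"(residual SD {partition.sd_resid:.2f} species)",
        "",
        metrics.to_string(index=False),
    ]
    report = "\n".join(report_lines)

    if config.out_dir:
        import pathlib

        out = pathlib.Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_forecast_archive(archive, out / "forecast_archive.csv")
        metrics.to_csv(out / "metrics.csv", index=False)
        horizon_metrics.to_csv(out / "metrics_by_horizon.csv", index=False)
        observer.write_posterior(post, out / "observer_posterior.csv")
        (out / "report.txt").write_text(report + "\n")

    return archive, metrics, decompositions, report


def write_forecast_archive(archive: ForecastArchive, path) -> None:
    """Write the archive as CSV with a leading '# key: value' metadata block."""
    archive.validate()
    with open(path, "w") as fh:
        for key in sorted(archive.metadata):
            fh.write(f"# {key}: {archive.metadata[key]}\n")
        archive.frame.to_csv(fh, index=False)


def read_forecast_archive(path) -> ForecastArchive:
    metadata = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition(": ")
            metadata[key] = int(value) if value.lstrip("-").isdigit() else value
        frame = pd.read_csv(fh, float_precision="round_trip")
    archive = ForecastArchive(frame=frame, metadata=metadata)
    archive.validate()
    return archive


def evaluate_archive(
    archive: ForecastArchive, observed: pd.DataFrame, allow_in_sample: bool = False
) -> pd.DataFrame:
    """Join an archive against observations and compute the metric table.

    Refuses to evaluate against observations from the archive's own
    training period unless ``allow_in_sample`` acknowledges the in-sample
    comparison.
    """
    train_end = int(archive.metadata["train_end"])
    in_sample = observed["year"] <= train_end
    if in_sample.any() and not allow_in_sample:
        raise ValueError(
            f"{int(in_sample.sum())} observations fall in the training period "
            f"(<= {train_end}); pass allow_in_sample=True to evaluate anyway"
        )
    sets = {
        (model, corrected): grp
        for (model, corrected), grp in archive.frame.groupby(["model", "corrected"])
    }
    return evaluation.metrics_table(sets, observed)
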