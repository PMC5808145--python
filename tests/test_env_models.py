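"""Environmental model tests: GBM benchmarks, stacked-SDM probabilities and
the Bernoulli-sum variance, JSDM reductions and recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import richcast as rc
from richcast import env_models


def _cov(n, seed=0, year=2000):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "site_id": [f"s{i:04d}" for i in range(n)],
        "year": year,
        "env1": rng.uniform(0, 1, n),
        "env2": rng.uniform(0, 1, n),
    })


def test_gbm_recovers_step_function():
    cov = _cov(400, seed=1)
    y = np.where(cov["env1"] > 0.5, 70.0, 30.0)
    fit = rc.fit_richness_gbm(cov, y, rc.GbmSpec(max_trees=400), seed=2)
    hold = _cov(300, seed=3)
    truth = np.where(hold["env1"] > 0.5, 70.0, 30.0)
    pred, sd = fit.predict(hold)
    r2 = 1 - np.mean((pred - truth) ** 2) / truth.var()
    assert r2 > 0.95
    assert fit.selected_trees <= 400


def test_gbm_pure_noise_has_no_skill():
    rng = np.random.default_rng(5)
    cov = _cov(300, seed=5)
    y = rng.normal(50, 5, len(cov))
    fit = rc.fit_richness_gbm(cov, y, rc.GbmSpec(max_trees=300), seed=6)
    hold = _cov(300, seed=7)
    truth = np.random.default_rng(8).normal(50, 5, len(hold))
    pred, _ = fit.predict(hold)
    r2 = 1 - np.mean((pred - truth) ** 2) / truth.var()
    assert abs(r2) < 0.2
    # OOB selection truncates a no-signal fit before the tree budget and
    # leaves predictions close to the plain mean
    assert fit.selected_trees < 300
    assert np.std(pred) < 0.5 * np.std(y)


def test_gbm_identical_covariates_identical_predictions():
    cov = _cov(200, seed=9)
    y = 30 + 40 * cov["env1"].to_numpy() + np.random.default_rng(9).normal(0, 2, 200)
    fit = rc.fit_richness_gbm(cov, y, rc.GbmSpec(max_trees=200), seed=10)
    twin = cov.head(20).copy()
    twin["site_id"] = "elsewhere"
    p1, _ = fit.predict(cov.head(20))
    p2, _ = fit.predict(twin)
    assert np.array_equal(p1, p2)


def test_gbm_constant_response_warns():
    cov = _cov(50, seed=11)
    with pytest.warns(UserWarning, match="constant"):
        fit = rc.fit_richness_gbm(cov, np.full(50, 42.0), seed=12)
    pred, sd = fit.predict(cov)
    assert np.all(pred == 42.0) and np.all(sd == 0.0)


def _threshold_community(n=300, seed=13):
    cov = _cov(n, seed=seed)
    det1 = (cov["env1"] > 0.5).astype(int)
    det2 = (cov["env2"] > 0.4).astype(int)
    rows = []
    for i in range(n):
        rows.append((cov["site_id"][i], 2000, "sp_a", det1[i]))
        rows.append((cov["site_id"][i], 2000, "sp_b", det2[i]))
    comm = pd.DataFrame(rows, columns=["site_id", "year", "species_id", "detected"])
    return cov, comm


def test_stacked_sdm_learns_threshold_species():
    cov, comm = _threshold_community(n=500)
    sdm = rc.fit_stacked_sdm(comm, cov, n_trees=300, seed=14)
    hold = _cov(200, seed=15)
    X = hold[sdm.env_cols].to_numpy()
    p = sdm.forests["sp_a"].predict_proba_presence(X)
    # away from the decision edge, and inside the support of the other
    # covariate (forests are unreliable at the edge of the training range)
    clear = (np.abs(hold["env1"] - 0.5) > 0.2) & hold["env2"].between(0.05, 0.95)
    high = hold["env1"][clear] > 0.5
    assert p[clear.to_numpy()][high[clear].to_numpy()].min() > 0.9
    assert p[clear.to_numpy()][~high[clear].to_numpy()].max() < 0.1


def test_stacked_sdm_single_class_species_flagged():
    cov, comm = _threshold_community(n=60, seed=16)
    comm.loc[comm["species_id"] == "sp_b", "detected"] = 1
    with pytest.warns(UserWarning, match="single class"):
        sdm = rc.fit_stacked_sdm(comm, cov, n_trees=20, seed=17)
    assert "sp_b" in sdm.single_class
    fc = rc.predict_stacked_richness(sdm, cov)
    assert len(fc) == len(cov)


def test_stacked_richness_closed_form():
    """mean = sum p_i, var = sum p_i (1 - p_i): p = (1, 0, 0.5) gives
    mean 1.5 and variance 0.25; degenerate p in {0, 1} gives variance 0."""
    cov = _cov(3, seed=18)
    sdm = env_models.StackedSdm(
        forests={
            "a": env_models._ConstantProb(1.0),
            "b": env_models._ConstantProb(0.0),
            "c": env_models._ConstantProb(0.5),
        },
        env_cols=["env1", "env2"], species=["a", "b", "c"],
    )
    fc = rc.predict_stacked_richness(sdm, cov)
    assert np.allclose(fc["mean"], 1.5)
    assert np.allclose(fc["sd"] ** 2, 0.25)
    sdm.forests["c"] = env_models._ConstantProb(1.0)
    fc = rc.predict_stacked_richness(sdm, cov)
    assert np.allclose(fc["sd"], 0.0)


def test_stacked_variance_matches_bernoulli_monte_carlo():
    rng = np.random.default_rng(19)
    p = rng.uniform(0.05, 0.95, 40)
    sdm = env_models.StackedSdm(
        forests={f"s{i}": env_models._ConstantProb(pi) for i, pi in enumerate(p)},
        env_cols=["env1", "env2"], species=[f"s{i}" for i in range(40)],
    )
    fc = rc.predict_stacked_richness(sdm, _cov(1, seed=20))
    draws = (rng.uniform(size=(200_000, 40)) < p).sum(axis=1)
    assert fc["mean"][0] == pytest.approx(draws.mean(), abs=0.05)
    assert fc["sd"][0] ** 2 == pytest.approx(draws.var(ddof=1), rel=0.02)


def test_stacked_corrected_with_zero_effects_agrees_in_expectation():
    """With all observer-effect draws at zero, the per-tree-draw forest and
    the plain forest agree up to forest-level Monte-Carlo noise."""
    cov, comm = _threshold_community(n=250, seed=21)
    zero_draws = np.zeros((10, len(cov)))
    plain = rc.fit_stacked_sdm(comm, cov, n_trees=150, seed=22)
    corr = rc.fit_stacked_sdm(comm, cov, observer_draws=zero_draws,
                              n_trees=150, seed=23)
    hold = _cov(150, seed=24)
    X = hold[plain.env_cols].to_numpy()
    p1 = plain.forests["sp_a"].predict_proba_presence(X)
    p2 = corr.forests["sp_a"].predict_proba_presence(X)
    assert np.mean(np.abs(p1 - p2)) < 0.08


def test_jsdm_without_latents_matches_independent_logistic(small_community):
    _, cov, comm, _ = small_community
    fit = rc.fit_jsdm(comm, cov, n_latent=0, seed=1)
    import statsmodels.api as sm
    wide = comm.pivot_table(index=["site_id", "year"], columns="species_id",
                            values="detected")
    X = cov.set_index(["site_id", "year"]).loc[wide.index][["env1", "env2"]].to_numpy()
    Xs = (X - fit.x_mean) / fit.x_scale
    for j, sp in enumerate(fit.species[:5]):
        y = wide[sp].to_numpy()
        if y.min() == y.max():
            continue
        res = sm.Logit(y, sm.add_constant(Xs)).fit(disp=0)
        assert fit.alpha[j] == pytest.approx(res.params[0], abs=0.02)
        assert np.allclose(fit.beta[j], res.params[1:], atol=0.02)


def test_jsdm_recovers_latent_loadings():
    """One strong latent factor: the estimated loading vector is colinear
    with the generating loadings (|r| > 0.7)."""
    cfg = rc.SimConfig(n_sites=150, year_start=1995, year_end=2004,
                       n_species=25, n_latent=1, seed=5, p_observe=1.0,
                       sigma_obs=0.0)
    cov = rc.simulate_covariates(cfg)
    comm, _ = rc.simulate_community_panel(cfg, cov)
    fit = rc.fit_jsdm(comm, cov, n_latent=1, seed=1, n_mc=48)
    lam_true = comm.attrs["truth"]["loadings"]
    r = np.corrcoef(lam_true.ravel(), fit.loadings.ravel())[0, 1]
    assert abs(r) > 0.7


def test_jsdm_species_permutation_symmetry(small_community):
    _, cov, comm, _ = small_community
    fit = rc.fit_jsdm(comm, cov, n_latent=0, seed=1)
    renamed = comm.copy()
    mapping = {sp: f"zz_{sp}" for sp in fit.species}
    renamed["species_id"] = renamed["species_id"].map(mapping)
    fit2 = rc.fit_jsdm(renamed, cov, n_latent=0, seed=1)
    # species sort order is preserved under the zz_ prefix
    assert np.allclose(fit2.alpha, fit.alpha, atol=1e-6)
    assert np.allclose(fit2.beta, fit.beta, atol=1e-6)


def test_jsdm_zero_loadings_reduce_to_stacked_formula(small_community):
    _, cov, comm, _ = small_community
    fit = rc.fit_jsdm(comm, cov, n_latent=0, seed=1)
    head = cov.head(15)
    fc = rc.predict_jsdm_richness(fit, head, n_samples=6000, seed=2)
    Xs = (head[["env1", "env2"]].to_numpy() - fit.x_mean) / fit.x_scale
    p = expit(fit.alpha[None, :] + Xs @ fit.beta.T)
    assert np.allclose(fc["mean"], p.sum(axis=1), atol=0.25)
    assert np.allclose(fc["sd"], np.sqrt((p * (1 - p)).sum(axis=1)), atol=0.2)


def test_jsdm_latents_widen_intervals(small_community):
    """Nonzero loadings produce predictive SDs above the independent-
    Bernoulli SD computed from the same marginal probabilities."""
    _, cov, comm, _ = small_community
    fit = rc.fit_jsdm(comm, cov, n_latent=1, seed=1, n_mc=32)
    assert np.abs(fit.loadings).max() > 0.2
    head = cov.head(10)
    fc = rc.predict_jsdm_richness(fit, head, n_samples=6000, seed=3)
    # independent-Bernoulli SD from the JSDM's own marginal probabilities
    rng = np.random.default_rng(4)
    Xs = (head[["env1", "env2"]].to_numpy() - fit.x_mean) / fit.x_scale
    z = rng.standard_normal((4000, 1))
    sd_indep = []
    for j in range(len(head)):
        p_marg = expit(fit.alpha[None, :] + Xs[j][None, :] @ fit.beta.T
                       + z @ fit.loadings.T).mean(axis=0)
        sd_indep.append(np.sqrt((p_marg * (1 - p_marg)).sum()))
    assert np.mean(fc["sd"].to_numpy() - np.asarray(sd_indep)) > 0


def test_jsdm_prediction_stabilizes_with_samples(small_community):
    _, cov, comm, _ = small_community
    fit = rc.fit_jsdm(comm, cov, n_latent=0, seed=1)
    head = cov.head(5)
    a = rc.predict_jsdm_richness(fit, head, n_samples=20_000, seed=5)
    b = rc.predict_jsdm_richness(fit, head, n_samples=20_000, seed=6)
    assert np.abs(a["mean"] - b["mean"]).max() < 0.1
    with pytest.raises(ValueError):
        rc.predict_jsdm_richness(fit, head, n_samples=10)
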