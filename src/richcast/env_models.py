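"""Environmental richness forecasters: GBM, stacked SDMs, latent-factor JSDM.

These models are trained across all sites with no site-identity predictors,
so two site-years with identical covariates receive identical predictive
distributions.  Three variants are implemented:

* richness GBM — boosted regression trees on richness directly (squared
  error loss, interaction depth 5, shrinkage 0.015, up to 10,000 trees with
  the tree count chosen by the out-of-bag improvement estimator);
* stacked SDMs — one random forest per species predicting occurrence;
  richness mean is the sum of occurrence probabilities and its variance the
  independent-Bernoulli sum  sigma^2 = sum_i p_i (1 - p_i);
* JSDM — a latent-factor logistic joint model in which shared site latent
  variables induce inter-species dependence and hence over-dispersed
  richness relative to the independent-Bernoulli formula.  It is fit by
  Monte-Carlo maximum marginal likelihood over fixed standard-normal latent
  draws (common random numbers, so the objective is deterministic given the
  seed).

Observer correction: the stacked SDMs give each tree a different posterior
draw of the training observer effects as an extra predictor (effect 0, the
"typical observer", at prediction time); the GBM and JSDM take the
posterior-mean observer effect as one extra column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.ensemble import GradientBoostingRegressor, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "GbmSpec",
    "GbmModel",
    "JsdmFit",
    "fit_richness_gbm",
    "fit_stacked_sdm",
    "predict_stacked_richness",
    "fit_jsdm",
    "predict_jsdm_richness",
]

KEY_COLS = ("site_id", "year")


def _design(covariates: pd.DataFrame, env_cols=None):
    cols = (
        [c for c in covariates.columns if c not in KEY_COLS]
        if env_cols is None
        else list(env_cols)
    )
    return covariates[cols].to_numpy(dtype=float), cols


# ---------------------------------------------------------------- GBM

@dataclass
class GbmSpec:
    interaction_depth: int = 5
    shrinkage: float = 0.015
    max_trees: int = 10_000
    subsample: float = 0.5      # enables the out-of-bag improvement estimator


@dataclass
class GbmModel:
    model: GradientBoostingRegressor
    env_cols: list
    selected_trees: int
    resid_sd: float
    constant: float | None = None

    def predict(self, covariates: pd.DataFrame):
        """Gaussian summary (mean, sd) per covariate row; homoscedastic sd."""
        if self.constant is not None:
            mean = np.full(len(covariates), self.constant)
        else:
            X, _ = _design(covariates, self.env_cols)
            mean = self.model.predict(X)
        return mean, np.full(len(covariates), self.resid_sd)


def fit_richness_gbm(
    covariates: pd.DataFrame,
    richness,
    spec: GbmSpec | None = None,
    seed: int = 0,
    observer_effect=None,
) -> GbmModel:
    """Boosted-tree richness model with out-of-bag tree-count selection.

    ``covariates`` rows align with ``richness``; ``observer_effect``
    (posterior-mean per row) is appended as an extra predictor when given.
    The ensemble is truncated at the tree count maximizing the cumulative
    out-of-bag improvement, and the predictive SD is the training-residual
    SD of the truncated model.
    """
    spec = spec or GbmSpec()
    y = np.asarray(richness, dtype=float)
    X, cols = _design(covariates)
    if observer_effect is not None:
        X = np.column_stack([X, np.asarray(observer_effect, dtype=float)])
        cols = cols + ["observer_effect"]
    if np.ptp(y) == 0:
        warnings.warn("constant response; returning constant predictor", stacklevel=2)
        return GbmModel(model=None, env_cols=cols, selected_trees=0,
                        resid_sd=0.0, constant=float(y[0]))
    gbr = GradientBoostingRegressor(
        loss="squared_error",
        max_depth=spec.interaction_depth,
        learning_rate=spec.shrinkage,
        n_estimators=spec.max_trees,
        subsample=spec.subsample,
        random_state=seed,
    )
    gbr.fit(X, y)
    best_n = int(np.argmax(np.cumsum(gbr.oob_improvement_))) + 1
    gbr.estimators_ = gbr.estimators_[:best_n]  # truncate at the OOB optimum
    resid = y - gbr.predict(X)
    return GbmModel(model=gbr, env_cols=cols, selected_trees=best_n,
                    resid_sd=float(resid.std(ddof=1)))


# ---------------------------------------------------------------- stacked SDMs

class _ConstantProb:
    """Stand-in forest for a species observed in a single class."""

    def __init__(self, p: float):
        self.p = float(p)

    def predict_proba_presence(self, X, obs_col=None):
        return np.full(X.shape[0], self.p)


class _VoteForest:
    """Random forest reporting the fraction of trees voting presence."""

    def __init__(self, forest: RandomForestClassifier):
        self.forest = forest

    def predict_proba_presence(self, X, obs_col=None):
        votes = np.stack([t.predict(X.astype(np.float32)) for t in self.forest.estimators_])
        return votes.mean(axis=0)


class _DrawForest:
    """Per-tree forest where tree t saw observer-effect draw t as a predictor.

    At prediction time the observer-effect column is 0 (typical observer)
    unless an explicit column is supplied.
    """

    def __init__(self, trees):
        self.trees = trees

    def predict_proba_presence(self, X, obs_col=None):
        col = np.zeros(X.shape[0]) if obs_col is None else np.asarray(obs_col)
        Xa = np.column_stack([X, col])
        votes = np.stack([t.predict(Xa) for t in self.trees])
        return votes.mean(axis=0)


@dataclass
class StackedSdm:
    forests: dict
    env_cols: list
    species: list
    single_class: list = field(default_factory=list)


def fit_stacked_sdm(
    community_train: pd.DataFrame,
    covariates: pd.DataFrame,
    observer_draws: np.ndarray | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> StackedSdm:
    """One presence/absence random forest per species.

    ``community_train`` is long (site_id, year, species_id, detected);
    ``covariates`` supplies one row per training site-year.  In corrected
    mode ``observer_draws`` is an (n_draws, n_site_years) array of observer
    effects aligned to the covariate rows: tree t trains with draw
    t mod n_draws as an extra predictor.  Species seen in only one class
    get a constant-probability stand-in (flagged).  Probabilities are the
    fraction of trees voting presence; minimum leaf size 5.
    """
    wide = community_train.pivot_table(
        index=["site_id", "year"], columns="species_id", values="detected"
    )
    if wide.isna().any().any():
        raise KeyError("community panel does not cover every site-year x species")
    keys = wide.index.to_frame(index=False)
    cov = covariates.set_index(["site_id", "year"])
    try:
        cov_rows = cov.loc[list(wide.index)]
    except KeyError as exc:
        raise KeyError(f"covariates missing training site-years: {exc}") from exc
    X, cols = _design(cov_rows.reset_index(), env_cols=None)

    rng = np.random.default_rng(seed)
    forests: dict = {}
    single_class: list = []
    for species in wide.columns:
        y = wide[species].to_numpy(dtype=int)
        if y.min() == y.max():
            single_class.append(species)
            warnings.warn(f"species {species} has a single class; constant probability",
                          stacklevel=2)
            forests[species] = _ConstantProb(float(y[0]))
            continue
        if observer_draws is None:
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                min_samples_leaf=5,
                max_features="sqrt",
                random_state=int(rng.integers(2**31 - 1)),
            )
            rf.fit(X.astype(np.float32), y)
            forests[species] = _VoteForest(rf)
        else:
            n_draws = observer_draws.shape[0]
            trees = []
            for t in range(n_trees):
                Xt = np.column_stack([X, observer_draws[t % n_draws]])
                boot = rng.integers(0, X.shape[0], X.shape[0])
                if y[boot].min() == y[boot].max():
                    continue  # degenerate bootstrap resample
                tree = DecisionTreeClassifier(
                    max_features="sqrt",
                    min_samples_leaf=5,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                tree.fit(Xt[boot], y[boot])
                trees.append(tree)
            forests[species] = (
                _DrawForest(trees) if trees else _ConstantProb(float(y.mean()))
            )
    return StackedSdm(forests=forests, env_cols=cols,
                      species=list(wide.columns), single_class=single_class)


def predict_stacked_richness(
    sdm: StackedSdm, covariates: pd.DataFrame, observer_effect=None
) -> pd.DataFrame:
    """Richness forecast by stacking: mean = sum p_i, var = sum p_i(1-p_i).

    ``observer_effect`` (per covariate row) feeds the observer-effect
    predictor of draw-trained forests; plain forests ignore it.
    """
    X = covariates[sdm.env_cols].to_numpy(dtype=float)
    P = np.stack(
        [
            sdm.forests[sp].predict_proba_presence(X, obs_col=observer_effect)
            for sp in sdm.species
        ],
        axis=1,
    )
    mean = P.sum(axis=1)
    var = (P * (1.0 - P)).sum(axis=1)
    out = covariates[list(KEY_COLS)].copy()
    out["mean"] = mean
    out["sd"] = np.sqrt(var)
    return out


# ---------------------------------------------------------------- JSDM

@dataclass
class JsdmFit:
    """Latent-factor logistic JSDM parameters.

    Occupancy logit for species i in row j with latent z:
    alpha[i] + X[j] @ beta[i] + z @ loadings[i], z ~ N(0, I_n_latent).
    Covariates are standardized internally; the stored scale is applied at
    prediction.
    """

    species: list
    env_cols: list
    alpha: np.ndarray            # (S,)
    beta: np.ndarray             # (S, n_env)
    loadings: np.ndarray         # (S, n_latent)
    n_latent: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    converged: bool = True


def _community_matrix(community: pd.DataFrame, covariates: pd.DataFrame):
    wide = community.pivot_table(
        index=["site_id", "year"], columns="species_id", values="detected"
    )
    cov = covariates.set_index(["site_id", "year"])
    try:
        cov_rows = cov.loc[list(wide.index)]
    except KeyError as exc:
        raise KeyError(f"covariates missing site-years: {exc}") from exc
    X, cols = _design(cov_rows.reset_index(), env_cols=None)
    return wide, X, cols


def fit_jsdm(
    community_train: pd.DataFrame,
    covariates: pd.DataFrame,
    observer_effect=None,
    n_latent: int = 2,
    seed: int = 0,
    n_mc: int = 32,
    max_iter: int = 300,
) -> JsdmFit:
    """Fit the latent-factor JSDM by Monte-Carlo maximum likelihood.

    The marginal likelihood integrates the latent factors out with K =
    ``n_mc`` fixed standard-normal draws (importance weights via softmax),
    optimized by L-BFGS with an analytic gradient.  With ``n_latent=0``
    this reduces to independent per-species logistic regressions.  The
    posterior-mean ``observer_effect`` per row is appended as an extra
    covariate when given.
    """
    Y_wide, X, cols = _community_matrix(community_train, covariates)
    if observer_effect is not None:
        X = np.column_stack([X, np.asarray(observer_effect, dtype=float)])
        cols = cols + ["observer_effect"]
    Y = Y_wide.to_numpy(dtype=float)
    J, S = Y.shape
    x_mean = X.mean(axis=0)
    x_scale = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Xs = (X - x_mean) / x_scale
    E = Xs.shape[1]
    L = n_latent

    rng = np.random.default_rng(seed)
    K = n_mc if L > 0 else 1
    Z = rng.standard_normal((K, L)) if L > 0 else np.zeros((1, 0))

    prev = np.clip(Y.mean(axis=0), 1e-3, 1 - 1e-3)
    alpha0 = np.log(prev / (1 - prev))
    theta0 = np.concatenate(
        [alpha0, np.zeros(S * E), 0.1 * rng.standard_normal(S * L)]
    )

    def unpack(theta):
        alpha = theta[:S]
        beta = theta[S:S + S * E].reshape(S, E)
        lam = theta[S + S * E:].reshape(S, L)
        return alpha, beta, lam

    def nll_grad(theta):
        alpha, beta, lam = unpack(theta)
        # eta: (J, K, S)
        eta = alpha[None, None, :] + (Xs @ beta.T)[:, None, :]
        if L > 0:
            eta = eta + (Z @ lam.T)[None, :, :]
        # per-row, per-draw complete-data log-likelihood f: (J, K)
        f = (Y[:, None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=2)
        lse = logsumexp(f, axis=1)
        nll = -(lse.sum() - J * np.log(K))
        w = np.exp(f - lse[:, None])            # softmax weights (J, K)
        g_eta = w[:, :, None] * (Y[:, None, :] - expit(eta))   # (J, K, S)
        g_alpha = -g_eta.sum(axis=(0, 1))
        g_beta = -np.einsum("jks,je->se", g_eta, Xs)
        g_lam = (
            -np.einsum("jks,kl->sl", g_eta, Z) if L > 0 else np.zeros((S, 0))
        )
        grad = np.concatenate([g_alpha, g_beta.ravel(), g_lam.ravel()])
        return nll, grad

    res = minimize(nll_grad, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    if not res.success:
        warnings.warn(f"JSDM optimizer did not converge: {res.message}", stacklevel=2)
    alpha, beta, lam = unpack(res.x)
    return JsdmFit(
        species=list(Y_wide.columns), env_cols=cols, alpha=alpha, beta=beta,
        loadings=lam, n_latent=L, x_mean=x_mean, x_scale=x_scale,
        converged=bool(res.success),
    )


def predict_jsdm_richness(
    fit: JsdmFit,
    covariates: pd.DataFrame,
    n_samples: int = 1000,
    seed: int = 0,
    observer_effect=None,
) -> pd.DataFrame:
    """Monte-Carlo richness forecast from the JSDM.

    For each covariate row, sample latent factors, compute per-species
    occupancy probabilities, draw Bernoulli detections, and summarize the
    sampled richness with its mean and SD (Gaussian summary).
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100 for a stable summary")
    cols = [c for c in fit.env_cols if c != "observer_effect"]
    X = covariates[cols].to_numpy(dtype=float)
    if "observer_effect" in fit.env_cols:
        col = (np.zeros(len(covariates)) if observer_effect is None
               else np.asarray(observer_effect, dtype=float))
        X = np.column_stack([X, col])
    Xs = (X - fit.x_mean) / fit.x_scale
    J = Xs.shape[0]
    rng = np.random.default_rng(seed)

    base = fit.alpha[None, :] + Xs @ fit.beta.T      # (J, S)
    mean = np.empty(J)
    sd = np.empty(J)
    for j in range(J):
        z = (rng.standard_normal((n_samples, fit.n_latent))
             if fit.n_latent > 0 else np.zeros((n_samples, 0)))
        eta = base[j][None, :] + z @ fit.loadings.T
        p = expit(eta)
        rich = (rng.uniform(size=p.shape) < p).sum(axis=1)
        mean[j] = rich.mean()
        sd[j] = rich.std(ddof=1)
    out = covariates[list(KEY_COLS)].copy()
    out["mean"] = mean
    out["sd"] = sd
    return out
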