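"""Hierarchical site + observer mixed model for richness panels.

The model is

    y[i] = mu + a[site(i)] + b[observer(i)] + eps[i]

with exchangeable normal random effects ``a ~ N(0, sigma_site^2)``,
``b ~ N(0, sigma_obs^2)`` and iid residuals ``eps ~ N(0, sigma_resid^2)``.
Because observers tend to repeatedly survey the same site, site effects are
essential to keep inferred observer deviations observer-related rather than
site-related.  The model partitions richness variance into site, observer,
and residual components and supplies posterior draws of the observer
effects that downstream forecasters subtract to obtain the richness a
"typical" observer would have recorded.

Sampling is blocked Gibbs with conjugate normal updates for ``mu``, ``a``,
``b`` and inverse-gamma updates for the three variances under a half-t
(nu = 2, scale 25 species) prior on each SD, implemented through the
Huang-Wand inverse-gamma auxiliary-variable hierarchy so every conditional
is conjugate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ObserverPosterior",
    "VariancePartition",
    "fit_observer_model",
    "variance_partition",
    "corrected_richness_draws",
    "posterior_mean_observer_effects",
    "write_posterior",
    "read_posterior",
]

_HALF_T_NU = 2.0


@dataclass
class ObserverPosterior:
    """Posterior draws from the site + observer mixed model.

    Arrays are indexed by draw; ``site_effects`` / ``observer_effects`` are
    DataFrames of shape (n_draws, n_levels) with level tokens as columns.
    ``rhat`` maps each variance parameter to its split-chain potential
    scale reduction factor.
    """

    mu: np.ndarray
    site_effects: pd.DataFrame
    observer_effects: pd.DataFrame
    sigma_site: np.ndarray
    sigma_obs: np.ndarray
    sigma_resid: np.ndarray
    rhat: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.mu.size


@dataclass
class VariancePartition:
    frac_site: float
    frac_obs: float
    frac_resid: float
    sd_resid: float

    def __post_init__(self) -> None:
        total = self.frac_site + self.frac_obs + self.frac_resid
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variance fractions sum to {total}, not 1")


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction on a single chain of draws."""
    n = x.size // 2
    if n < 2:
        return float("nan")
    chains = np.stack([x[:n], x[n:2 * n]])
    within = chains.var(axis=1, ddof=1).mean()
    between = n * chains.mean(axis=1).var(ddof=1)
    if within == 0:
        return float("nan")
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def fit_observer_model(
    train: pd.DataFrame,
    n_draws: int = 500,
    seed: int = 0,
    warmup: int = 1000,
    prior_scale: float = 25.0,
) -> ObserverPosterior:
    """Fit the site + observer model by blocked Gibbs sampling.

    Parameters
    ----------
    train : richness panel (site_id, year, observer_id, richness)
    n_draws : post-warmup draws to keep (default 500).
    warmup : burn-in iterations discarded before keeping draws.
    prior_scale : scale (species) of the half-t prior on each SD.

    Notes
    -----
    If every site is surveyed by a single observer throughout, site and
    observer effects are confounded; a warning is emitted and the fit is
    still returned.
    """
    if train["site_id"].nunique() < 2:
        raise ValueError("need at least 2 sites to separate site and observer variance")
    y = train["richness"].to_numpy(dtype=float)
    sites, s_idx = np.unique(train["site_id"].to_numpy(), return_inverse=True)
    obs, o_idx = np.unique(train["observer_id"].to_numpy(), return_inverse=True)
    n, S, O = y.size, sites.size, obs.size

    obs_per_site = (
        train.groupby("site_id")["observer_id"].nunique().to_numpy()
    )
    if np.all(obs_per_site == 1):
        warnings.warn(
            "every site has exactly one observer: site and observer effects "
            "are confounded; variance attribution is unreliable",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    n_s = np.bincount(s_idx, minlength=S).astype(float)
    n_o = np.bincount(o_idx, minlength=O).astype(float)

    # init at data-driven values
    mu = y.mean()
    a = np.zeros(S)
    b = np.zeros(O)
    sig2_a = max(np.var(train.groupby("site_id")["richness"].mean()), 1.0)
    sig2_b = 1.0
    sig2_e = max(y.var(), 1.0)
    aux_a = aux_b = aux_e = 1.0

    nu, A2 = _HALF_T_NU, prior_scale**2
    keep_mu = np.empty(n_draws)
    keep_a = np.empty((n_draws, S))
    keep_b = np.empty((n_draws, O))
    keep_sa = np.empty(n_draws)
    keep_sb = np.empty(n_draws)
    keep_se = np.empty(n_draws)

    for it in range(warmup + n_draws):
        # mu | rest  (flat prior)
        r = y - a[s_idx] - b[o_idx]
        mu = rng.normal(r.mean(), np.sqrt(sig2_e / n))

        # a | rest, blocked over sites
        r = y - mu - b[o_idx]
        prec = n_s / sig2_e + 1.0 / sig2_a
        mean = (np.bincount(s_idx, weights=r, minlength=S) / sig2_e) / prec
        a = mean + rng.standard_normal(S) / np.sqrt(prec)

        # b | rest, blocked over observers
        r = y - mu - a[s_idx]
        prec = n_o / sig2_e + 1.0 / sig2_b
        mean = (np.bincount(o_idx, weights=r, minlength=O) / sig2_e) / prec
        b = mean + rng.standard_normal(O) / np.sqrt(prec)

        # variances (Huang-Wand half-t hierarchy)
        sig2_a = 1.0 / rng.gamma((nu + S) / 2.0, 1.0 / (nu / aux_a + 0.5 * a @ a))
        aux_a = 1.0 / rng.gamma((nu + 1) / 2.0, 1.0 / (nu / sig2_a + 1.0 / A2))
        sig2_b = 1.0 / rng.gamma((nu + O) / 2.0, 1.0 / (nu / aux_b + 0.5 * b @ b))
        aux_b = 1.0 / rng.gamma((nu + 1) / 2.0, 1.0 / (nu / sig2_b + 1.0 / A2))
        eps = y - mu - a[s_idx] - b[o_idx]
        sig2_e = 1.0 / rng.gamma((nu + n) / 2.0, 1.0 / (nu / aux_e + 0.5 * eps @ eps))
        aux_e = 1.0 / rng.gamma((nu + 1) / 2.0, 1.0 / (nu / sig2_e + 1.0 / A2))

        if it >= warmup:
            k = it - warmup
            keep_mu[k] = mu
            keep_a[k] = a
            keep_b[k] = b
            keep_sa[k] = np.sqrt(sig2_a)
            keep_sb[k] = np.sqrt(sig2_b)
            keep_se[k] = np.sqrt(sig2_e)

    rhat = {
        "sigma_site": _split_rhat(keep_sa),
        "sigma_obs": _split_rhat(keep_sb),
        "sigma_resid": _split_rhat(keep_se),
    }
    return ObserverPosterior(
        mu=keep_mu,
        site_effects=pd.DataFrame(keep_a, columns=list(sites)),
        observer_effects=pd.DataFrame(keep_b, columns=list(obs)),
        sigma_site=keep_sa,
        sigma_obs=keep_sb,
        sigma_resid=keep_se,
        rhat=rhat,
    )


def variance_partition(post: ObserverPosterior) -> VariancePartition:
    """Posterior-mean variance fractions, computed per draw then averaged."""
    v = np.stack([post.sigma_site**2, post.sigma_obs**2, post.sigma_resid**2])
    frac = v / v.sum(axis=0)
    f = frac.mean(axis=1)
    f = f / f.sum()  # guard rounding so fractions sum to 1 exactly
    return VariancePartition(
        frac_site=float(f[0]),
        frac_obs=float(f[1]),
        frac_resid=float(f[2]),
        sd_resid=float(post.sigma_resid.mean()),
    )


def _observer_effect_matrix(panel: pd.DataFrame, post: ObserverPosterior) -> np.ndarray:
    """(n_draws, n_rows) observer effects aligned to panel rows; unseen -> 0."""
    known = post.observer_effects.columns
    eff = np.zeros((post.n_draws, len(panel)))
    obs = panel["observer_id"].to_numpy()
    unseen = set()
    col_index = {c: j for j, c in enumerate(known)}
    for i, o in enumerate(obs):
        j = col_index.get(o)
        if j is None:
            unseen.add(o)
        else:
            eff[:, i] = post.observer_effects.iloc[:, j].to_numpy()
    if unseen:
        warnings.warn(
            f"{len(unseen)} observers unseen in training get effect 0",
            stacklevel=3,
        )
    return eff


def corrected_richness_draws(
    panel: pd.DataFrame, post: ObserverPosterior
) -> list[pd.DataFrame]:
    """Observer-corrected panels, one per posterior draw.

    Draw ``d``'s panel carries richness ``y - b_obs^(d)``: the richness a
    typical (zero-effect) observer would have recorded.  Observers absent
    from the posterior get effect 0 (with a warning).
    """
    eff = _observer_effect_matrix(panel, post)
    out = []
    for d in range(post.n_draws):
        p = panel.copy()
        p["richness"] = panel["richness"].to_numpy(dtype=float) - eff[d]
        out.append(p)
    return out


def posterior_mean_observer_effects(
    panel: pd.DataFrame, post: ObserverPosterior
) -> np.ndarray:
    """Posterior-mean observer effect per panel row (unseen observers -> 0)."""
    return _observer_effect_matrix(panel, post).mean(axis=0)


def write_posterior(post: ObserverPosterior, path) -> None:
    """Serialize draws to long columnar text (draw, parameter, level, value)."""
    parts = [
        pd.DataFrame({"draw": np.arange(post.n_draws), "parameter": "mu",
                      "level": "", "value": post.mu}),
    ]
    for name, arr in (("sigma_site", post.sigma_site),
                      ("sigma_obs", post.sigma_obs),
                      ("sigma_resid", post.sigma_resid)):
        parts.append(pd.DataFrame({"draw": np.arange(post.n_draws),
                                   "parameter": name, "level": "", "value": arr}))
    for name, frame in (("site_effect", post.site_effects),
                        ("observer_effect", post.observer_effects)):
        long = frame.reset_index(names="draw").melt(
            id_vars="draw", var_name="level", value_name="value"
        )
        long.insert(1, "parameter", name)
        parts.append(long)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_posterior(path) -> ObserverPosterior:
    long = pd.read_csv(path, keep_default_na=False)
    scalars = {}
    for name in ("mu", "sigma_site", "sigma_obs", "sigma_resid"):
        sub = long[long["parameter"] == name].sort_values("draw")
        scalars[name] = sub["value"].to_numpy(dtype=float)
    frames = {}
    for name in ("site_effect", "observer_effect"):
        sub = long[long["parameter"] == name]
        frames[name] = sub.pivot(index="draw", columns="level", values="value")
        frames[name].columns.name = None
        frames[name].index.name = None
    return ObserverPosterior(
        mu=scalars["mu"],
        site_effects=frames["site_effect"],
        observer_effects=frames["observer_effect"],
        sigma_site=scalars["sigma_site"],
        sigma_obs=scalars["sigma_obs"],
        sigma_resid=scalars["sigma_resid"],
    )
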