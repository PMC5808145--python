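import numpy as np
import pandas as pd
import pytest

import richcast as rc


@pytest.fixture(scope="session")
def default_panel():
    """Mid-sized richness panel at the generator's default variance split."""
    cfg = rc.SimConfig(n_sites=120, seed=11, p_observe=1.0)
    panel, truth = rc.simulate_richness_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def default_posterior(default_panel):
    """Observer-model posterior fit to the default panel's training years."""
    _, panel, _ = default_panel
    train, _ = rc.split_train_test(panel, 2003)
    post = rc.fit_observer_model(train, n_draws=200, seed=21, warmup=500)
    return train, post


@pytest.fixture(scope="session")
def small_community():
    """Community panel with one latent factor and matching covariates."""
    cfg = rc.SimConfig(
        n_sites=60, year_start=1996, year_end=2005, n_species=18,
        n_latent=1, seed=31, p_observe=1.0,
    )
    cov = rc.simulate_covariates(cfg)
    community, richness = rc.simulate_community_panel(cfg, cov)
    return cfg, cov, community, richness


def toy_forecast(site_ids, years, mean, sd, horizon=None):
    frame = pd.DataFrame({
        "site_id": np.repeat(site_ids, len(years)),
        "year": np.tile(years, len(site_ids)),
    })
    frame["mean"] = np.asarray(mean, dtype=float)
    frame["sd"] = np.asarray(sd, dtype=float)
    if horizon is not None:
        frame["horizon"] = np.tile(horizon, len(site_ids))
    return frame
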