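import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

import guildnet as gn  # noqa: E402
from guildnet.data import HurdleResponse  # noqa: E402


@pytest.fixture(scope="session")
def small_study():
    """Small paired-guild simulation shared across tests."""
    cfg = gn.SimulationConfig(n_samples=60, n_species_fungi=12, n_species_bacteria=12,
                              n_factors=2, seed=3)
    return gn.simulate_community(cfg)


@pytest.fixture(scope="session")
def small_response(small_study):
    parts = [gn.assemble_hurdle_response(small_study.tables[g]) for g in ("fungi", "bacteria")]
    return gn.concat_hurdle_responses(*parts)


@pytest.fixture(scope="session")
def small_design(small_study):
    return gn.build_joint_design(small_study.metadata, "full")


@pytest.fixture(scope="session")
def small_fit(small_design, small_response):
    est = gn.HurdleLatentFactorJSDM(n_factors=2, n_chains=2, n_iter=800, n_burn=300,
                                    thin=5, random_state=11)
    return est.fit(small_design, small_response)


def make_single_species_response(pa: np.ndarray, abund: np.ndarray) -> HurdleResponse:
    """One-species hurdle response for oracle checks (already standardized)."""
    pa = np.asarray(pa, float)[:, None]
    ab = np.asarray(abund, float)[:, None]
    return HurdleResponse(
        pa=pd.DataFrame(pa), abund=pd.DataFrame(ab),
        log_mean=pd.Series([0.0]), log_sd=pd.Series([1.0]),
        guild=pd.Series(["fungi"]), degenerate=pd.Series([False]),
    )


def make_fake_fit(lam_draws: np.ndarray, sigma2_draws: np.ndarray,
                  beta_draws: np.ndarray | None = None, n_factors: int | None = None,
                  guild=None):
    """Assemble a fitted-looking estimator from crafted posterior draws.

    lam_draws: (d, 2p, q) over the duplicated response columns;
    sigma2_draws: (d, p); beta_draws: (d, 2p, k) optional.
    """
    d, ncol, q = lam_draws.shape
    p = ncol // 2
    if beta_draws is None:
        beta_draws = np.zeros((d, ncol, 1))
    k = beta_draws.shape[2]
    est = gn.HurdleLatentFactorJSDM(n_factors=n_factors if n_factors is not None else q)
    est.chains_ = [{
        "beta": beta_draws, "lam": lam_draws,
        "eta": np.zeros((d, 2, q)), "sigma2": sigma2_draws,
        "delta": np.ones((d, q)),
    }]
    est.n_draws_ = d
    est.p_ = p
    est.species_ = pd.Index([f"S{j}" for j in range(p)])
    est.guild_ = np.asarray(guild if guild is not None
                            else ["fungi"] * (p // 2) + ["bacteria"] * (p - p // 2))
    est.degenerate_ = np.zeros(p, bool)
    est.x_mean_ = np.zeros(k)
    est.x_scale_ = np.ones(k)
    est.beta_mean_ = beta_draws.mean(axis=0)
    est.lambda_mean_ = lam_draws.mean(axis=0)
    est.sigma2_mean_ = sigma2_draws.mean(axis=0)
    est.design_info_ = None
    return est
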