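"""Synthetic paired-guild communities from the hurdle latent-factor model.

The generator mirrors the fitted model: per species a probit occurrence part
and a lognormal abundance-given-presence part, both driven by deadwood
covariates (niches) and shared sample-level latent factors. Ground-truth
parameters are returned so that estimator output can be checked against them.
Counts are constructed by exponentiating the latent abundances and normalizing
to a per-sample target sequencing depth (the model itself specifies no count
law; this construction preserves the lognormal structure the model assumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import (
    DECAY_LEVELS,
    GUILDS,
    TREE_LEVELS,
    CommunityTable,
    DesignMatrix,
    build_joint_design,
)

# study design frequencies over the 118 sampled logs
TREE_FREQS = {"beech": 39, "fir": 36, "spruce": 43}
DECAY_FREQS = {"<5": 21, "5-15": 39, "16-38": 36, ">38": 22}


@dataclass
class SimulationConfig:
    """Conditions for the synthetic study.

    Defaults mirror the field study: 118 deadwood logs, 452 fungal and 570
    bacterial OTUs (post-filter scale), three latent factors, read depths in
    the low thousands to low tens of thousands. ``loading_scale_*`` controls
    the magnitude of factor loadings per guild (residual associations);
    ``niche_scale`` the magnitude of covariate responses.
    """

    n_samples: int = 118
    n_species_fungi: int = 452
    n_species_bacteria: int = 570
    n_factors: int = 3
    loading_scale_fungi: float = 1.0
    loading_scale_bacteria: float = 1.0
    niche_scale: float = 0.8
    intercept_mean: float = -0.6
    intercept_sd: float = 0.4
    sigma_abund_range: tuple[float, float] = (0.5, 1.1)
    count_scale: float = 1.0
    depth_log_mean: dict = field(default_factory=lambda: {"fungi": np.log(6000.0), "bacteria": np.log(5500.0)})
    depth_log_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_species_fungi", "n_species_bacteria", "n_factors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("loading_scale_fungi", "loading_scale_bacteria", "niche_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def n_species(self, guild: str) -> int:
        return {"fungi": self.n_species_fungi, "bacteria": self.n_species_bacteria}[guild]

    def loading_scale(self, guild: str) -> float:
        return {"fungi": self.loading_scale_fungi, "bacteria": self.loading_scale_bacteria}[guild]


def make_asymmetric_scenario(config: SimulationConfig | None = None) -> SimulationConfig:
    """Scenario with asymmetric guild coupling to the shared factors.

    Bacterial loadings are three times the fungal ones, so bacteria track the
    shared sample-level factors strongly while fungal variation is dominated by
    covariates. Conditioning on fungi then informs the factors enough to help
    predict bacteria, whereas conditioning on bacteria adds little for fungi —
    the directional signature the evaluation module tests for.
    """
    config = config or SimulationConfig()
    return replace(config, loading_scale_fungi=0.5, loading_scale_bacteria=1.5)


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Draw sample metadata emulating deadwood logs.

    Continuous covariates use ranges typical of decomposing beech/spruce/fir
    wood; tree species and decay class follow the study design frequencies;
    target read depths are lognormal per guild.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    def categorical(levels, freqs):
        p = np.array([freqs[l] for l in levels], float)
        return rng.choice(levels, size=n, p=p / p.sum())

    meta = pd.DataFrame(
        {
            "water": np.clip(rng.normal(45.0, 12.0, n), 5.0, 95.0),
            "ph": np.clip(rng.normal(4.6, 0.6, n), 3.0, 7.5),
            "c": np.clip(rng.normal(48.0, 2.0, n), 40.0, 56.0),
            "n": np.clip(rng.lognormal(np.log(0.2), 0.45, n), 0.03, 2.0),
            "lignin": np.clip(rng.normal(27.0, 5.0, n), 10.0, 50.0),
            "tree_species": categorical(TREE_LEVELS, TREE_FREQS),
            "decay_class": categorical(DECAY_LEVELS, DECAY_FREQS),
            "dbh": rng.uniform(30.0, 100.0, n),
        },
        index=pd.Index([f"log{i + 1:03d}" for i in range(n)], name="sample"),
    )
    for guild in GUILDS:
        depths = rng.lognormal(config.depth_log_mean[guild], config.depth_log_sd, n)
        meta[f"reads_{guild}"] = np.maximum(np.round(depths), 100).astype(int)
    return meta


class GroundTruth(NamedTuple):
    """Generative parameters on the standardized-design scale.

    ``beta``/``lam`` keyed by (guild, part) with part in {"occurrence",
    "abundance"}; ``R`` keyed by part holds the implied residual correlation
    matrix over the joint species set (fungi columns first).
    """

    beta: dict
    lam: dict
    eta: np.ndarray
    sigma: dict
    R: dict
    design: DesignMatrix
    x_std: np.ndarray
    species: dict


class SimulatedStudy(NamedTuple):
    tables: dict  # guild -> CommunityTable
    metadata: pd.DataFrame
    truth: GroundTruth


def standardize_columns(x: np.ndarray) -> np.ndarray:
    """Z-score non-constant columns; constant columns (intercept) untouched."""
    x = np.asarray(x, float).copy()
    sd = x.std(axis=0)
    nonconst = sd > 0
    x[:, nonconst] = (x[:, nonconst] - x[:, nonconst].mean(axis=0)) / sd[nonconst]
    return x


def true_association_matrix(lam_joint: np.ndarray, resid_var: np.ndarray) -> np.ndarray:
    """Correlation form of Omega = Lambda Lambda' + diag(resid_var)."""
    omega = lam_joint @ lam_joint.T + np.diag(resid_var)
    d = 1.0 / np.sqrt(np.diag(omega))
    return omega * d[:, None] * d[None, :]


def simulate_community(config: SimulationConfig, meta: pd.DataFrame | None = None) -> SimulatedStudy:
    """Simulate paired fungal/bacterial count tables with known ground truth."""
    if meta is None:
        meta = simulate_covariates(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    design = build_joint_design(meta, model="full")
    x = standardize_columns(design.values)
    n, k = x.shape
    q = config.n_factors
    eta = rng.standard_normal((n, q))

    beta, lam, sigma, species = {}, {}, {}, {}
    pa_parts, abund_parts = {}, {}
    for guild in GUILDS:
        p = config.n_species(guild)
        prefix = "F" if guild == "fungi" else "B"
        species[guild] = [f"{prefix}{j + 1:04d}" for j in range(p)]
        ls = config.loading_scale(guild)
        for part in ("occurrence", "abundance"):
            b = rng.normal(0.0, config.niche_scale, (k, p))
            if part == "occurrence":
                b[0] = rng.normal(config.intercept_mean, config.intercept_sd, p)
            else:
                b[0] = 0.0
            beta[guild, part] = b
            lam[guild, part] = rng.normal(0.0, ls, (p, q))
        sigma[guild] = rng.uniform(*config.sigma_abund_range, p)

        lin_pa = x @ beta[guild, "occurrence"] + eta @ lam[guild, "occurrence"].T
        pa = (lin_pa + rng.standard_normal((n, p)) > 0).astype(np.int8)
        # keep every sample occupied so depths stay positive
        empty = pa.sum(axis=1) == 0
        if empty.any():
            pa[empty, np.argmax(lin_pa[empty], axis=1)] = 1
        lin_ab = x @ beta[guild, "abundance"] + eta @ lam[guild, "abundance"].T
        abund = lin_ab + rng.standard_normal((n, p)) * sigma[guild][None, :]
        pa_parts[guild], abund_parts[guild] = pa, abund

    tables = {}
    for guild in GUILDS:
        pa, abund = pa_parts[guild], abund_parts[guild]
        w = np.where(pa > 0, np.exp(config.count_scale * abund), 0.0)
        share = w / w.sum(axis=1, keepdims=True)
        target = meta[f"reads_{guild}"].to_numpy(float)[:, None]
        counts = np.floor(share * target + 0.5)  # round half-up
        counts = np.where(pa > 0, np.maximum(counts, 1), 0).astype(np.int64)
        tables[guild] = CommunityTable(
            pd.DataFrame(counts, index=meta.index, columns=species[guild]), guild=guild
        )
    meta = meta.copy()
    for guild in GUILDS:
        meta[f"reads_{guild}"] = tables[guild].depth.to_numpy()

    R = {}
    for part in ("occurrence", "abundance"):
        lam_joint = np.vstack([lam["fungi", part], lam["bacteria", part]])
        resid = (
            np.ones(lam_joint.shape[0])
            if part == "occurrence"
            else np.concatenate([sigma["fungi"] ** 2, sigma["bacteria"] ** 2])
        )
        R[part] = true_association_matrix(lam_joint, resid)

    truth = GroundTruth(beta=beta, lam=lam, eta=eta, sigma=sigma, R=R,
                        design=design, x_std=x, species=species)
    return SimulatedStudy(tables=tables, metadata=meta, truth=truth)


def generative_variance_shares(truth: GroundTruth, guild: str, part: str = "occurrence") -> dict:
    """Closed-form decomposition of generative variance per species, averaged
    over the guild: covariate (fixed) vs latent-factor (random) vs residual."""
    x = truth.x_std
    b = truth.beta[guild, part]
    lam = truth.lam[guild, part]
    fixed = (x @ b).var(axis=0)
    random_ = (lam**2).sum(axis=1)
    resid = np.ones(b.shape[1]) if part == "occurrence" else truth.sigma[guild] ** 2
    total = fixed + random_ + resid
    return {
        "fixed": float(np.mean(fixed / total)),
        "random": float(np.mean(random_ / total)),
        "residual": float(np.mean(resid / total)),
    }


def expected_prevalence(intercept: float) -> float:
    """Prevalence implied by a constant linear predictor under the probit law."""
    return float(norm.cdf(intercept))
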