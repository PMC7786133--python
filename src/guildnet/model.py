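"""Hurdle latent-factor joint species distribution model, fit by Gibbs sampling.

The joint response contains every OTU twice: a probit presence-absence column
(residual variance fixed at 1, sampled via truncated-normal data augmentation)
and a lognormal abundance column observed only where the OTU is present
(absences are missing and contribute nothing to the likelihood). All columns
share one set of sample-level latent factors eta with species loadings Lambda;
the residual covariance Omega = Lambda Lambda' (plus the part-specific
residual variance on the diagonal) induces the species-to-species association
matrix. Loadings carry a multiplicative-gamma shrinkage prior; niche
coefficients beta have independent normal priors on internally standardized
covariates; abundance residual variances are inverse-gamma.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from .data import DesignMatrix, HurdleResponse

logger = logging.getLogger("guildnet")

_EPS = 1e-13


def retained_draws(n_chains: int, n_iter: int, n_burn: int, thin: int) -> int:
    """Number of posterior draws kept across chains for given MCMC settings."""
    if not 0 <= n_burn < n_iter:
        raise ValueError("need 0 <= n_burn < n_iter")
    if thin <= 0 or (n_iter - n_burn) % thin:
        raise ValueError("thin must be positive and divide n_iter - n_burn")
    return n_chains * (n_iter - n_burn) // thin


def _truncnorm_probit(mu: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample z ~ N(mu, 1) truncated to z > 0 where y = 1 and z <= 0 where y = 0.

    Both branches use the lower tail of the normal CDF (by symmetry for the
    presence branch), which stays accurate for extreme linear predictors.
    """
    u = rng.uniform(size=mu.shape)
    lower = np.clip(u * ndtr(np.where(y > 0, mu, -mu)), 1e-300, 1.0)
    q = ndtri(lower)
    return np.where(y > 0, mu - q, mu + q)


def _sample_mvn_precision(prec: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(prec^-1 b, prec^-1) for a stack of small systems.

    prec: (m, d, d); b: (m, d) -> (m, d).
    """
    cov = np.linalg.inv(prec)
    cov = 0.5 * (cov + np.swapaxes(cov, -1, -2))
    mean = np.einsum("mij,mj->mi", cov, b)
    chol = np.linalg.cholesky(cov)
    eps = rng.standard_normal(b.shape)
    return mean + np.einsum("mij,mj->mi", chol, eps)


@dataclass
class Priors:
    beta_var: float = 1.0
    shrink_a1: float = 2.1
    shrink_a2: float = 3.1
    shrink_nu: float = 3.0
    sigma2_shape: float = 1.0
    sigma2_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be positive")


class GibbsCore:
    """One-sweep Gibbs machinery over the duplicated (probit + lognormal) response.

    Column layout: the first ``p`` columns are probit presence-absence, the
    last ``p`` their abundance counterparts. Exposes ``prior_state``,
    ``sweep``, and ``simulate_response`` so the same transition kernel serves
    model fitting and joint-distribution (simulate-then-update) validation.
    """

    def __init__(self, x: np.ndarray, y_pa: np.ndarray, y_ab: np.ndarray,
                 n_factors: int, priors: Priors):
        self.x = np.asarray(x, float)
        self.n, self.k = self.x.shape
        self.q = int(n_factors)
        self.priors = priors
        self.xtx = self.x.T @ self.x
        self.set_data(y_pa, y_ab)

    def set_data(self, y_pa: np.ndarray, y_ab: np.ndarray) -> None:
        self.y_pa = np.asarray(y_pa, float)
        self.p = self.y_pa.shape[1]
        self.ncol = 2 * self.p
        ab = np.asarray(y_ab, float)
        self.mask_ab = np.isfinite(ab) & (self.y_pa > 0)
        self.y_ab = np.where(self.mask_ab, ab, 0.0)
        # full observation weights: probit columns always observed (via z)
        self.obs = np.concatenate(
            [np.ones_like(self.y_pa), self.mask_ab.astype(float)], axis=1
        )
        # per-column X'X over observed rows (fixed across sweeps)
        m = self.mask_ab.astype(float)
        xtx_ab = np.einsum("nk,np,nl->pkl", self.x, m, self.x, optimize=True)
        self.xtx_stack = np.concatenate(
            [np.broadcast_to(self.xtx, (self.p, self.k, self.k)), xtx_ab], axis=0
        )

    # -- state ---------------------------------------------------------------

    def prior_state(self, rng: np.random.Generator) -> dict:
        pr = self.priors
        phi = rng.gamma(pr.shrink_nu / 2.0, 2.0 / pr.shrink_nu, (self.ncol, self.q))
        delta = np.concatenate(
            [rng.gamma(pr.shrink_a1, 1.0, 1), rng.gamma(pr.shrink_a2, 1.0, max(self.q - 1, 0))]
        )
        tau = np.cumprod(delta)
        lam = rng.standard_normal((self.ncol, self.q)) / np.sqrt(phi * tau[None, :])
        sigma2 = pr.sigma2_rate / rng.gamma(pr.sigma2_shape, 1.0, self.p)
        return {
            "beta": rng.normal(0.0, np.sqrt(pr.beta_var), (self.ncol, self.k)),
            "lam": lam,
            "eta": rng.standard_normal((self.n, self.q)),
            "sigma2": sigma2,
            "phi": phi,
            "delta": delta,
            "z": np.zeros((self.n, self.p)),
        }

    def _resid_var(self, st: dict) -> np.ndarray:
        return np.concatenate([np.ones(self.p), st["sigma2"]])

    def _latent_y(self, st: dict) -> np.ndarray:
        return np.concatenate([st["z"], self.y_ab], axis=1)

    # -- full-conditional updates ---------------------------------------------

    def sweep(self, st: dict, rng: np.random.Generator) -> None:
        pr = self.priors
        x, q, p = self.x, self.q, self.p

        # (1) probit liabilities
        mu = x @ st["beta"].T + st["eta"] @ st["lam"].T
        st["z"] = _truncnorm_probit(mu[:, :p], self.y_pa, rng)
        y = self._latent_y(st)
        s = self._resid_var(st)

        # (2) niche coefficients beta
        resid = (y - st["eta"] @ st["lam"].T) * self.obs
        b = (x.T @ resid).T / s[:, None]
        prec = self.xtx_stack / s[:, None, None]
        prec[:, np.arange(self.k), np.arange(self.k)] += 1.0 / pr.beta_var
        st["beta"] = _sample_mvn_precision(prec, b, rng)

        if q == 0:
            self._update_sigma2(st, rng)
            return

        # (3) loadings with multiplicative-gamma shrinkage
        tau = np.cumprod(st["delta"])
        resid = (y - x @ st["beta"].T) * self.obs
        ete = st["eta"].T @ st["eta"]
        ete_ab = np.einsum("nq,np,nr->pqr", st["eta"], self.mask_ab.astype(float),
                           st["eta"], optimize=True)
        ete_stack = np.concatenate([np.broadcast_to(ete, (p, q, q)), ete_ab], axis=0)
        prec = ete_stack / s[:, None, None]
        prec[:, np.arange(q), np.arange(q)] += st["phi"] * tau[None, :]
        b = (resid.T @ st["eta"]) / s[:, None]
        st["lam"] = _sample_mvn_precision(prec, b, rng)

        # (4) factor scores eta
        lam_s = st["lam"] / s[:, None]
        resid = (y - x @ st["beta"].T) * self.obs
        prec = np.einsum("jq,nj,jr->nqr", lam_s, self.obs, st["lam"], optimize=True)
        prec[:, np.arange(q), np.arange(q)] += 1.0
        b = resid @ lam_s
        st["eta"] = _sample_mvn_precision(prec, b, rng)

        # (5) abundance residual variances
        self._update_sigma2(st, rng)

        self._update_shrinkage(st, rng)

        bad = ~(np.isfinite(st["beta"]).all(axis=1) & np.isfinite(st["lam"]).all(axis=1))
        if bad.any():
            raise FloatingPointError(
                f"non-finite Gibbs update for response column(s) {np.flatnonzero(bad)[:5]}"
            )

    def _update_sigma2(self, st: dict, rng: np.random.Generator) -> None:
        pr = self.priors
        p = self.p
        resid_ab = (self.y_ab - self.x @ st["beta"][p:].T - st["eta"] @ st["lam"][p:].T)
        sse = ((resid_ab**2) * self.mask_ab).sum(axis=0)
        n_obs = self.mask_ab.sum(axis=0)
        shape = pr.sigma2_shape + 0.5 * n_obs
        rate = pr.sigma2_rate + 0.5 * sse
        st["sigma2"] = rate / rng.gamma(shape, 1.0)

    def _update_shrinkage(self, st: dict, rng: np.random.Generator) -> None:
        pr = self.priors
        q = self.q
        tau = np.cumprod(st["delta"])
        lam2 = st["lam"] ** 2
        st["phi"] = rng.gamma(
            (pr.shrink_nu + 1.0) / 2.0, 2.0 / (pr.shrink_nu + tau[None, :] * lam2)
        )
        phil2 = (st["phi"] * lam2).sum(axis=0)  # per factor
        delta = st["delta"]
        for h in range(q):
            tau_mh = np.cumprod(np.where(np.arange(q) == h, 1.0, delta))
            a = (pr.shrink_a1 if h == 0 else pr.shrink_a2) + 0.5 * self.ncol * (q - h)
            rate = 1.0 + 0.5 * np.sum(tau_mh[h:] * phil2[h:])
            delta[h] = rng.gamma(a, 1.0 / rate)
        st["delta"] = delta

    def simulate_response(self, st: dict, rng: np.random.Generator) -> None:
        """Draw a response from the model given the current parameters and
        install it as the data (hurdle coupling: abundance observed iff present)."""
        mu = self.x @ st["beta"].T + st["eta"] @ st["lam"].T
        z = mu[:, :self.p] + rng.standard_normal((self.n, self.p))
        y_pa = (z > 0).astype(float)
        ab = mu[:, self.p:] + rng.standard_normal((self.n, self.p)) * np.sqrt(st["sigma2"])[None, :]
        ab = np.where(y_pa > 0, ab, np.nan)
        st["z"] = z
        self.set_data(y_pa, ab)


class HurdleLatentFactorJSDM(BaseEstimator):
    """Joint species distribution model with a probit/lognormal hurdle response
    and sample-level latent factors, in scikit-learn estimator style.

    Parameters
    ----------
    n_factors : int
        Number of latent factors (fixed, not adaptively truncated).
    prior_beta_var : float
        Prior variance of niche coefficients on the standardized covariate scale.
    shrink_a1, shrink_a2, shrink_nu : float
        Multiplicative-gamma shrinkage hyperparameters for the loadings.
    sigma2_shape, sigma2_rate : float
        Inverse-gamma prior for abundance residual variances.
    n_chains, n_iter, n_burn, thin : int
        MCMC settings; ``n_burn`` defaults to ``n_iter // 3`` and ``thin`` must
        divide ``n_iter - n_burn``.
    standardize : bool
        Z-score non-constant design columns internally (coefficients are
        reported on both scales).
    random_state : int or None
        Master seed; per-chain seeds are spawned deterministically from it.
    """

    def __init__(self, n_factors: int = 3, prior_beta_var: float = 1.0,
                 shrink_a1: float = 2.1, shrink_a2: float = 3.1, shrink_nu: float = 3.0,
                 sigma2_shape: float = 1.0, sigma2_rate: float = 1.0,
                 n_chains: int = 2, n_iter: int = 5000, n_burn: int | None = None,
                 thin: int = 10, standardize: bool = True, random_state: int | None = None):
        self.n_factors = n_factors
        self.prior_beta_var = prior_beta_var
        self.shrink_a1 = shrink_a1
        self.shrink_a2 = shrink_a2
        self.shrink_nu = shrink_nu
        self.sigma2_shape = sigma2_shape
        self.sigma2_rate = sigma2_rate
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.thin = thin
        self.standardize = standardize
        self.random_state = random_state

    # -- helpers --------------------------------------------------------------

    def _priors(self) -> Priors:
        return Priors(self.prior_beta_var, self.shrink_a1, self.shrink_a2,
                      self.shrink_nu, self.sigma2_shape, self.sigma2_rate)

    def _coerce_design(self, X) -> np.ndarray:
        if isinstance(X, DesignMatrix):
            return X.values
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(float)
        return np.asarray(X, float)

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.x_mean_[None, :]) / self.x_scale_[None, :]

    # -- fitting ---------------------------------------------------------------

    def fit(self, X, y: HurdleResponse):
        """Fit the model; ``X`` is a design matrix (DesignMatrix, DataFrame, or
        array) and ``y`` a (possibly multi-guild concatenated) HurdleResponse."""
        if not isinstance(y, HurdleResponse):
            raise TypeError("y must be a HurdleResponse (see assemble_hurdle_response)")
        x = self._coerce_design(X)
        if x.ndim != 2 or x.shape[0] != y.pa.shape[0]:
            raise ValueError("design and response are not row-aligned")
        if y.pa.shape[1] < 1:
            raise ValueError("need at least one OTU")
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design matrix is rank deficient")
        n_burn = self.n_iter // 3 if self.n_burn is None else self.n_burn
        n_per_chain = retained_draws(1, self.n_iter, n_burn, self.thin)

        if self.standardize:
            self.x_mean_ = x.mean(axis=0)
            self.x_scale_ = x.std(axis=0)
            const = self.x_scale_ == 0
            self.x_mean_[const] = 0.0
            self.x_scale_[const] = 1.0
        else:
            self.x_mean_ = np.zeros(x.shape[1])
            self.x_scale_ = np.ones(x.shape[1])
        xs = self._standardize(x)

        self.species_ = y.otu_ids
        self.guild_ = y.guild.to_numpy()
        self.degenerate_ = y.degenerate.to_numpy()
        self.design_info_ = X if isinstance(X, DesignMatrix) else None
        self.p_ = y.pa.shape[1]
        core = GibbsCore(xs, y.pa.to_numpy(float), y.abund.to_numpy(float),
                         self.n_factors, self._priors())
        self._core_shape_ = (core.n, core.k, core.p, core.q)

        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_chains)
        chains = []
        for c, seed in enumerate(seeds):
            rng = np.random.default_rng(seed)
            st = core.prior_state(rng)
            out = {
                "beta": np.empty((n_per_chain, core.ncol, core.k)),
                "lam": np.empty((n_per_chain, core.ncol, core.q)),
                "eta": np.empty((n_per_chain, core.n, core.q)),
                "sigma2": np.empty((n_per_chain, core.p)),
                "delta": np.empty((n_per_chain, core.q)),
            }
            d = 0
            for it in range(1, self.n_iter + 1):
                core.sweep(st, rng)
                if it > n_burn and (it - n_burn) % self.thin == 0:
                    for key in out:
                        out[key][d] = st[key]
                    d += 1
            chains.append(out)
            logger.info("chain %d finished: %d retained draws", c, d)
        self.chains_ = chains
        self.n_draws_ = self.n_chains * n_per_chain
        self.n_burn_ = n_burn
        self.beta_mean_ = np.mean([c["beta"].mean(axis=0) for c in chains], axis=0)
        self.lambda_mean_ = np.mean([c["lam"].mean(axis=0) for c in chains], axis=0)
        self.sigma2_mean_ = np.mean([c["sigma2"].mean(axis=0) for c in chains], axis=0)
        return self

    # -- persistence ------------------------------------------------------------

    def save(self, path) -> None:
        """Persist posterior draws as flat binary arrays plus a JSON index."""
        import json
        from pathlib import Path

        self._check_fitted()
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        index = {
            "params": self.get_params(),
            "n_draws": self.n_draws_, "n_burn": self.n_burn_, "p": int(self.p_),
            "species": [str(s) for s in self.species_],
            "guild": [str(g) for g in self.guild_],
            "degenerate": [bool(b) for b in self.degenerate_],
            "x_mean": self.x_mean_.tolist(), "x_scale": self.x_scale_.tolist(),
            "n_chains": len(self.chains_), "blocks": sorted(self.chains_[0]),
        }
        for c, chain in enumerate(self.chains_):
            for key, arr in chain.items():
                np.save(path / f"chain{c}_{key}.npy", arr)
        if self.design_info_ is not None:
            d = self.design_info_
            index["design"] = {
                "columns": d.column_names, "group_map": d.group_map,
                "reference_levels": d.reference_levels, "model": d.model,
                "sample_ids": [str(i) for i in d.frame.index],
            }
            np.save(path / "design_values.npy", d.values)
        with open(path / "index.json", "w") as fh:
            json.dump(index, fh, indent=2)

    @classmethod
    def load(cls, path) -> "HurdleLatentFactorJSDM":
        """Reconstruct a fitted model saved with :meth:`save` exactly."""
        import json
        from pathlib import Path

        path = Path(path)
        with open(path / "index.json") as fh:
            index = json.load(fh)
        est = cls(**index["params"])
        est.chains_ = [
            {key: np.load(path / f"chain{c}_{key}.npy") for key in index["blocks"]}
            for c in range(index["n_chains"])
        ]
        est.n_draws_ = index["n_draws"]
        est.n_burn_ = index["n_burn"]
        est.p_ = index["p"]
        est.species_ = pd.Index(index["species"])
        est.guild_ = np.asarray(index["guild"])
        est.degenerate_ = np.asarray(index["degenerate"], bool)
        est.x_mean_ = np.asarray(index["x_mean"])
        est.x_scale_ = np.asarray(index["x_scale"])
        est.design_info_ = None
        if "design" in index:
            d = index["design"]
            frame = pd.DataFrame(np.load(path / "design_values.npy"),
                                 columns=d["columns"], index=d["sample_ids"])
            est.design_info_ = DesignMatrix(frame, d["group_map"],
                                            d["reference_levels"], model=d["model"])
        est.beta_mean_ = np.mean([c["beta"].mean(axis=0) for c in est.chains_], axis=0)
        est.lambda_mean_ = np.mean([c["lam"].mean(axis=0) for c in est.chains_], axis=0)
        est.sigma2_mean_ = np.mean([c["sigma2"].mean(axis=0) for c in est.chains_], axis=0)
        return est

    # -- posterior access -------------------------------------------------------

    def pooled(self, name: str) -> np.ndarray:
        """Draws of a stored block pooled over chains, shape (n_draws, ...)."""
        return np.concatenate([c[name] for c in self.chains_], axis=0)

    def beta_original_scale(self) -> np.ndarray:
        """Posterior-mean coefficients mapped back to the unstandardized design."""
        # mu = sum_j b_j (x_j - m_j) / s_j, so slope_j -> b_j / s_j and the
        # intercept absorbs -sum_j b_j m_j / s_j (intercept col has m=0, s=1)
        beta = self.beta_mean_ / self.x_scale_[None, :]
        shift = (self.beta_mean_ * (self.x_mean_ / self.x_scale_)[None, :]).sum(axis=1)
        beta[:, 0] = self.beta_mean_[:, 0] - shift
        return beta

    # -- prediction --------------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "chains_"):
            raise RuntimeError("model is not fitted")

    def predict_unconditional(self, X, seed: int | None = None, n_eta: int = 1):
        """Posterior-predictive presence probabilities and expected standardized
        log abundances for new samples, with factor scores drawn from their
        standard-normal prior (covariate information only)."""
        self._check_fitted()
        x = self._standardize(self._coerce_design(X))
        rng = np.random.default_rng(seed)
        p = self.p_
        prob = np.zeros((x.shape[0], p))
        abund = np.zeros((x.shape[0], p))
        total = 0
        for beta, lam in zip(self.pooled("beta"), self.pooled("lam")):
            for _ in range(n_eta):
                eta = rng.standard_normal((x.shape[0], lam.shape[1]))
                mu = x @ beta.T + eta @ lam.T
                prob += ndtr(mu[:, :p])
                abund += mu[:, p:]
                total += 1
        return prob / total, abund / total

    def predict_proba(self, X, seed: int | None = None) -> np.ndarray:
        return self.predict_unconditional(X, seed=seed)[0]

    def predict(self, X, seed: int | None = None) -> np.ndarray:
        """Expected standardized log abundance given presence."""
        return self.predict_unconditional(X, seed=seed)[1]

    def predict_in_sample(self):
        """Explanatory-regime predictions for the training samples, using the
        stored (data-conditioned) factor scores of each draw."""
        self._check_fitted()
        p = self.p_
        prob = 0.0
        abund = 0.0
        draws = zip(self.pooled("beta"), self.pooled("lam"), self.pooled("eta"))
        xs = None
        for beta, lam, eta in draws:
            if xs is None:
                xs = self._xs_cache()
            mu = xs @ beta.T + eta @ lam.T
            prob = prob + ndtr(mu[:, :p])
            abund = abund + mu[:, p:]
        return prob / self.n_draws_, abund / self.n_draws_

    def _xs_cache(self) -> np.ndarray:
        if self.design_info_ is None:
            raise RuntimeError("in-sample prediction needs the design passed at fit time "
                               "as a DesignMatrix")
        return self._standardize(self.design_info_.values)

    def predict_conditional(self, X, pa_obs, ab_obs, focal: np.ndarray,
                            outer_draws: int = 100, inner_burn: int = 50,
                            inner_draws: int = 100, seed: int | None = None):
        """Predict focal species conditioning on observed non-focal species.

        For each retained posterior draw (an evenly spaced subsample of
        ``outer_draws``), the factor scores of the new samples are sampled from
        their conditional posterior given the non-focal occurrences (probit
        liabilities re-augmented by truncated normals) and abundances (used
        directly where present); focal predictions are then averaged over the
        inner Gibbs draws and outer posterior draws.

        Parameters
        ----------
        focal : bool array (n_species,)
            True for the species to predict; all focal data are ignored.
        pa_obs, ab_obs : arrays (n_samples_new, n_species)
            Observations; only non-focal columns are used. ``ab_obs`` is on the
            standardized log scale with NaN where absent.
        """
        self._check_fitted()
        x = self._standardize(self._coerce_design(X))
        focal = np.asarray(focal, bool)
        if focal.shape[0] != self.p_:
            raise ValueError("focal mask length must equal the number of species")
        nf = ~focal
        rng = np.random.default_rng(seed)
        n_new = x.shape[0]
        p, q = self.p_, self.n_factors

        pa_nf = np.asarray(pa_obs, float)[:, nf]
        ab_nf = np.asarray(ab_obs, float)[:, nf]
        m_ab = np.isfinite(ab_nf) & (pa_nf > 0)
        ab_nf = np.where(m_ab, ab_nf, 0.0)

        beta_all, lam_all = self.pooled("beta"), self.pooled("lam")
        sigma2_all = self.pooled("sigma2")
        idx = np.unique(np.linspace(0, self.n_draws_ - 1, min(outer_draws, self.n_draws_)).astype(int))

        prob = np.zeros((n_new, focal.sum()))
        abund = np.zeros((n_new, focal.sum()))
        total = 0
        for t in idx:
            beta, lam, sigma2 = beta_all[t], lam_all[t], sigma2_all[t]
            b_pa_nf, l_pa_nf = beta[:p][nf], lam[:p][nf]
            b_ab_nf, l_ab_nf = beta[p:][nf], lam[p:][nf]
            b_pa_f, l_pa_f = beta[:p][focal], lam[:p][focal]
            b_ab_f, l_ab_f = beta[p:][focal], lam[p:][focal]
            s_nf = sigma2[nf]

            mu_pa_base = x @ b_pa_nf.T
            mu_ab_base = x @ b_ab_nf.T
            mu_f_pa = x @ b_pa_f.T
            mu_f_ab = x @ b_ab_f.T
            eta = np.zeros((n_new, q))
            if nf.sum() == 0:
                for _ in range(inner_draws):
                    eta = rng.standard_normal((n_new, q))
                    prob += ndtr(mu_f_pa + eta @ l_pa_f.T)
                    abund += mu_f_ab + eta @ l_ab_f.T
                    total += 1
                continue

            prec0 = l_pa_nf.T @ l_pa_nf + np.eye(q)
            l_ab_s = l_ab_nf / s_nf[:, None]
            prec_ab = np.einsum("jq,nj,jr->nqr", l_ab_s, m_ab.astype(float), l_ab_nf,
                                optimize=True)
            prec = prec_ab + prec0[None, :, :]
            ab_resid_term = ((ab_nf - mu_ab_base) * m_ab) @ l_ab_s
            for it in range(inner_burn + inner_draws):
                z = _truncnorm_probit(mu_pa_base + eta @ l_pa_nf.T, pa_nf, rng)
                b = (z - mu_pa_base) @ l_pa_nf + ab_resid_term
                eta = _sample_mvn_precision(prec, b, rng)
                if it >= inner_burn:
                    prob += ndtr(mu_f_pa + eta @ l_pa_f.T)
                    abund += mu_f_ab + eta @ l_ab_f.T
                    total += 1
        return prob / total, abund / total


# ---------------------------------------------------------------------------
# convergence diagnostics


@dataclass
class ConvergenceReport:
    """Per-block ESS and PSRF with the summaries used for reporting."""

    psrf: pd.Series
    ess: pd.Series

    @property
    def max_psrf(self) -> float:
        return float(np.nanmax(self.psrf))

    @property
    def min_ess(self) -> float:
        return float(np.nanmin(self.ess))


def compute_psrf(chains, split: bool = False) -> float:
    """Gelman-Rubin potential scale reduction factor for one scalar parameter.

    ``chains`` is an (n_chains, n_draws) array (or list of 1-D arrays).
    Convention: R = sqrt((W + B/n) / W) with W the mean within-chain variance
    and B/n the variance of chain means — identical chains give exactly 1.
    ``split=True`` halves each chain first (recommended for trend detection).
    """
    x = np.asarray(chains, float)
    if x.ndim != 2 or (x.shape[0] < 2 and not split):
        raise ValueError("need >= 2 chains of equal length (or one chain with split=True)")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w == 0:
        warnings.warn("constant chains: PSRF undefined", RuntimeWarning, stacklevel=2)
        return np.nan
    return float(np.sqrt((w + b_over_n) / w))


def compute_ess(chains) -> float:
    """Autocorrelation-based effective sample size for one scalar parameter
    (Geyer initial-monotone truncation via arviz), clipped at the total number
    of draws. Constant chains yield 0 with a warning."""
    import arviz as az

    x = np.asarray(chains, float)
    if x.ndim == 1:
        x = x[None, :]
    if np.allclose(x, x.flat[0]):
        warnings.warn("constant chain: ESS undefined, reporting 0", RuntimeWarning, stacklevel=2)
        return 0.0
    ess = float(az.ess(az.convert_to_dataset(x), method="mean")["x"].values)
    return min(ess, float(x.size))


def convergence_report(fit: HurdleLatentFactorJSDM, n_assoc: int = 100,
                       seed: int = 0) -> dict:
    """ESS and PSRF for the niche-coefficient block and a random subset of
    association (Omega) entries, summarized per block."""
    rng = np.random.default_rng(seed)
    split = len(fit.chains_) < 2  # halve a lone chain so PSRF stays defined
    beta = [c["beta"] for c in fit.chains_]  # chains of (d, ncol, k)
    d, ncol, k = beta[0].shape
    labels, series = [], []
    take = rng.choice(ncol * k, size=min(200, ncol * k), replace=False)
    for t in take:
        j, c = divmod(int(t), k)
        labels.append(f"beta[{j},{c}]")
        series.append(np.stack([b[:, j, c] for b in beta]))
    report = {}
    psrf = pd.Series([compute_psrf(s, split=split) for s in series], index=labels)
    ess = pd.Series([compute_ess(s) for s in series], index=labels)
    report["beta"] = ConvergenceReport(psrf=psrf, ess=ess)

    lam = [c["lam"] for c in fit.chains_]
    pairs = set()
    p2 = lam[0].shape[1]
    while len(pairs) < min(n_assoc, p2 * (p2 - 1) // 2):
        j, l = rng.integers(0, p2, 2)
        if j < l:
            pairs.add((int(j), int(l)))
    labels, series = [], []
    for j, l in sorted(pairs):
        labels.append(f"omega[{j},{l}]")
        series.append(np.stack([(c[:, j, :] * c[:, l, :]).sum(axis=1) for c in lam]))
    psrf = pd.Series([compute_psrf(s, split=split) for s in series], index=labels)
    ess = pd.Series([compute_ess(s) for s in series], index=labels)
    report["omega"] = ConvergenceReport(psrf=psrf, ess=ess)
    return report
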