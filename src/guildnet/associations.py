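"""Residual association networks and variance partitioning from posterior draws.

Per posterior draw the residual covariance of a model part is
Omega = Lambda Lambda' + diag(resid), with resid = 1 for the probit
(occurrence) part and sigma_j^2 for the lognormal (abundance) part; its
correlation form R is the species-to-species association matrix. Edge support
is the posterior probability that an association keeps a common sign.
Contrasting the network of the depth-only null model with the full
(environment-aware) model separates shared habitat use from residual
association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DesignMatrix
from .model import HurdleLatentFactorJSDM

PARTS = ("occurrence", "abundance", "combined")


@dataclass
class AssociationNetwork:
    """Posterior summary of the residual correlation matrix for one model part."""

    R_mean: pd.DataFrame
    support_positive: pd.DataFrame  # posterior P(r > 0)
    support_negative: pd.DataFrame  # posterior P(r < 0)
    guild: pd.Series
    support_level: float
    part: str

    @property
    def species(self) -> pd.Index:
        return self.R_mean.index

    def supported(self) -> pd.DataFrame:
        """Boolean matrix of supported associations at the stated level."""
        sup = (np.maximum(self.support_positive.to_numpy(),
                          self.support_negative.to_numpy()) >= self.support_level)
        np.fill_diagonal(sup, False)
        return pd.DataFrame(sup, index=self.species, columns=self.species)

    def edge_list(self) -> pd.DataFrame:
        """Supported edges as a tidy table (upper triangle only)."""
        sup = self.supported().to_numpy()
        rows = []
        ids = self.species
        for j, l in zip(*np.nonzero(np.triu(sup, 1))):
            rows.append({
                "source_otu": ids[j],
                "target_otu": ids[l],
                "source_guild": self.guild.iloc[j],
                "target_guild": self.guild.iloc[l],
                "posterior_mean_correlation": self.R_mean.iloc[j, l],
                "support": max(self.support_positive.iloc[j, l],
                               self.support_negative.iloc[j, l]),
                "sign": int(np.sign(self.R_mean.iloc[j, l])),
            })
        cols = ["source_otu", "target_otu", "source_guild", "target_guild",
                "posterior_mean_correlation", "support", "sign"]
        return pd.DataFrame(rows, columns=cols)

    def n_edges(self, between_guild: bool | None = None) -> int:
        edges = self.edge_list()
        if between_guild is None or edges.empty:
            return len(edges)
        between = edges["source_guild"] != edges["target_guild"]
        return int(between.sum()) if between_guild else int((~between).sum())

    def to_graph(self):
        """Supported network as a networkx graph (guild as node attribute)."""
        import networkx as nx

        g = nx.Graph()
        for sp, guild in self.guild.items():
            g.add_node(sp, guild=guild)
        for _, e in self.edge_list().iterrows():
            g.add_edge(e.source_otu, e.target_otu,
                       weight=e.posterior_mean_correlation, support=e.support)
        return g


def _correlation_from_loadings(lam: np.ndarray, resid: np.ndarray) -> np.ndarray:
    omega = lam @ lam.T
    omega[np.arange(len(resid)), np.arange(len(resid))] += resid
    d = 1.0 / np.sqrt(np.diag(omega))
    return omega * d[:, None] * d[None, :]


def _draw_correlations(fit: HurdleLatentFactorJSDM, part: str):
    """Yield the residual correlation matrix of each retained draw."""
    p = fit.p_
    lam_all = fit.pooled("lam")
    sigma2_all = fit.pooled("sigma2")
    for lam, sigma2 in zip(lam_all, sigma2_all):
        if part == "occurrence":
            yield _correlation_from_loadings(lam[:p], np.ones(p))
        elif part == "abundance":
            yield _correlation_from_loadings(lam[p:], sigma2)
        else:  # combined: average of the two parts' correlations, per draw
            r = _correlation_from_loadings(lam[:p], np.ones(p))
            r = 0.5 * (r + _correlation_from_loadings(lam[p:], sigma2))
            yield r


def compute_association_network(fit: HurdleLatentFactorJSDM, part: str = "occurrence",
                                support_level: float = 0.95) -> AssociationNetwork:
    """Posterior-mean residual correlations and sign support for one model part."""
    if part not in PARTS:
        raise ValueError(f"part must be one of {PARTS}")
    if fit.p_ < 2:
        raise ValueError("association network needs at least 2 species")
    p = fit.p_
    mean = np.zeros((p, p))
    pos = np.zeros((p, p))
    neg = np.zeros((p, p))
    n = 0
    for r in _draw_correlations(fit, part):
        mean += r
        pos += r > 0
        neg += r < 0
        n += 1
    mean /= n
    pos /= n
    neg /= n
    ids = fit.species_
    guild = pd.Series(fit.guild_, index=ids)
    return AssociationNetwork(
        R_mean=pd.DataFrame(mean, index=ids, columns=ids),
        support_positive=pd.DataFrame(pos, index=ids, columns=ids),
        support_negative=pd.DataFrame(neg, index=ids, columns=ids),
        guild=guild, support_level=support_level, part=part,
    )


def compare_networks(null_net: AssociationNetwork, full_net: AssociationNetwork) -> pd.DataFrame:
    """Classify each supported null-model edge as retained, sign-flipped, or
    lost in the full model, separately within and between guilds."""
    if not null_net.species.equals(full_net.species):
        raise ValueError("networks are defined over different species sets")
    sup0 = null_net.supported().to_numpy()
    sup1 = full_net.supported().to_numpy()
    sign0 = np.sign(null_net.R_mean.to_numpy())
    sign1 = np.sign(full_net.R_mean.to_numpy())
    guild = null_net.guild.to_numpy()
    between = guild[:, None] != guild[None, :]
    rows = []
    for scope, mask in (("within_guild", ~between), ("between_guild", between)):
        base = np.triu(sup0 & mask, 1)
        n0 = int(base.sum())
        retained = int((base & sup1 & (sign0 == sign1)).sum())
        flipped = int((base & sup1 & (sign0 != sign1)).sum())
        lost = n0 - retained - flipped
        rows.append({
            "scope": scope, "null_edges": n0, "retained": retained,
            "sign_flipped": flipped, "lost": lost,
            "lost_fraction": lost / n0 if n0 else np.nan,
        })
    return pd.DataFrame(rows)


def variance_partition(fit: HurdleLatentFactorJSDM, design: DesignMatrix) -> pd.DataFrame:
    """Partition explained variance per species and model part into covariate
    groups (chemical, physical, depth) and the latent-factor random effect.

    Per draw and species: the fixed-effect variance of group g over samples is
    the g-diagonal block of Cov(X beta), with each cross-group covariance block
    split equally between the two groups involved; the random-effect variance
    is sum_f lambda_f^2. Proportions are of the explained (modelled) variance
    and sum to 1. Averaged over draws.
    """
    xs = (design.values - fit.x_mean_[None, :]) / fit.x_scale_[None, :]
    names = design.column_names
    groups = sorted({g for g in design.group_map.values()})
    gidx = {g: [i for i, c in enumerate(names) if design.group_map.get(c) == g]
            for g in groups}
    xc = xs - xs.mean(axis=0, keepdims=True)
    cov_x = xc.T @ xc / (xs.shape[0] - 1)

    beta_all = fit.pooled("beta")
    lam_all = fit.pooled("lam")
    ncol = beta_all.shape[1]
    p = fit.p_
    comp_names = groups + ["random_effect"]
    acc = np.zeros((ncol, len(comp_names)))
    for beta, lam in zip(beta_all, lam_all):
        # per-column covariate variance split by group
        contrib = np.zeros((ncol, len(groups)))
        for a, ga in enumerate(groups):
            ia = gidx[ga]
            if not ia:
                continue
            for b, gb in enumerate(groups):
                ib = gidx[gb]
                if not ib:
                    continue
                block = np.einsum("jk,kl,jl->j", beta[:, ia], cov_x[np.ix_(ia, ib)],
                                  beta[:, ib])
                contrib[:, a] += 0.5 * block
                contrib[:, b] += 0.5 * block
        rand = (lam**2).sum(axis=1)
        total = contrib.sum(axis=1) + rand
        total[total == 0] = 1.0
        acc[:, :-1] += contrib / total[:, None]
        acc[:, -1] += rand / total
    acc /= len(beta_all)

    rows = []
    for j in range(ncol):
        part = "occurrence" if j < p else "abundance"
        sp = fit.species_[j % p]
        for c, comp in enumerate(comp_names):
            rows.append({
                "otu": sp, "guild": fit.guild_[j % p], "part": part,
                "component": comp, "proportion": acc[j, c],
            })
    return pd.DataFrame(rows)


def variance_partition_summary(vp: pd.DataFrame) -> pd.DataFrame:
    """Guild-level averages over species and parts (the text-box summaries)."""
    return (vp.groupby(["guild", "component"], as_index=False)["proportion"]
            .mean())
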