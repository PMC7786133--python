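"""Explanatory, unconditional, and conditional predictive power.

Explanatory power refits nothing: the model fitted to all data predicts the
training samples using its data-conditioned factor scores. Predictive power
uses 2-fold cross-validation across samples: unconditional predictions use the
environmental covariates only (factor scores from their prior); conditional
predictions additionally condition the factor scores on the observed
occurrences and abundances of the non-focal guild in the test samples. The
difference between conditional and unconditional power is the information
value of one guild for predicting the other — the directionality statistic.

Occurrence predictions are scored by AUC (Mann-Whitney, ties count 1/2);
abundances by R^2 = 1 - SSE/SST on the standardized log scale (can be
negative out of sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import roc_auc_score

from .data import GUILDS, CommunityTable, DesignMatrix, HurdleResponse, build_joint_design
from .model import HurdleLatentFactorJSDM

logger = logging.getLogger("guildnet")

REGIMES = ("explanatory", "unconditional", "conditional")


@dataclass
class CVSpec:
    """Cross-validation settings.

    ``outer_draws``/``inner_burn``/``inner_draws`` control the conditional
    factor-score inference: for each of ``outer_draws`` posterior draws an
    inner Gibbs chain of ``inner_burn + inner_draws`` sweeps samples the test
    samples' factor scores given the non-focal guild.
    """

    n_folds: int = 2
    seed: int = 0
    outer_draws: int = 100
    inner_burn: int = 50
    inner_draws: int = 100

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


def assign_folds(n_samples: int, n_folds: int = 2, seed: int = 0) -> np.ndarray:
    """Seeded random partition of samples into near-equal folds."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    folds = np.empty(n_samples, int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        folds[chunk] = f
    return folds


def compute_auc(labels, scores) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def compute_r2(observed, predicted) -> float:
    """1 - SSE/SST over paired nonmissing values; negative when predictions
    are worse than the observed mean."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    keep = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[keep], pred[keep]
    if obs.size < 3:
        raise ValueError("R^2 needs at least 3 paired values")
    sst = ((obs - obs.mean()) ** 2).sum()
    if sst == 0:
        raise ValueError("R^2 undefined for constant observations")
    return float(1.0 - ((obs - pred) ** 2).sum() / sst)


def _per_species_metrics(response: HurdleResponse, prob: np.ndarray, abund: np.ndarray,
                         valid: np.ndarray) -> pd.DataFrame:
    """Per-species AUC and R^2 for one model x regime; species with one class,
    too few presences, or a degenerate abundance part are skipped."""
    pa = response.pa.to_numpy()
    ab = response.abund.to_numpy()
    rows = []
    skipped = 0
    for j, otu in enumerate(response.otu_ids):
        guild = response.guild.iloc[j]
        if not valid[j]:
            skipped += 1
            continue
        if len(np.unique(pa[:, j])) == 2:
            rows.append({"otu": otu, "guild": guild, "part": "occurrence",
                         "metric": "auc", "value": compute_auc(pa[:, j], prob[:, j])})
        else:
            skipped += 1
        present = pa[:, j] > 0
        if (not response.degenerate.iloc[j]) and present.sum() >= 3:
            try:
                r2 = compute_r2(ab[present, j], abund[present, j])
            except ValueError:
                continue
            rows.append({"otu": otu, "guild": guild, "part": "abundance",
                         "metric": "r2", "value": r2})
    if skipped:
        logger.info("skipped %d species from evaluation averages", skipped)
    return pd.DataFrame(rows, columns=["otu", "guild", "part", "metric", "value"])


def _focal_masks(response: HurdleResponse) -> dict:
    guild = response.guild.to_numpy()
    return {g: guild == g for g in GUILDS if (guild == g).any()}


def evaluate_models(meta: pd.DataFrame, response: HurdleResponse,
                    models=("null", "full"), cv: CVSpec | None = None,
                    estimator: HurdleLatentFactorJSDM | None = None,
                    regimes=REGIMES) -> pd.DataFrame:
    """Fit null/full models and score them under the requested regimes.

    Returns a tidy per-species table with columns
    (model, regime, otu, guild, part, metric, value); use
    :func:`summarize_report` for the guild-mean table and
    :func:`directionality_gain` for the conditional-minus-unconditional gains.
    """
    cv = cv or CVSpec()
    template = estimator or HurdleLatentFactorJSDM()
    results = []
    for model in models:
        design = build_joint_design(meta, model=model)
        if "explanatory" in regimes:
            fit = _clone(template, seed_offset=hash((model, "expl")) % 2**16)
            fit.fit(design, response)
            prob, abund = fit.predict_in_sample()
            m = _per_species_metrics(response, prob, abund, np.ones(response.n_otus, bool))
            m["model"], m["regime"] = model, "explanatory"
            results.append(m)
        if "unconditional" in regimes or "conditional" in regimes:
            preds = _cross_validate(meta, response, model, template, cv,
                                    conditional="conditional" in regimes)
            for regime in ("unconditional", "conditional"):
                if regime not in regimes:
                    continue
                prob, abund = preds[regime]
                m = _per_species_metrics(response, prob, abund, preds["valid"])
                m["model"], m["regime"] = model, regime
                results.append(m)
    report = pd.concat(results, ignore_index=True)
    return report[["model", "regime", "otu", "guild", "part", "metric", "value"]]


def _clone(est: HurdleLatentFactorJSDM, seed_offset: int = 0) -> HurdleLatentFactorJSDM:
    params = est.get_params()
    base = params.get("random_state") or 0
    params["random_state"] = (base + seed_offset) % (2**31 - 1)
    return HurdleLatentFactorJSDM(**params)


def _cross_validate(meta: pd.DataFrame, response: HurdleResponse, model: str,
                    template: HurdleLatentFactorJSDM, cv: CVSpec,
                    conditional: bool) -> dict:
    n = len(meta)
    p = response.n_otus
    folds = assign_folds(n, cv.n_folds, cv.seed)
    prob_u = np.full((n, p), np.nan)
    ab_u = np.full((n, p), np.nan)
    prob_c = np.full((n, p), np.nan)
    ab_c = np.full((n, p), np.nan)
    valid = np.ones(p, bool)
    masks = _focal_masks(response)
    pa_arr = response.pa.to_numpy(float)
    ab_arr = response.abund.to_numpy(float)

    for f in range(cv.n_folds):
        test = folds == f
        train = ~test
        meta_tr = meta.loc[train]
        resp_tr = _subset_rows(response, train)
        # species unseen in a training fold cannot be evaluated fairly
        valid &= resp_tr.pa.to_numpy().sum(axis=0) > 0
        design_tr = build_joint_design(meta_tr, model=model)
        design_te = build_joint_design(meta, model=model).frame.loc[test]
        fit = _clone(template, seed_offset=(hash((model, "cv", f)) % 2**16))
        fit.fit(design_tr, resp_tr)
        pu, au = fit.predict_unconditional(design_te, seed=cv.seed * 1000 + f)
        prob_u[test], ab_u[test] = pu, au
        if conditional:
            for g, focal in masks.items():
                pc, ac = fit.predict_conditional(
                    design_te, pa_arr[test], ab_arr[test], focal,
                    outer_draws=cv.outer_draws, inner_burn=cv.inner_burn,
                    inner_draws=cv.inner_draws, seed=cv.seed * 1000 + 500 + f,
                )
                rows = np.flatnonzero(test)
                prob_c[np.ix_(rows, np.flatnonzero(focal))] = pc
                ab_c[np.ix_(rows, np.flatnonzero(focal))] = ac
    out = {"unconditional": (prob_u, ab_u), "valid": valid}
    if conditional:
        out["conditional"] = (prob_c, ab_c)
    return out


def _subset_rows(response: HurdleResponse, rows: np.ndarray) -> HurdleResponse:
    rows = np.asarray(rows)
    if rows.dtype == bool:
        rows = np.flatnonzero(rows)
    return HurdleResponse(
        pa=response.pa.iloc[rows], abund=response.abund.iloc[rows],
        log_mean=response.log_mean, log_sd=response.log_sd,
        guild=response.guild, degenerate=response.degenerate,
    )


def summarize_report(report: pd.DataFrame) -> pd.DataFrame:
    """Guild-mean metric per model x regime x part, with species counts."""
    out = (report.groupby(["guild", "part", "metric", "model", "regime"], as_index=False)
           .agg(value=("value", "mean"), n_species=("value", "size")))
    return out


def directionality_gain(report: pd.DataFrame) -> pd.DataFrame:
    """Information value of the non-focal guild: conditional minus
    unconditional guild-mean metric, plus the environment gain
    (full-unconditional minus null-unconditional) for comparison."""
    summary = summarize_report(report)
    piv = summary.pivot_table(index=["guild", "part", "metric", "model"],
                              columns="regime", values="value")
    rows = []
    for (guild, part, metric, model), r in piv.iterrows():
        row = {"guild": guild, "part": part, "metric": metric, "model": model}
        if "conditional" in r and "unconditional" in r:
            row["conditional_gain"] = r["conditional"] - r["unconditional"]
        rows.append(row)
    gains = pd.DataFrame(rows)
    # environment gain: full vs null unconditional power
    env = piv.reset_index()
    if "unconditional" in piv.columns and set(env["model"]) >= {"null", "full"}:
        u = env.pivot_table(index=["guild", "part", "metric"], columns="model",
                            values="unconditional")
        u["environment_gain"] = u["full"] - u["null"]
        gains = gains.merge(u["environment_gain"].reset_index(),
                            on=["guild", "part", "metric"], how="left")
    return gains


def report_table(report: pd.DataFrame) -> pd.DataFrame:
    """Wide table of guild-mean powers: one row per guild x part x model with
    explanatory / unconditional / conditional columns (NA where missing)."""
    summary = summarize_report(report)
    piv = summary.pivot_table(index=["part", "guild", "model"], columns="regime",
                              values="value")
    n = summary.pivot_table(index=["part", "guild", "model"], columns="regime",
                            values="n_species", aggfunc="max")
    out = piv.reindex(columns=list(REGIMES)).reset_index()
    out.insert(3, "n_species", n.max(axis=1).to_numpy())
    return out


# ---------------------------------------------------------------------------
# community-level diagnostics


def diversity_diagnostics(table_fungi: CommunityTable, table_bacteria: CommunityTable,
                          permutations: int = 999, seed: int = 0) -> dict:
    """Cross-guild diversity checks.

    Richness: per-guild species richness is regressed on sequencing depth and
    the residuals correlated between guilds (Pearson with t and p). Beta
    diversity: Bray-Curtis dissimilarities on relative abundances, correlated
    between guilds over sample pairs (parametric Pearson t/p for comparability
    plus a Mantel permutation p, which respects the non-independence of pairs).
    """
    if not table_fungi.sample_ids.equals(table_bacteria.sample_ids):
        raise ValueError("tables must cover the same samples in the same order")
    out = {}
    resid = {}
    richness_raw = {}
    for t in (table_fungi, table_bacteria):
        rich = (t.counts.to_numpy() > 0).sum(axis=1).astype(float)
        depth = t.depth.to_numpy(float)
        slope, intercept = np.polyfit(depth, rich, 1)
        resid[t.guild] = rich - (intercept + slope * depth)
        richness_raw[t.guild] = rich
    r, p = stats.pearsonr(resid["fungi"], resid["bacteria"])
    n = len(resid["fungi"])
    out["richness_residual_correlation"] = {
        "r": float(r), "t": float(r * np.sqrt((n - 2) / (1 - r**2))), "p": float(p),
    }
    r_raw, p_raw = stats.pearsonr(richness_raw["fungi"], richness_raw["bacteria"])
    out["richness_raw_correlation"] = {"r": float(r_raw), "p": float(p_raw)}

    dms = {}
    for t in (table_fungi, table_bacteria):
        rel = t.counts.to_numpy(float) / t.depth.to_numpy(float)[:, None]
        dms[t.guild] = pdist(rel, metric="braycurtis")
    r, p = stats.pearsonr(dms["fungi"], dms["bacteria"])
    m = len(dms["fungi"])
    out["beta_diversity_correlation"] = {
        "r": float(r), "t": float(r * np.sqrt((m - 2) / (1 - r**2))), "p_parametric": float(p),
    }
    from skbio.stats.distance import DistanceMatrix, mantel

    ids = [str(s) for s in table_fungi.sample_ids]
    mr, mp, _ = mantel(DistanceMatrix(squareform(dms["fungi"]), ids=ids),
                       DistanceMatrix(squareform(dms["bacteria"]), ids=ids),
                       method="pearson", permutations=permutations, seed=seed)
    out["beta_diversity_correlation"]["p_mantel"] = float(mp)
    out["beta_diversity_correlation"]["r_mantel"] = float(mr)
    return out
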