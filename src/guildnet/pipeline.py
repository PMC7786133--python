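"""End-to-end orchestration: load or simulate -> filter -> fit null & full ->
networks -> variance partitioning -> cross-validation -> reports.

A run is driven by one YAML config (see :func:`template_config`); every stage
writes TSV/JSON artifacts into the output directory and records itself in the
run manifest. Completed stages whose artifacts exist under the same config
hash are skipped on resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import (
    compare_networks,
    compute_association_network,
    variance_partition,
    variance_partition_summary,
)
from .data import (
    CommunityTable,
    FilterSpec,
    HurdleResponse,
    assemble_hurdle_response,
    build_joint_design,
    concat_hurdle_responses,
    filter_otus,
    read_community_table,
    read_metadata,
    write_community_table,
    write_edge_list,
    write_manifest,
    write_matrix,
    write_report,
)
from .evaluate import (
    CVSpec,
    directionality_gain,
    diversity_diagnostics,
    evaluate_models,
    report_table,
)
from .model import HurdleLatentFactorJSDM, convergence_report
from .simulate import SimulationConfig, make_asymmetric_scenario, simulate_community

logger = logging.getLogger("guildnet")


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``data`` / ``simulation`` is set."""

    outdir: str = "guildnet_run"
    seed: int = 0
    data: dict | None = None          # {counts_fungi, counts_bacteria, metadata}
    simulation: dict | None = None    # SimulationConfig fields (+ asymmetric: bool)
    filter: dict = field(default_factory=dict)        # FilterSpec fields
    model: dict = field(default_factory=dict)         # HurdleLatentFactorJSDM params
    cv: dict = field(default_factory=dict)            # CVSpec fields
    support_level: float = 0.95
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if (self.data is None) == (self.simulation is None):
            raise ValueError("config must set exactly one of 'data' and 'simulation'")
        if self.data is not None:
            for key in ("counts_fungi", "counts_bacteria", "metadata"):
                if key not in self.data:
                    raise ValueError(f"data block missing {key!r}")
                if not Path(self.data[key]).exists():
                    raise FileNotFoundError(self.data[key])

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def template_config() -> str:
    """A commented YAML template with every default documented."""
    return """\
# guildnet run configuration
outdir: guildnet_run
seed: 0
# Exactly one of `data` and `simulation` must be present.
# data:
#   counts_fungi: fungi_counts.tsv        # samples x OTUs, tab-separated
#   counts_bacteria: bacteria_counts.tsv
#   metadata: metadata.tsv                # water, ph, c, n, lignin, tree_species,
#                                         # decay_class, dbh, reads_fungi, reads_bacteria
simulation:
  n_samples: 60
  n_species_fungi: 15
  n_species_bacteria: 15
  n_factors: 2
  asymmetric: true          # bacterial loadings 3x fungal (directional scenario)
filter:
  min_prevalence: 0.10      # keep OTUs with prevalence strictly > 10%
  min_max_relabund: 0.005   # ... and >= 0.5% relative abundance in >= 1 sample
model:
  n_factors: 2
  n_chains: 2
  n_iter: 2000              # desk-scale default; field-scale profile: 4 chains,
  n_burn: 500               # 150000 iterations, 50000 burn, thin 100
  thin: 5
cv:
  n_folds: 2
  outer_draws: 40           # posterior draws used for conditional prediction
  inner_burn: 20
  inner_draws: 40
support_level: 0.95         # posterior sign-support needed for a network edge
verbosity: info
"""


class PipelineRun:
    """Stage runner with manifest bookkeeping and resume support."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = self._load_manifest()

    def _load_manifest(self) -> dict:
        chash = self.config.config_hash()
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                manifest = json.load(fh)
            if manifest.get("config_hash") == chash:
                return manifest
        return {
            "config_hash": chash,
            "version": __version__,
            "seed": self.config.seed,
            "stages": {},
        }

    def _save(self) -> None:
        write_manifest(self.manifest, self.manifest_path)

    def done(self, stage: str) -> bool:
        info = self.manifest["stages"].get(stage)
        if not info or info.get("status") != "ok":
            return False
        return all(Path(p).exists() for p in info.get("artifacts", []))

    def run_stage(self, stage: str, fn, *args, **kwargs):
        if self.done(stage):
            logger.info("stage %s: up to date, skipping", stage)
            return None
        t0 = time.time()
        try:
            artifacts = fn(*args, **kwargs) or []
        except Exception as exc:
            self.manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            self._save()
            raise
        self.manifest["stages"][stage] = {
            "status": "ok",
            "wall_time_s": round(time.time() - t0, 2),
            "artifacts": [str(a) for a in artifacts],
        }
        self._save()
        return artifacts


def _load_or_simulate(config: RunConfig):
    if config.data is not None:
        tables = {
            "fungi": read_community_table(config.data["counts_fungi"], "fungi"),
            "bacteria": read_community_table(config.data["counts_bacteria"], "bacteria"),
        }
        meta = read_metadata(config.data["metadata"])
        return tables, meta
    sim_kwargs = dict(config.simulation)
    asym = sim_kwargs.pop("asymmetric", False)
    sim_kwargs.setdefault("seed", config.seed)
    sim = SimulationConfig(**sim_kwargs)
    if asym:
        sim = make_asymmetric_scenario(sim)
    study = simulate_community(sim)
    return study.tables, study.metadata


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest."""
    run = PipelineRun(config)
    outdir = run.outdir
    fspec = FilterSpec(**config.filter)
    est = HurdleLatentFactorJSDM(**{"random_state": config.seed, **config.model})
    cv = CVSpec(**{"seed": config.seed, **config.cv})

    tables, meta = _load_or_simulate(config)

    def stage_input():
        arts = []
        for guild, t in tables.items():
            path = outdir / f"counts_{guild}.tsv"
            write_community_table(t, path)
            arts.append(path)
        meta.to_csv(outdir / "metadata.tsv", sep="\t")
        arts.append(outdir / "metadata.tsv")
        return arts

    run.run_stage("input", stage_input)

    filtered = {g: filter_otus(t, fspec) for g, t in tables.items()}
    responses = {g: assemble_hurdle_response(t) for g, t in filtered.items()}
    response = concat_hurdle_responses(responses["fungi"], responses["bacteria"])

    def stage_filter():
        arts = []
        for guild, t in filtered.items():
            path = outdir / f"counts_{guild}_filtered.tsv"
            write_community_table(t, path)
            arts.append(path)
        return arts

    run.run_stage("filter", stage_filter)

    def stage_diagnostics():
        diag = diversity_diagnostics(filtered["fungi"], filtered["bacteria"],
                                     seed=config.seed)
        path = outdir / "diversity_diagnostics.json"
        write_manifest(diag, path)
        return [path]

    run.run_stage("diagnostics", stage_diagnostics)

    # fitted models are persisted under the output directory so that later
    # stages (and resumed runs) reload them instead of refitting
    fits: dict = {}

    def get_fit(model: str) -> HurdleLatentFactorJSDM:
        if model in fits:
            return fits[model]
        post_dir = outdir / f"posterior_{model}"
        if (post_dir / "index.json").exists():
            fit = HurdleLatentFactorJSDM.load(post_dir)
        else:
            design = build_joint_design(meta, model=model)
            fit = HurdleLatentFactorJSDM(**{
                **est.get_params(),
                "random_state": config.seed + (0 if model == "null" else 1)})
            fit.fit(design, response)
            fit.save(post_dir)
        fits[model] = fit
        return fit

    for model in ("null", "full"):

        def stage_fit(model=model):
            fit = get_fit(model)
            conv = convergence_report(fit, seed=config.seed)
            path = outdir / f"convergence_{model}.tsv"
            rows = [{"block": block, "max_psrf": rep.max_psrf, "min_ess": rep.min_ess}
                    for block, rep in conv.items()]
            write_report(pd.DataFrame(rows), path)
            return [path, outdir / f"posterior_{model}" / "index.json"]

        run.run_stage(f"fit_{model}", stage_fit)

    def stage_networks():
        nets = {
            (model, part): compute_association_network(
                get_fit(model), part=part, support_level=config.support_level)
            for model in ("null", "full") for part in ("occurrence", "abundance")
        }
        arts = []
        for (model, part), net in nets.items():
            epath = outdir / f"network_{model}_{part}_edges.tsv"
            write_edge_list(net.edge_list(), epath)
            mpath = outdir / f"network_{model}_{part}_R.tsv"
            write_matrix(net.R_mean, mpath)
            arts += [epath, mpath]
        contrast = pd.concat(
            [compare_networks(nets["null", part], nets["full", part]).assign(part=part)
             for part in ("occurrence", "abundance")], ignore_index=True)
        cpath = outdir / "network_contrast.tsv"
        write_report(contrast, cpath)
        arts.append(cpath)
        return arts

    run.run_stage("networks", stage_networks)

    def stage_varpart():
        fit = get_fit("full")
        vp = variance_partition(fit, fit.design_info_)
        path = outdir / "variance_partition.tsv"
        write_report(vp, path)
        spath = outdir / "variance_partition_summary.tsv"
        write_report(variance_partition_summary(vp), spath)
        return [path, spath]

    run.run_stage("varpart", stage_varpart)

    def stage_cv():
        report = evaluate_models(meta, response, models=("null", "full"),
                                 cv=cv, estimator=est)
        rpath = outdir / "evaluation_per_species.tsv"
        write_report(report, rpath)
        tpath = outdir / "table_powers.tsv"
        write_report(report_table(report), tpath)
        gpath = outdir / "directionality_gains.tsv"
        write_report(directionality_gain(report), gpath)
        return [rpath, tpath, gpath]

    run.run_stage("cv", stage_cv)

    run.manifest["status"] = "complete"
    run._save()
    return run.manifest
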