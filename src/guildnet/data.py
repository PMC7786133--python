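"""Community tables, metadata, OTU filtering, design matrices, and result export.

Counts are tab-separated files with samples as rows (first column sample id,
header row of OTU ids). Metadata carries deadwood chemistry (water %, pH, C %,
N %, lignin %), physical log characteristics (tree species, decay class, DBH),
and per-guild sequencing depths.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("guildnet")

GUILDS = ("fungi", "bacteria")

TREE_LEVELS = ("beech", "spruce", "fir")
DECAY_LEVELS = ("<5", "5-15", "16-38", ">38")

#: metadata columns required by the full model
METADATA_COLUMNS = (
    "water",
    "ph",
    "c",
    "n",
    "lignin",
    "tree_species",
    "decay_class",
    "dbh",
    "reads_fungi",
    "reads_bacteria",
)

#: names under which a carbon-to-nitrogen ratio column may appear; always dropped
CN_ALIASES = ("cn", "c_n", "cn_ratio", "c_n_ratio", "c/n")


class CommunityTableError(ValueError):
    """Raised when a community table fails validation."""


@dataclass
class CommunityTable:
    """Integer OTU count matrix for one guild, samples as rows.

    ``depth`` (total reads per sample) is defined as the row sum, so the
    row-sum invariant holds by construction.
    """

    counts: pd.DataFrame
    guild: str

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise CommunityTableError(f"unknown guild {self.guild!r}; expected one of {GUILDS}")
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].tolist()
            raise CommunityTableError(f"duplicated sample ids: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].tolist()
            raise CommunityTableError(f"duplicated OTU ids: {dup}")
        if c.shape[0] < 2:
            raise CommunityTableError("need at least 2 samples")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                i, j = np.argwhere(arr != np.round(arr))[0]
                raise CommunityTableError(
                    f"non-integer count at sample {c.index[i]!r}, OTU {c.columns[j]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise CommunityTableError(
                f"negative count at sample {c.index[i]!r}, OTU {c.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def depth(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]


@dataclass
class FilterSpec:
    """Rare-OTU screen: keep OTUs with prevalence strictly above
    ``min_prevalence`` and a per-sample relative abundance of at least
    ``min_max_relabund`` in at least one sample."""

    min_prevalence: float = 0.10
    min_max_relabund: float = 0.005

    def __post_init__(self) -> None:
        for name in ("min_prevalence", "min_max_relabund"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1), got {v}")


def read_community_table(path, guild: str, transposed: bool = False) -> CommunityTable:
    """Read a TSV count table (first column sample id, header OTU ids).

    ``transposed=True`` accepts OTU-by-sample tables and flips them.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transposed:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise CommunityTableError(
                f"non-numeric count at sample {bad.index[0]!r}, OTU {col!r} in {path}"
            )
    return CommunityTable(df, guild=guild)


def write_community_table(table: CommunityTable, path) -> None:
    table.counts.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate metadata and drop any C/N-ratio column (excluded from models
    because it is nearly collinear with wood N content)."""
    meta = meta.copy()
    drop = [c for c in meta.columns if c.strip().lower() in CN_ALIASES]
    if drop:
        logger.info("ignoring C/N ratio column(s) %s: excluded as an explanatory variable", drop)
        meta = meta.drop(columns=drop)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    for col in ("water", "c", "n", "lignin"):
        vals = meta[col].to_numpy(float)
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError(f"{col} must be a percentage in [0, 100]")
    ph = meta["ph"].to_numpy(float)
    if np.any((ph <= 0) | (ph >= 14)):
        raise ValueError("pH must lie in (0, 14)")
    if meta[list(METADATA_COLUMNS)].isna().any().any():
        bad = meta.columns[meta[list(METADATA_COLUMNS)].isna().any()].tolist()
        raise ValueError(f"missing values in covariates: {bad}")
    bad_levels = set(meta["tree_species"]) - set(TREE_LEVELS)
    if bad_levels:
        raise ValueError(f"unknown tree species levels: {sorted(bad_levels)}")
    bad_levels = set(meta["decay_class"]) - set(DECAY_LEVELS)
    if bad_levels:
        raise ValueError(f"unknown decay class levels: {sorted(bad_levels)}")
    return meta


def filter_otus(table: CommunityTable, spec: FilterSpec) -> CommunityTable:
    """Apply the rare-OTU screen; sample rows are unchanged.

    Prevalence is compared strictly (> threshold) while the relative-abundance
    maximum is inclusive (>= threshold).
    """
    counts = table.counts
    depth = table.depth.to_numpy(float)
    present = counts.to_numpy() > 0
    prevalence = present.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        relabund = counts.to_numpy(float) / depth[:, None]
    relabund = np.nan_to_num(relabund)
    max_relabund = relabund.max(axis=0)
    keep = (prevalence > spec.min_prevalence) & (max_relabund >= spec.min_max_relabund)
    if not keep.any():
        raise CommunityTableError(
            "all OTUs removed by the filter; relax min_prevalence/min_max_relabund"
        )
    return CommunityTable(counts.loc[:, counts.columns[keep]], guild=table.guild)


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignMatrix:
    """Fixed-effect design with covariate-group bookkeeping.

    ``group_map`` assigns every non-intercept column to exactly one of
    {chemical, physical, depth}; used downstream by variance partitioning.
    """

    frame: pd.DataFrame
    group_map: dict[str, str]
    reference_levels: dict[str, str] = field(default_factory=dict)
    model: str = "full"

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(float)

    @property
    def column_names(self) -> list[str]:
        return list(self.frame.columns)

    def __post_init__(self) -> None:
        for col in self.frame.columns:
            if col == "intercept":
                continue
            if col not in self.group_map:
                raise ValueError(f"design column {col!r} not assigned to a covariate group")


def _log_reads(meta: pd.DataFrame, guild: str) -> pd.Series:
    reads = meta[f"reads_{guild}"].to_numpy(float)
    if np.any(reads <= 0):
        raise ValueError(f"reads_{guild} must be positive before log transform")
    return pd.Series(np.log(reads), index=meta.index, name=f"log_reads_{guild}")


def _chemical_physical_columns(meta: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    n_content = meta["n"].to_numpy(float)
    if np.any(n_content <= 0):
        raise ValueError("N content must be positive before log transform")
    cols = {
        "water": meta["water"].to_numpy(float),
        "ph": meta["ph"].to_numpy(float),
        "c": meta["c"].to_numpy(float),
        "log_n": np.log(n_content),
        "lignin": meta["lignin"].to_numpy(float),
    }
    group = {k: "chemical" for k in cols}
    tree = pd.Categorical(meta["tree_species"], categories=TREE_LEVELS)
    for lev in TREE_LEVELS[1:]:
        name = f"tree_{lev}"
        cols[name] = (tree == lev).astype(float)
        group[name] = "physical"
    decay = pd.Categorical(meta["decay_class"], categories=DECAY_LEVELS)
    decay_names = {"5-15": "decay_5to15", "16-38": "decay_16to38", ">38": "decay_gt38"}
    for lev in DECAY_LEVELS[1:]:
        name = decay_names[lev]
        cols[name] = (decay == lev).astype(float)
        group[name] = "physical"
    cols["dbh"] = meta["dbh"].to_numpy(float)
    group["dbh"] = "physical"
    return pd.DataFrame(cols, index=meta.index), group


def build_design_matrix(meta: pd.DataFrame, model: str = "full", guild: str = "fungi") -> DesignMatrix:
    """Per-guild design: null = intercept + that guild's log reads (2 columns);
    full adds wood chemistry and physical covariates (13 columns)."""
    if model not in ("null", "full"):
        raise ValueError(f"model must be 'null' or 'full', got {model!r}")
    if guild not in GUILDS:
        raise ValueError(f"guild must be one of {GUILDS}")
    meta = validate_metadata(meta)
    depth_col = _log_reads(meta, guild)
    parts = {"intercept": np.ones(len(meta))}
    group: dict[str, str] = {}
    if model == "full":
        chem_phys, group = _chemical_physical_columns(meta)
        parts.update({c: chem_phys[c].to_numpy() for c in chem_phys.columns})
    parts[depth_col.name] = depth_col.to_numpy()
    group[depth_col.name] = "depth"
    frame = pd.DataFrame(parts, index=meta.index)
    refs = {"tree_species": TREE_LEVELS[0], "decay_class": DECAY_LEVELS[0]}
    logger.info(
        "built %s design for %s: %d columns (reference levels %s)",
        model, guild, frame.shape[1], refs,
    )
    return DesignMatrix(frame, group, refs, model=model)


def build_joint_design(meta: pd.DataFrame, model: str = "full") -> DesignMatrix:
    """Design for the joint two-guild model: as the per-guild design but with
    one log-reads column per guild (both in the 'depth' group)."""
    if model not in ("null", "full"):
        raise ValueError(f"model must be 'null' or 'full', got {model!r}")
    meta = validate_metadata(meta)
    parts = {"intercept": np.ones(len(meta))}
    group: dict[str, str] = {}
    if model == "full":
        chem_phys, group = _chemical_physical_columns(meta)
        parts.update({c: chem_phys[c].to_numpy() for c in chem_phys.columns})
    for guild in GUILDS:
        s = _log_reads(meta, guild)
        parts[s.name] = s.to_numpy()
        group[s.name] = "depth"
    frame = pd.DataFrame(parts, index=meta.index)
    refs = {"tree_species": TREE_LEVELS[0], "decay_class": DECAY_LEVELS[0]}
    return DesignMatrix(frame, group, refs, model=model)


# ---------------------------------------------------------------------------
# hurdle response


@dataclass
class HurdleResponse:
    """Two-part response: presence-absence and standardized log abundance
    conditional on presence (absences are missing, not zero).

    ``log_mean``/``log_sd`` are the per-OTU scaling parameters over presences;
    OTUs with fewer than two presences or zero log-count variance are flagged
    in ``degenerate`` (their abundance part is unidentifiable).
    """

    pa: pd.DataFrame
    abund: pd.DataFrame
    log_mean: pd.Series
    log_sd: pd.Series
    guild: pd.Series
    degenerate: pd.Series

    @property
    def otu_ids(self) -> pd.Index:
        return self.pa.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.pa.index

    @property
    def n_otus(self) -> int:
        return self.pa.shape[1]


def assemble_hurdle_response(table: CommunityTable) -> HurdleResponse:
    """Truncate counts to presence-absence and z-score log counts over presences."""
    counts = table.counts.to_numpy(float)
    pa = (counts > 0).astype(np.int8)
    if (pa.sum(axis=0) == 0).any():
        j = int(np.argmax(pa.sum(axis=0) == 0))
        raise CommunityTableError(
            f"OTU {table.otu_ids[j]!r} has no presences; filter before assembling"
        )
    logc = np.full_like(counts, np.nan)
    np.log(counts, out=logc, where=counts > 0)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(logc, axis=0)
        sd = np.nanstd(logc, axis=0, ddof=1)
    n_pres = pa.sum(axis=0)
    degenerate = (n_pres < 2) | ~np.isfinite(sd) | (sd == 0)
    if degenerate.any():
        logger.info(
            "%d OTU(s) have an unidentifiable abundance part (<2 presences or zero variance)",
            int(degenerate.sum()),
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    abund = (logc - mu) / safe_sd
    idx, cols = table.sample_ids, table.otu_ids
    return HurdleResponse(
        pa=pd.DataFrame(pa, index=idx, columns=cols),
        abund=pd.DataFrame(abund, index=idx, columns=cols),
        log_mean=pd.Series(mu, index=cols),
        log_sd=pd.Series(np.where(degenerate, np.nan, sd), index=cols),
        guild=pd.Series(table.guild, index=cols),
        degenerate=pd.Series(degenerate, index=cols),
    )


def concat_hurdle_responses(*responses: HurdleResponse) -> HurdleResponse:
    """Column-concatenate per-guild responses into the joint response in which
    every OTU appears once in the presence part and once in the abundance part."""
    first = responses[0]
    for r in responses[1:]:
        if not r.sample_ids.equals(first.sample_ids):
            raise ValueError("sample ids differ between guild responses")
    cat = lambda attr: pd.concat([getattr(r, attr) for r in responses], axis=1)  # noqa: E731
    cats = lambda attr: pd.concat([getattr(r, attr) for r in responses])  # noqa: E731
    joint = HurdleResponse(
        pa=cat("pa"), abund=cat("abund"),
        log_mean=cats("log_mean"), log_sd=cats("log_sd"),
        guild=cats("guild"), degenerate=cats("degenerate"),
    )
    if joint.pa.columns.has_duplicates:
        raise ValueError("duplicated OTU ids across guilds; prefix them per guild")
    return joint


def back_transform_abundance(resp: HurdleResponse) -> pd.DataFrame:
    """Recover log counts from standardized abundances (present entries only)."""
    return resp.abund * resp.log_sd + resp.log_mean


# ---------------------------------------------------------------------------
# export helpers


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
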