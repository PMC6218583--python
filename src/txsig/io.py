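"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV.  Gene sets travel as GMT (one set per
line: name, description, then members).  The run configuration is a flat
YAML file that round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .containers import CountMatrix, GeneSetCollection, GeneSignature, RankedProfile

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "RunConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_gmt",
    "write_gmt",
    "read_ranked_profile",
    "write_ranked_profile",
    "read_signature",
    "write_signature",
    "read_de_table",
    "write_de_table",
    "read_annotation",
]


@dataclass
class RunConfig:
    """Run-level parameters of the analysis pipeline.

    Defaults mirror the study design this package emulates: differentially
    expressed genes are called at a 10% false-discovery rate, query
    signatures take the 75 most up- and 75 most down-regulated genes, and
    gene sets of 15-250 (effective) members enter the enrichment stage.

    Attributes
    ----------
    seed : master seed; every random stage derives its stream from it.
    fdr_deg : FDR threshold for calling differentially expressed genes.
    fdr_pathway : FDR threshold a pathway must pass in every contrast.
    signature_k : number of genes in each block of the query signature.
    set_min, set_max : inclusive bounds on effective gene-set size.
    n_perm : permutations for enrichment and connectivity null models.
    overlap_threshold : Jaccard index above which two sets are redundant.
    gsea_weight : exponent on |statistic| in the enrichment running sum.
    """

    seed: int = 0
    fdr_deg: float = 0.10
    fdr_pathway: float = 0.10
    signature_k: int = 75
    set_min: int = 15
    set_max: int = 250
    n_perm: int = 1000
    overlap_threshold: float = 0.5
    gsea_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        for name in ("fdr_deg", "fdr_pathway"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        for name in ("signature_k", "set_min", "set_max", "n_perm"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if not self.set_min < self.set_max:
            raise ValueError("set_min must be < set_max")
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in (0,1]")
        if self.gsea_weight < 0:
            raise ValueError("gsea_weight must be non-negative")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(path: PathLike, condition_map_path: PathLike) -> CountMatrix:
    """Parse a gene x sample count TSV plus its sample-to-condition map.

    The count file has a header row of sample names and gene identifiers in
    the first column.  Cells must be non-negative integers; violations are
    reported with their (gene, sample) coordinates.  The condition map is a
    two-column TSV (sample, condition) covering every sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene identifier: {dup!r}")
    counts = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        parsed = pd.to_numeric(df[col].str.strip(), errors="coerce")
        bad = parsed.isna() | (parsed != np.floor(parsed.fillna(0.5)))
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-integer count at gene {gene!r}, sample {col!r}"
            )
        neg = parsed < 0
        if neg.any():
            gene = df.index[neg.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: negative count at gene {gene!r}, sample {col!r}"
            )
        counts[col] = parsed.astype(np.int64)
    cmap = pd.read_csv(condition_map_path, sep="\t", dtype=str)
    if cmap.shape[1] < 2:
        raise ValueError(f"{condition_map_path}: expected columns (sample, condition)")
    cmap = cmap.iloc[:, :2]
    cmap.columns = ["sample", "condition"]
    if cmap["sample"].duplicated().any():
        dup = cmap["sample"][cmap["sample"].duplicated()].iloc[0]
        raise ValueError(f"{condition_map_path}: duplicate sample {dup!r}")
    conditions = pd.Series(
        cmap["condition"].to_numpy(), index=cmap["sample"].to_numpy()
    )
    missing = [s for s in counts.columns if s not in conditions.index]
    if missing:
        raise ValueError(f"{condition_map_path}: samples missing from map: {missing}")
    return CountMatrix(counts, conditions)


def write_count_matrix(cm: CountMatrix, path: PathLike, condition_map_path: PathLike) -> None:
    out = cm.counts.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    pd.DataFrame(
        {"sample": cm.sample_ids, "condition": [cm.conditions[s] for s in cm.sample_ids]}
    ).to_csv(condition_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, members...

    Within-set duplicate members are collapsed with a logged warning;
    duplicate set names are an error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 fields "
                    f"(name, description, members...), got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "%s:%d: set %r has duplicate members; collapsed %d -> %d",
                    path, lineno, name, len(members), len(unique),
                )
            sets[name] = frozenset(unique)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            desc = collection.descriptions.get(name, "")
            members = sorted(collection[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# ranked profiles


def read_ranked_profile(path: PathLike) -> RankedProfile:
    """Parse a two-column TSV (gene, signed statistic) into a ranking.

    Genes are ordered by statistic descending; ties break by ascending
    gene identifier.  Duplicate genes or non-numeric statistics are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene, statistic)")
    genes = df.iloc[:, 0].to_numpy()
    stats = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if stats.isna().any():
        row = int(stats.isna().to_numpy().nonzero()[0][0])
        raise ValueError(
            f"{path}: non-numeric statistic {df.iloc[row, 1]!r} "
            f"for gene {genes[row]!r}"
        )
    return RankedProfile.from_unsorted(list(genes), stats.to_numpy(dtype=float))


def write_ranked_profile(profile: RankedProfile, path: PathLike) -> None:
    pd.DataFrame({"gene": profile.genes, "stat": profile.stats}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# signatures, DE tables, annotations


def write_signature(sig: GeneSignature, path: PathLike, stats: dict | None = None) -> None:
    """Write a signature as TSV with columns (gene, direction, rank, stat)."""
    rows = []
    for rank, g in enumerate(sig.up, start=1):
        rows.append((g, "up", rank, np.nan if stats is None else stats.get(g, np.nan)))
    for rank, g in enumerate(sig.down, start=1):
        rows.append((g, "down", rank, np.nan if stats is None else stats.get(g, np.nan)))
    pd.DataFrame(rows, columns=["gene", "direction", "rank", "stat"]).to_csv(
        path, sep="\t", index=False
    )


def read_signature(path: PathLike, name: str | None = None) -> GeneSignature:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "direction": str})
    for col in ("gene", "direction"):
        if col not in df.columns:
            raise ValueError(f"{path}: signature file needs a {col!r} column")
    if "rank" in df.columns:
        df = df.sort_values(["direction", "rank"], kind="stable")
    up = list(df.loc[df["direction"] == "up", "gene"])
    down = list(df.loc[df["direction"] == "down", "gene"])
    return GeneSignature(name or Path(path).stem, tuple(up), tuple(down))


def write_de_table(table: pd.DataFrame, path: PathLike) -> None:
    out = table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_de_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("log2fc", "stat", "p", "fdr"):
        if col not in df.columns:
            raise ValueError(f"{path}: DE table missing column {col!r}")
    return df


def read_annotation(path: PathLike) -> dict:
    """Parse a two-column (gene, role) annotation table into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (gene, role)")
    genes = df.iloc[:, 0]
    roles = df.iloc[:, 1]
    return dict(zip(genes, roles))
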