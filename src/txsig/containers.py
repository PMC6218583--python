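"""Core in-memory containers shared across the pipeline stages.

The pipeline moves four kinds of objects between stages: an integer count
matrix with a sample-to-condition map, gene-set collections, ranked gene
profiles (a full gene list ordered by a signed statistic), and up/down
query signatures.  All gene identifiers are opaque, case-sensitive strings
matched by exact equality across files and stages.

Every ordering in the package uses a single total tie rule: sort by the
statistic (descending) and break ties by ascending gene identifier, so
repeated runs are reproducible to the byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "RankedProfile",
    "GeneSignature",
    "DEResult",
    "rank_order",
]


def rank_order(genes: Sequence[str], stats: np.ndarray) -> np.ndarray:
    """Indices sorting ``stats`` descending, ties by ascending gene id.

    This is the package-wide total order used for every ranking.
    """
    genes = np.asarray(genes, dtype=object)
    stats = np.asarray(stats, dtype=float)
    return np.lexsort((genes, -stats))


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample matrix with condition labels.

    Parameters
    ----------
    counts
        DataFrame indexed by gene identifier with one column per sample.
        Cells must be non-negative integers.
    conditions
        Series mapping every sample (index) to its condition label.
    """

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere((values != np.floor(values)) | ~np.isfinite(values))
                g, s = bad[0]
                raise ValueError(
                    "non-integer count at gene "
                    f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative count at gene "
                f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
            )
        missing = [s for s in self.counts.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples missing from condition map: {missing}")
        # keep only (and order) the mapped samples that exist in the matrix
        self.conditions = self.conditions.loc[list(self.counts.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def condition_labels(self) -> list[str]:
        """Distinct condition labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c, None)
        return list(seen)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.conditions[s] == condition]

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.conditions.copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def restrict(self, names: Iterable[str]) -> "GeneSetCollection":
        keep = [n for n in self.names if n in set(names)]
        return GeneSetCollection(
            {n: self.sets[n] for n in keep},
            {n: self.descriptions[n] for n in keep if n in self.descriptions},
        )


@dataclass(frozen=True)
class RankedProfile:
    """All genes of a profile ordered by a signed statistic, descending.

    ``genes[0]`` carries the largest statistic.  Ties in the statistic are
    broken by ascending gene identifier so the order is total.
    """

    genes: tuple
    stats: tuple

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        stats = tuple(float(s) for s in self.stats)
        if len(genes) != len(stats):
            raise ValueError("genes and stats must have equal length")
        if len(set(genes)) != len(genes):
            seen: set[str] = set()
            for g in genes:
                if g in seen:
                    raise ValueError(f"duplicate gene in ranked profile: {g!r}")
                seen.add(g)
        for i in range(len(stats) - 1):
            if stats[i] < stats[i + 1]:
                raise ValueError("stats must be non-increasing")
            if stats[i] == stats[i + 1] and genes[i] > genes[i + 1]:
                raise ValueError("tied stats must be ordered by ascending gene id")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "stats", stats)

    @classmethod
    def from_unsorted(
        cls, genes: Sequence[str], stats: Sequence[float]
    ) -> "RankedProfile":
        """Build a profile from unordered (gene, statistic) pairs."""
        genes = list(genes)
        if len(set(genes)) != len(genes):
            seen: set[str] = set()
            for g in genes:
                if g in seen:
                    raise ValueError(f"duplicate gene in ranked profile: {g!r}")
                seen.add(g)
        stats = np.asarray(list(stats), dtype=float)
        order = rank_order(genes, stats)
        return cls(
            tuple(genes[i] for i in order), tuple(float(stats[i]) for i in order)
        )

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self) -> dict:
        """Map gene id -> 0-based rank position."""
        return {g: i for i, g in enumerate(self.genes)}

    def stats_array(self) -> np.ndarray:
        return np.asarray(self.stats, dtype=float)

    def reversed(self) -> "RankedProfile":
        """The profile with its ordering and statistics negated."""
        return RankedProfile.from_unsorted(
            list(self.genes), [-s for s in self.stats]
        )


@dataclass(frozen=True)
class GeneSignature:
    """Disjoint ordered up- and down-regulated gene lists (the query)."""

    name: str
    up: tuple
    down: tuple

    def __post_init__(self) -> None:
        up = tuple(self.up)
        down = tuple(self.down)
        if len(set(up)) != len(up) or len(set(down)) != len(down):
            raise ValueError(f"signature {self.name!r} has duplicate genes in a block")
        overlap = set(up) & set(down)
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: up/down blocks overlap: {sorted(overlap)}"
            )
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)


@dataclass
class DEResult:
    """Per-gene differential statistics for one condition-vs-control contrast.

    ``table`` is indexed by gene and has columns ``log2fc``, ``stat``,
    ``p`` and ``fdr``.  ``stat`` (the signed Wald statistic) is the ranking
    key used by every downstream stage.
    """

    condition: str
    control: str
    table: pd.DataFrame

    REQUIRED = ("log2fc", "stat", "p", "fdr")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"DE table missing column {col!r}")
        if self.table.index.has_duplicates:
            raise ValueError("DE table has duplicate genes")

    @property
    def contrast(self) -> tuple:
        return (self.condition, self.control)

    @property
    def name(self) -> str:
        return f"{self.condition}_vs_{self.control}"

    def ranked_profile(self) -> RankedProfile:
        """Full ranking of all tested genes by the signed statistic."""
        return RankedProfile.from_unsorted(
            list(self.table.index), self.table["stat"].to_numpy()
        )
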