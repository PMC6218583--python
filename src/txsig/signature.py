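"""Signature calling: DEGs per contrast, cross-contrast intersection,
top-k/bottom-k query extraction, annotation overlap.

A gene is a DEG when its BH-adjusted p-value falls strictly below the FDR
threshold; its direction comes from the sign of the ranking statistic.
The common signature across contrasts keeps only genes called in the same
direction in every contrast; a gene up in some contrasts and down in
others is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .containers import DEResult, GeneSignature, rank_order

__all__ = [
    "CommonSignature",
    "call_degs",
    "intersect_common",
    "extract_query_signature",
    "annotate_overlap",
]


@dataclass
class CommonSignature:
    """Genes called in the same direction in every contrast."""

    up: frozenset
    down: frozenset
    per_contrast_membership: dict = field(default_factory=dict)

    @property
    def genes(self) -> frozenset:
        return self.up | self.down

    def direction_of(self, gene: str) -> str:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        raise KeyError(gene)


def call_degs(de: DEResult, fdr_threshold: float = 0.10):
    """Split a contrast's genes into (up, down) DEG sets at the threshold.

    The comparison is strict (< threshold); genes with statistic exactly 0
    are never called.
    """
    t = de.table
    sig = t["fdr"] < fdr_threshold
    up = frozenset(t.index[sig & (t["stat"] > 0)])
    down = frozenset(t.index[sig & (t["stat"] < 0)])
    return up, down


def intersect_common(calls: Mapping[str, tuple]) -> CommonSignature:
    """Intersect per-contrast (up, down) DEG calls into the common signature.

    ``calls`` maps contrast name -> (up set, down set).  A gene belongs to
    the common up-set iff it is up-called in every contrast (same for
    down); discordant genes appear in neither.  With a single contrast the
    result equals that contrast's calls.
    """
    if len(calls) < 1:
        raise ValueError("need at least one contrast")
    ups = [frozenset(u) for u, _ in calls.values()]
    downs = [frozenset(d) for _, d in calls.values()]
    common_up = frozenset.intersection(*ups)
    common_down = frozenset.intersection(*downs)
    # up in all contrasts excludes down in any single contrast (per-contrast
    # calls are sign-split), so the two intersections are disjoint already.
    membership = {c: (frozenset(u), frozenset(d)) for c, (u, d) in calls.items()}
    return CommonSignature(common_up, common_down, membership)


def extract_query_signature(de: DEResult, k: int = 75) -> GeneSignature:
    """Top-k / bottom-k genes of the contrast's statistic ranking.

    Genes are sorted by statistic descending (ties by ascending gene id);
    ``up`` is the first k, ``down`` the last k.  2k may equal the number of
    genes (the two blocks then partition the list); 2k greater than the
    number of genes is an error since the blocks would overlap.
    """
    n = len(de.table)
    if 2 * k > n:
        raise ValueError(
            f"need at least {2 * k} genes for k={k}, have {n} "
            f"(short by {2 * k - n})"
        )
    genes = list(de.table.index)
    stats = de.table["stat"].to_numpy(dtype=float)
    order = rank_order(genes, stats)
    up = tuple(genes[i] for i in order[:k])
    down = tuple(genes[i] for i in order[n - k:])
    return GeneSignature(de.name, up, down)


def annotate_overlap(
    up: Sequence[str], down: Sequence[str], annotation: Mapping[str, str]
) -> pd.DataFrame:
    """Cross a (up, down) gene split with a gene -> role annotation table.

    Returns a tidy frame with one row per (direction, role) combination
    observed, columns ``direction``, ``role``, ``count`` and the
    comma-joined ``genes``; genes absent from the table are tallied under
    the role ``unannotated``.
    """
    rows = []
    for direction, genes in (("up", up), ("down", down)):
        by_role: dict[str, list] = {}
        for g in sorted(set(genes)):
            role = annotation.get(g, "unannotated")
            by_role.setdefault(role, []).append(g)
        for role in sorted(by_role):
            members = by_role[role]
            rows.append((direction, role, len(members), ",".join(members)))
    return pd.DataFrame(rows, columns=["direction", "role", "count", "genes"])
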