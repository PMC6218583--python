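"""Pre-ranked gene-set enrichment with a gene-permutation null.

Given a full gene ranking (signed statistics, descending) and a gene-set
collection, the stage computes the weighted Kolmogorov-Smirnov running-sum
enrichment score per set, normalizes it against random same-size gene sets
(NES), assigns permutation p-values and BH FDRs, prunes highly overlapping
sets greedily by Jaccard index, and selects the pathways enriched with a
consistent sign across all contrasts.

The running sum walks the ranking; at position i,

    P_hit(i)  = sum of |stat_j|^weight over set members at ranks <= i,
                normalized by the total over all members,
    P_miss(i) = fraction of non-members at ranks <= i,

and the enrichment score is the signed deviation P_hit - P_miss of maximal
magnitude (positive wins exact-magnitude ties).  The leading edge is the
set members at or before the extremum for a positive score, and strictly
after it for a negative score.

The permutation null draws random gene sets of identical effective size
from the ranked universe, the standard choice for pre-ranked enrichment
where no sample labels exist to permute.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GeneSetCollection, RankedProfile
from .diffexpr import benjamini_hochberg
from .signature import CommonSignature

logger = logging.getLogger(__name__)

__all__ = [
    "filter_gene_sets",
    "enrichment_score",
    "permutation_nes",
    "enrich_collection",
    "remove_redundant",
    "consistent_pathways",
    "display_score",
    "leading_edge_common",
]


def filter_gene_sets(
    collection: GeneSetCollection,
    universe: Sequence[str],
    set_min: int = 15,
    set_max: int = 250,
) -> GeneSetCollection:
    """Intersect each set with the universe, keep sizes in [set_min, set_max].

    Bounds are inclusive and apply to the *effective* size (members present
    in the universe).  Sets are returned with their effective membership.
    """
    if len(universe) == 0:
        raise ValueError("universe is empty")
    uni = frozenset(universe)
    kept: dict[str, frozenset] = {}
    for name in collection.names:
        eff = collection[name] & uni
        if set_min <= len(eff) <= set_max:
            kept[name] = eff
    if not kept:
        logger.warning(
            "no gene set survived size filtering to [%d, %d]", set_min, set_max
        )
    return GeneSetCollection(
        kept, {n: collection.descriptions.get(n, "") for n in kept}
    )


def enrichment_score(
    profile: RankedProfile, set_members, weight: float = 1.0
):
    """Weighted KS running-sum enrichment score and leading edge.

    Returns ``(es, leading_edge)`` where ``es`` lies in [-1, 1] and
    ``leading_edge`` is the list of set members (in rank order) driving the
    extremum.  The set must be a non-empty strict subset of the profile.
    """
    members = frozenset(set_members)
    genes = profile.genes
    n = len(genes)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the profile")
    if n_hit == n:
        raise ValueError("gene set covers the whole profile universe")
    stats = profile.stats_array()
    w = np.abs(stats) ** weight
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0.0:  # all member statistics are exactly zero
        w_hit = hit.astype(float)
        total = float(n_hit)
    p_hit = np.cumsum(w_hit) / total
    p_miss = np.cumsum(~hit) / (n - n_hit)
    dev = p_hit - p_miss
    # first index within 1e-12 of each extremum: stable when the running
    # sum attains an extremum at several positions exactly
    i_max = int(np.argmax(dev >= dev.max() - 1e-12))
    i_min = int(np.argmax(dev <= dev.min() + 1e-12))
    # positive extremum preferred on (near-)exact magnitude ties; the
    # 1e-12 slack keeps the choice stable under summation-order noise
    if dev[i_max] >= -dev[i_min] - 1e-12:
        es = float(dev[i_max])
        leading = [g for g, h in zip(genes[: i_max + 1], hit[: i_max + 1]) if h]
    else:
        es = float(dev[i_min])
        leading = [g for g, h in zip(genes[i_min + 1:], hit[i_min + 1:]) if h]
    return es, leading


def _es_from_positions(pos: np.ndarray, w_profile: np.ndarray, n: int) -> np.ndarray:
    """Enrichment scores for many position-encoded gene sets at once.

    ``pos`` is (B, t) of sorted 0-based rank positions; ``w_profile`` holds
    |stat|^weight for every rank.  Candidate extrema of the running sum
    occur only at member positions (maxima) and just before them or at the
    profile end (minima), which keeps the computation O(B * t).
    """
    B, t = pos.shape
    w = w_profile[pos]
    cw = np.cumsum(w, axis=1)
    total = cw[:, -1:]
    flat = total[:, 0] == 0.0
    if np.any(flat):  # degenerate all-zero weights: fall back to equal steps
        cw[flat] = np.arange(1, t + 1, dtype=float)
        total = np.where(total == 0.0, float(t), total)
    j = np.arange(t, dtype=float)
    miss = n - t
    # after processing member j (0-based): j+1 hits, pos[j]-j misses
    dev_at = cw / total - (pos - j) / miss
    # just before member j: j hits, pos[j]-j misses
    cw_prev = np.concatenate([np.zeros((B, 1)), cw[:, :-1]], axis=1)
    dev_before = cw_prev / total - (pos - j) / miss
    max_dev = np.maximum(dev_at.max(axis=1), 0.0)
    min_dev = np.minimum(dev_before.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev - 1e-12, max_dev, min_dev)


def _sample_position_sets(
    rng: np.random.Generator, n: int, t: int, n_perm: int, chunk: int = 256
) -> np.ndarray:
    """Draw n_perm sorted position subsets of size t from range(n)."""
    out = np.empty((n_perm, t), dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n), dtype=np.float64)
        part = np.argpartition(keys, t - 1, axis=1)[:, :t]
        out[done: done + b] = np.sort(part, axis=1)
        done += b
    return out


def permutation_nes(
    profile: RankedProfile,
    set_members,
    n_perm: int = 1000,
    seed=None,
    weight: float = 1.0,
    null_es: np.ndarray | None = None,
):
    """Normalize an enrichment score against random same-size gene sets.

    Returns ``(nes, p, null_es)``.  The null draws ``n_perm`` gene sets of
    identical effective size without replacement from the profile universe.
    NES divides the observed score by the mean |null score| over nulls of
    the same sign; the p-value is ``(1 + k) / (1 + m)`` where m counts the
    same-sign nulls and k those among them with |null| >= |es|.

    ``null_es`` may carry a precomputed null sample (as returned) so many
    sets of one effective size can share a single null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    members = frozenset(set_members) & frozenset(profile.genes)
    t = len(members)
    es, leading = enrichment_score(profile, members, weight=weight)
    n = len(profile)
    if null_es is None:
        rng = np.random.default_rng(seed)
        w_profile = np.abs(profile.stats_array()) ** weight
        pos = _sample_position_sets(rng, n, t, n_perm)
        null_es = _es_from_positions(pos, w_profile, n)
    if es == 0.0:
        return 0.0, 1.0, null_es
    same_sign = null_es > 0 if es > 0 else null_es < 0
    m = int(same_sign.sum())
    if m == 0:
        logger.warning(
            "no same-sign null ES among %d permutations; p floored", len(null_es)
        )
        scale = float(np.mean(np.abs(null_es))) if len(null_es) else 1.0
        nes = es / scale if scale > 0 else float(np.sign(es))
        return nes, 1.0 / (len(null_es) + 1.0), null_es
    nulls = null_es[same_sign]
    nes = es / float(np.mean(np.abs(nulls)))
    k = int((np.abs(nulls) >= abs(es)).sum())
    p = (1.0 + k) / (1.0 + m)
    return nes, p, null_es


def enrich_collection(
    profile: RankedProfile,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed=None,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Full enrichment table for one contrast.

    Returns a DataFrame indexed by set name with columns ``es``, ``nes``,
    ``p``, ``fdr``, ``size`` and ``leading_edge`` (tuple of genes).  FDR is
    Benjamini-Hochberg over the permutation p-values of the collection.
    Null ES samples are cached per effective set size, so same-size sets
    share one permutation draw.
    """
    rng = np.random.default_rng(seed)
    w_profile = np.abs(profile.stats_array()) ** weight
    n = len(profile)
    uni = frozenset(profile.genes)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name in collection.names:
        members = collection[name] & uni
        t = len(members)
        if t not in null_cache:
            pos = _sample_position_sets(rng, n, t, n_perm)
            null_cache[t] = _es_from_positions(pos, w_profile, n)
        es, leading = enrichment_score(profile, members, weight=weight)
        nes, p, _ = permutation_nes(
            profile, members, n_perm=n_perm, weight=weight, null_es=null_cache[t]
        )
        rows.append((name, es, nes, p, t, tuple(leading)))
    df = pd.DataFrame(
        rows, columns=["set", "es", "nes", "p", "size", "leading_edge"]
    ).set_index("set")
    df["fdr"] = benjamini_hochberg(df["p"].to_numpy())
    return df[["es", "nes", "p", "fdr", "size", "leading_edge"]]


def display_score(es: float, p: float) -> float:
    """Signed enrichment score scaled by -log10 of its p-value."""
    if not 0 < p <= 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return es * (-np.log10(p))


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def remove_redundant(
    per_contrast: Mapping[str, pd.DataFrame],
    collection: GeneSetCollection,
    overlap_threshold: float = 0.5,
) -> dict:
    """Greedy Jaccard pruning of overlapping gene sets across contrasts.

    Sets are visited in order of their best (smallest) p-value across
    contrasts (ties: larger mean |nes|, then name); a set is accepted iff
    its Jaccard index with every already-accepted set stays strictly below
    ``overlap_threshold``.  Returns the per-contrast tables restricted to
    the surviving sets.
    """
    tables = dict(per_contrast)
    names = list(next(iter(tables.values())).index)
    for tab in tables.values():
        if list(tab.index) != names:
            raise ValueError("contrasts must share one gene-set universe")
    best_p = np.min(np.column_stack([t["p"].to_numpy() for t in tables.values()]), axis=1)
    mean_abs_nes = np.mean(
        np.abs(np.column_stack([t["nes"].to_numpy() for t in tables.values()])), axis=1
    )
    order = sorted(
        range(len(names)), key=lambda i: (best_p[i], -mean_abs_nes[i], names[i])
    )
    accepted: list[str] = []
    for i in order:
        name = names[i]
        members = collection[name]
        if all(
            _jaccard(members, collection[a]) < overlap_threshold for a in accepted
        ):
            accepted.append(name)
    keep = [n for n in names if n in set(accepted)]
    return {c: tab.loc[keep] for c, tab in tables.items()}


def consistent_pathways(
    per_contrast: Mapping[str, pd.DataFrame],
    fdr_threshold: float = 0.10,
    top_n: int = 25,
) -> pd.DataFrame:
    """Pathways enriched with one sign and significant in every contrast.

    A pathway is consistent iff sign(nes) is identical and nonzero in all
    contrasts and fdr < ``fdr_threshold`` in all contrasts.  Consistent
    pathways are ranked by mean |nes| descending (ties by name) and at most
    ``top_n`` are kept.  The result carries a ``direction`` label plus
    per-contrast nes / fdr / display-score columns.
    """
    tables = dict(per_contrast)
    if not tables:
        raise ValueError("no contrasts supplied")
    names = set(next(iter(tables.values())).index)
    for tab in tables.values():
        if set(tab.index) != names:
            raise ValueError("contrasts have different pathway universes")
    contrasts = list(tables)
    rows = []
    for name in sorted(names):
        nes = np.array([tables[c].loc[name, "nes"] for c in contrasts], dtype=float)
        fdr = np.array([tables[c].loc[name, "fdr"] for c in contrasts], dtype=float)
        if np.any(nes == 0) or not (np.all(nes > 0) or np.all(nes < 0)):
            continue
        if not np.all(fdr < fdr_threshold):
            continue
        direction = "up" if nes[0] > 0 else "down"
        row = {
            "set": name,
            "direction": direction,
            "mean_abs_nes": float(np.mean(np.abs(nes))),
        }
        for c in contrasts:
            row[f"nes_{c}"] = float(tables[c].loc[name, "nes"])
            row[f"fdr_{c}"] = float(tables[c].loc[name, "fdr"])
            row[f"display_{c}"] = display_score(
                float(tables[c].loc[name, "es"]), float(tables[c].loc[name, "p"])
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        cols = ["set", "direction", "mean_abs_nes"]
        for c in contrasts:
            cols += [f"nes_{c}", f"fdr_{c}", f"display_{c}"]
        return pd.DataFrame(columns=cols).set_index("set")
    df = df.sort_values(
        ["mean_abs_nes", "set"], ascending=[False, True], kind="stable"
    ).head(top_n)
    return df.set_index("set")


def leading_edge_common(
    consistent: pd.DataFrame,
    per_contrast: Mapping[str, pd.DataFrame],
    common: CommonSignature,
) -> pd.DataFrame:
    """Leading-edge genes of consistent pathways that are also common DEGs.

    Takes the union of leading-edge genes over the consistent pathways
    (across all contrasts), intersects it with the common signature, and
    tags every gene with its common-signature direction.
    """
    edge: set = set()
    for name in consistent.index:
        for tab in per_contrast.values():
            if name in tab.index:
                edge.update(tab.loc[name, "leading_edge"])
    genes = sorted(edge & set(common.genes))
    return pd.DataFrame(
        {"gene": genes, "direction": [common.direction_of(g) for g in genes]}
    )
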