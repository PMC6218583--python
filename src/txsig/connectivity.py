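"""Bidirectional KS connectivity scoring of up/down query signatures
against reference ranked profiles.

This is the signature-matching engine: a query signature (top/bottom gene
blocks from one contrast) is compared with a reference profile (e.g. a
drug-treatment or tumor-vs-normal ranking).  A positive connectivity score
means the reference mimics the query's perturbation; a negative score
means it reverses it.

The one-sided statistic is the classic connectivity-map KS tag score: with
the matched tags at 1-based profile positions V(1) < ... < V(t) in a
profile of n genes,

    a = max_j ( j/t - V(j)/n ),    b = max_j ( V(j)/n - (j-1)/t ),

and the score is ``a`` if a >= b else ``-b``.  The combined score is zero
when the up- and down-tag scores share a sign, otherwise
(es_up - es_down)/2, rescaled by the maximum raw value attainable for the
matched block sizes (up-tags packed at the exact top, down-tags at the
exact bottom) so perfect concordance scores +1 and perfect discordance -1.
Profiles are scored independently, not rescaled as a batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GeneSignature, RankedProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityResult",
    "ks_tag_score",
    "connectivity_score",
    "permutation_p",
    "connectivity_panel",
]


@dataclass(frozen=True)
class ConnectivityResult:
    """Combined connectivity score with its one-sided components."""

    score: float
    es_up: float
    es_down: float
    n_matched_up: int
    n_matched_down: int
    p: float | None = None


def _ks_from_positions(pos1: np.ndarray, n: int) -> np.ndarray:
    """Vectorized KS tag score from sorted 1-based positions (B, t)."""
    B, t = pos1.shape
    j = np.arange(1, t + 1, dtype=float)
    a = (j / t - pos1 / n).max(axis=1)
    b = (pos1 / n - (j - 1) / t).max(axis=1)
    return np.where(a >= b, a, -b)


def ks_tag_score(profile: RankedProfile, tags) -> float:
    """One-sided KS tag score of a gene set's placement in a profile."""
    tags = frozenset(tags)
    positions = profile.positions()
    matched = sorted(positions[g] for g in tags if g in positions)
    if not matched:
        raise ValueError(
            f"no tag matches the profile; unmatched: {sorted(tags)}"
        )
    n = len(profile)
    if len(matched) == n:
        raise ValueError("tags cover the entire profile")
    pos1 = np.asarray(matched, dtype=float)[None, :] + 1.0
    return float(_ks_from_positions(pos1, n)[0])


def _max_raw(t_up: int, t_down: int, n: int) -> float:
    """Largest attainable |raw| score: up-tags at the exact top of the
    profile, down-tags at the exact bottom."""
    top = np.arange(1, t_up + 1, dtype=float)[None, :]
    bottom = np.arange(n - t_down + 1, n + 1, dtype=float)[None, :]
    es_up = float(_ks_from_positions(top, n)[0])
    es_down = float(_ks_from_positions(bottom, n)[0])
    return (es_up - es_down) / 2.0


def _combined(es_up: np.ndarray, es_down: np.ndarray, max_raw: float) -> np.ndarray:
    raw = np.where(es_up * es_down > 0, 0.0, (es_up - es_down) / 2.0)
    return raw / max_raw


def connectivity_score(
    query: GeneSignature, profile: RankedProfile
) -> ConnectivityResult:
    """Score a query signature against one reference ranked profile.

    Query genes absent from the profile are dropped (their count is logged
    and reported); each block must retain at least one matched gene.
    """
    positions = profile.positions()
    up = [g for g in query.up if g in positions]
    down = [g for g in query.down if g in positions]
    n_dropped = (len(query.up) - len(up)) + (len(query.down) - len(down))
    if n_dropped:
        logger.info(
            "query %r: dropped %d unmatched gene(s) against the profile",
            query.name, n_dropped,
        )
    if not up:
        raise ValueError(
            f"no up-tag of query {query.name!r} matches the profile; "
            f"unmatched: {sorted(query.up)}"
        )
    if not down:
        raise ValueError(
            f"no down-tag of query {query.name!r} matches the profile; "
            f"unmatched: {sorted(query.down)}"
        )
    if set(up) & set(down):
        raise ValueError("matched up/down blocks overlap")
    n = len(profile)
    if len(up) + len(down) > n:
        raise ValueError("profile smaller than the matched query")
    es_up = ks_tag_score(profile, up)
    es_down = ks_tag_score(profile, down)
    max_raw = _max_raw(len(up), len(down), n)
    score = float(
        _combined(np.array([es_up]), np.array([es_down]), max_raw)[0]
    )
    return ConnectivityResult(
        score=score,
        es_up=es_up,
        es_down=es_down,
        n_matched_up=len(up),
        n_matched_down=len(down),
    )


def permutation_p(
    sizes,
    profile: RankedProfile,
    observed_score: float,
    n_perm: int = 1000,
    seed=None,
) -> float:
    """Two-sided permutation p-value for an observed connectivity score.

    Null scores come from ``n_perm`` random disjoint (up, down) gene-set
    pairs of the given ``(t_up, t_down)`` sizes drawn from the profile;
    p = (1 + #{|null| >= |observed|}) / (1 + n_perm).
    """
    t_up, t_down = sizes
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(profile)
    if t_up + t_down > n:
        raise ValueError(
            f"profile of {n} genes cannot host disjoint blocks of "
            f"{t_up} + {t_down}"
        )
    rng = np.random.default_rng(seed)
    t = t_up + t_down
    null = np.empty(n_perm, dtype=float)
    max_raw = _max_raw(t_up, t_down, n)
    done = 0
    chunk = 256
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n))
        pos = np.argpartition(keys, t - 1, axis=1)[:, :t]
        pos = rng.permuted(pos, axis=1)  # random up/down split of the subset
        up_pos = np.sort(pos[:, :t_up], axis=1) + 1.0
        down_pos = np.sort(pos[:, t_up:], axis=1) + 1.0
        es_up = _ks_from_positions(up_pos, n)
        es_down = _ks_from_positions(down_pos, n)
        null[done: done + b] = _combined(es_up, es_down, max_raw)
        done += b
    k = int((np.abs(null) >= abs(observed_score)).sum())
    return (1.0 + k) / (1.0 + n_perm)


def connectivity_panel(
    queries: Sequence[GeneSignature],
    profiles: Mapping[str, RankedProfile],
    n_perm: int = 1000,
    seed=None,
) -> pd.DataFrame:
    """Full cross of query signatures against reference profiles.

    Returns a tidy table keyed by (query, profile) with the combined score,
    one-sided components, permutation p-value and matched-tag counts.
    Per-cell failures are recorded in the ``note`` column instead of
    aborting the panel.
    """
    if not queries or not profiles:
        raise ValueError("queries and profiles must be non-empty")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(queries) * len(profiles))
    rows = []
    i = 0
    for query in queries:
        for pname, profile in profiles.items():
            cell_seed = children[i]
            i += 1
            try:
                res = connectivity_score(query, profile)
                p = permutation_p(
                    (res.n_matched_up, res.n_matched_down),
                    profile,
                    res.score,
                    n_perm=n_perm,
                    seed=cell_seed,
                )
                rows.append(
                    (
                        query.name, pname, res.score, res.es_up, res.es_down,
                        p, res.n_matched_up, res.n_matched_down, "",
                    )
                )
            except ValueError as exc:
                rows.append(
                    (
                        query.name, pname, np.nan, np.nan, np.nan,
                        np.nan, 0, 0, str(exc),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "query", "profile", "score", "es_up", "es_down", "p",
            "n_matched_up", "n_matched_down", "note",
        ],
    )
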