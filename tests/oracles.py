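"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each statistic from its definition with
plain Python loops, sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def ks_tag_brute(positions, n: int) -> float:
    """Bidirectional KS tag score by direct enumeration of j.

    ``positions`` are the sorted 1-based ranks of the matched tags.
    """
    V = sorted(positions)
    t = len(V)
    a = max(j / t - V[j - 1] / n for j in range(1, t + 1))
    b = max(V[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a >= b else -b


def es_brute(genes, stats, members, weight: float):
    """Enrichment score by stepwise running-sum accumulation.

    Walks the ranking one gene at a time, tracking the hit and miss
    cumulative fractions, and returns the signed deviation of maximal
    magnitude (positive preferred on exact ties) plus the leading edge.
    """
    members = set(members)
    n = len(genes)
    hits = [g in members for g in genes]
    n_hit = sum(hits)
    n_miss = n - n_hit
    denom = sum(abs(s) ** weight for g, s in zip(genes, stats) if g in members)
    equal_steps = denom == 0
    p_hit = 0.0
    p_miss = 0.0
    best = 0.0
    best_i = -1
    devs = []
    for i, (g, s) in enumerate(zip(genes, stats)):
        if hits[i]:
            p_hit += 1.0 / n_hit if equal_steps else abs(s) ** weight / denom
        else:
            p_miss += 1.0 / n_miss
        devs.append(p_hit - p_miss)
    dev_max = max(devs)
    dev_min = min(devs)
    i_max = next(i for i in range(n) if devs[i] >= dev_max - 1e-12)
    i_min = next(i for i in range(n) if devs[i] <= dev_min + 1e-12)
    if devs[i_max] >= -devs[i_min] - 1e-12:  # positive wins ties
        es = devs[i_max]
        leading = [g for i, g in enumerate(genes) if i <= i_max and hits[i]]
    else:
        es = devs[i_min]
        leading = [g for i, g in enumerate(genes) if i > i_min and hits[i]]
    return es, leading


def bh_brute(pvals):
    """Benjamini-Hochberg by the textbook step-up rule."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def size_factors_brute(values: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors from first principles."""
    geo = np.exp(np.mean(np.log(np.where(values > 0, values, np.nan)), axis=1))
    # genes with any zero have undefined log geometric mean -> excluded
    ok = np.all(values > 0, axis=1)
    ratios = values[ok] / geo[ok][:, None]
    f = np.median(ratios, axis=0)
    return f / np.exp(np.mean(np.log(f)))
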