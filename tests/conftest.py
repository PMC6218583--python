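import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from txsig import CountMatrix, DEResult


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 genes x 6 samples, two conditions, simple structure."""
    counts = pd.DataFrame(
        {
            "s1": [10, 100, 7], "s2": [12, 110, 8], "s3": [11, 90, 6],
            "t1": [40, 100, 7], "t2": [44, 95, 9], "t3": [38, 105, 8],
        },
        index=["gA", "gB", "gC"],
    )
    cond = pd.Series(
        ["ctrl", "ctrl", "ctrl", "treat", "treat", "treat"],
        index=counts.columns,
    )
    return CountMatrix(counts, cond)


@pytest.fixture
def nb_matrix():
    """Factory: NB count matrix with optional planted fold change."""

    def make(n_genes=200, n_reps=3, mean=500.0, dispersion=0.05,
             planted=(), log2fc=1.5, seed=0) -> CountMatrix:
        rng = np.random.default_rng(seed)
        genes = [f"g{i:04d}" for i in range(n_genes)]
        samples = [f"c{r}" for r in range(n_reps)] + [f"t{r}" for r in range(n_reps)]
        mu = np.full((n_genes, 2 * n_reps), mean)
        for g in planted:
            mu[genes.index(g), n_reps:] *= 2.0 ** log2fc
        r = 1.0 / dispersion
        values = rng.negative_binomial(r, r / (r + mu))
        cond = pd.Series(["ctrl"] * n_reps + ["treat"] * n_reps, index=samples)
        return CountMatrix(pd.DataFrame(values, index=genes, columns=samples), cond)

    return make


@pytest.fixture
def de_from_stats():
    """Factory: a DEResult with prescribed per-gene columns."""

    def make(genes, stats, fdr=None, p=None, log2fc=None,
             condition="treat", control="ctrl") -> DEResult:
        n = len(genes)
        stats = np.asarray(stats, dtype=float)
        table = pd.DataFrame(
            {
                "log2fc": stats if log2fc is None else np.asarray(log2fc, float),
                "stat": stats,
                "p": np.full(n, 0.5) if p is None else np.asarray(p, float),
                "fdr": np.full(n, 0.5) if fdr is None else np.asarray(fdr, float),
            },
            index=list(genes),
        )
        return DEResult(condition=condition, control=control, table=table)

    return make
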