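"""Synthetic RNA-seq experiment generator with known planted truth.

Emulates a five-condition count experiment — one shared control plus four
transcription-factor overexpression conditions in triplicate — together
with gene-set collections and reference ranked profiles, so that every
downstream stage (differential ranking, common-signature intersection,
pre-ranked enrichment, connectivity scoring) can be tested against exact
bookkeeping of what was planted.

Counts are negative binomial with a shared dispersion; baseline gene means
are log-normal across genes (a realistic dynamic range) and each sample
carries a log-normal library-size factor.  Planted genes have their mean
multiplied by 2^(+-base_log2fc) in the affected condition(s): a core of
shared up/down genes perturbed identically in all overexpression
conditions, plus per-condition specific genes.  The generator does not
attempt read-level data, batch effects or isoform structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection, RankedProfile

__all__ = ["SimConfig", "SimTruth", "generate_counts", "generate_gene_sets",
           "generate_reference_profile", "write_truth"]


@dataclass
class SimConfig:
    """Parameters of the synthetic count experiment.

    Defaults echo the emulated study's scale — 13,716 genes surviving
    count filtering, four overexpression conditions in triplicate, and a
    shared core of 112 up- / 163 down-regulated genes — as friendly
    defaults, not as ground truth to reproduce.

    ``mean_log_mu`` / ``sd_log_mu`` parameterize the natural-log-normal
    baseline means.  The default median of ~400 counts per gene
    corresponds to libraries of a few to ten million assigned reads over
    ~14k genes — ordinary bulk RNA-seq depth — and keeps essentially the
    whole simulated universe above the low-count filter, consistent with
    the gene count here being the *post-filter* universe.  ``dispersion``
    is the NB dispersion alpha in var = mu + alpha mu^2;
    ``library_size_spread`` is the standard deviation of the log-normal
    per-sample library factors.
    """

    n_genes: int = 13716
    n_conditions: int = 4
    n_reps: int = 3
    n_shared_up: int = 112
    n_shared_down: int = 163
    n_specific: int = 50
    base_log2fc: float = 1.5
    mean_log_mu: float = 6.0
    sd_log_mu: float = 1.0
    dispersion: float = 0.05
    library_size_spread: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_conditions <= 0 or self.n_reps <= 0:
            raise ValueError("n_genes, n_conditions and n_reps must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.library_size_spread <= 0:
            raise ValueError("library_size_spread must be positive")
        if min(self.n_shared_up, self.n_shared_down, self.n_specific) < 0:
            raise ValueError("planted counts must be non-negative")
        total = (
            self.n_shared_up
            + self.n_shared_down
            + self.n_specific * self.n_conditions
        )
        if total > self.n_genes:
            raise ValueError(
                f"infeasible planting: {total} planted genes exceed "
                f"{self.n_genes} genes"
            )

    @property
    def conditions(self) -> list[str]:
        return [f"OE{i + 1}" for i in range(self.n_conditions)]

    @property
    def control(self) -> str:
        return "control"


@dataclass
class SimTruth:
    """Exact record of everything the generator planted."""

    shared_up: frozenset
    shared_down: frozenset
    specific: dict  # condition -> (up frozenset, down frozenset)
    base_log2fc: float
    dispersion: float
    perturbed_sets_up: list = field(default_factory=list)
    perturbed_sets_down: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shared_up & self.shared_down:
            raise ValueError("shared up/down planted sets overlap")

    def planted_for(self, condition: str):
        """(up, down) planted gene sets affecting one condition."""
        su, sd = self.specific.get(condition, (frozenset(), frozenset()))
        return self.shared_up | su, self.shared_down | sd

    @property
    def all_planted(self) -> frozenset:
        out = set(self.shared_up) | set(self.shared_down)
        for up, down in self.specific.values():
            out |= up | down
        return frozenset(out)


def _gene_ids(n: int) -> list:
    width = len(str(n))
    return [f"G{str(i).zfill(width)}" for i in range(1, n + 1)]


def generate_counts(config: SimConfig):
    """Simulate the count matrix and its planted truth.

    Returns ``(CountMatrix, SimTruth)``.  Same config and seed give
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    conditions = [config.control] + config.conditions
    samples, labels = [], []
    for cond in conditions:
        for r in range(1, config.n_reps + 1):
            samples.append(f"{cond}_r{r}")
            labels.append(cond)

    # plant disjoint gene blocks: shared core first, then per-condition extras
    perm = rng.permutation(config.n_genes)
    cursor = 0

    def take(k: int) -> frozenset:
        nonlocal cursor
        block = frozenset(genes[i] for i in perm[cursor: cursor + k])
        cursor += k
        return block

    shared_up = take(config.n_shared_up)
    shared_down = take(config.n_shared_down)
    specific = {}
    for cond in config.conditions:
        n_up = config.n_specific // 2
        n_down = config.n_specific - n_up
        specific[cond] = (take(n_up), take(n_down))

    truth = SimTruth(
        shared_up=shared_up,
        shared_down=shared_down,
        specific=specific,
        base_log2fc=config.base_log2fc,
        dispersion=config.dispersion,
    )

    mu = rng.lognormal(config.mean_log_mu, config.sd_log_mu, size=config.n_genes)
    lib = rng.lognormal(0.0, config.library_size_spread, size=len(samples))

    gene_index = {g: i for i, g in enumerate(genes)}
    fold = np.ones((config.n_genes, len(conditions)))
    up_mult = 2.0 ** config.base_log2fc
    down_mult = 2.0 ** (-config.base_log2fc)
    for c, cond in enumerate(conditions):
        if cond == config.control:
            continue
        up, down = truth.planted_for(cond)
        fold[[gene_index[g] for g in sorted(up)], c] = up_mult
        fold[[gene_index[g] for g in sorted(down)], c] = down_mult

    cond_of_sample = np.array([conditions.index(l) for l in labels])
    mean = mu[:, None] * fold[:, cond_of_sample] * lib[None, :]
    r = 1.0 / config.dispersion  # NB size parameter
    p = r / (r + mean)
    values = rng.negative_binomial(r, p)

    cm = CountMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.Series(labels, index=samples),
    )
    return cm, truth


def generate_gene_sets(
    truth: SimTruth,
    universe: Sequence[str],
    n_down_sets: int = 24,
    n_null_sets: int = 25,
    set_min: int = 15,
    set_max: int = 250,
    planted_size_range: tuple = (15, 120),
    signal_frac: float = 0.5,
    max_signal: int = 40,
    near_duplicate: bool = False,
    overlap_threshold: float = 0.5,
    seed=None,
) -> GeneSetCollection:
    """Build a gene-set collection with planted enrichment structure.

    Emits one set enriched in the shared up-regulated genes, ``n_down_sets``
    sets enriched in the shared down-regulated genes, ``n_null_sets`` sets
    of random unperturbed genes and, optionally, a near-duplicate of one
    null set (Jaccard >= ``overlap_threshold``) to exercise redundancy
    pruning.  All set sizes fall inside [set_min, set_max].  Planted-set
    names are recorded in ``truth.perturbed_sets_up`` / ``_down``.

    Null sets draw from the unperturbed part of the universe only: planted
    genes sit at the extreme ends of every contrast ranking, so a "null"
    set containing them would be consistently enriched by construction.

    Without the near-duplicate, the signal cap keeps every pairwise
    Jaccard index below ``overlap_threshold`` (asserted).
    """
    universe = list(universe)
    if not set(truth.all_planted) <= set(universe):
        raise ValueError("planted truth genes must be contained in the universe")
    pool_up = sorted(truth.shared_up & set(universe))
    pool_down = sorted(truth.shared_down & set(universe))
    background = sorted(set(universe) - truth.all_planted)
    lo, hi = planted_size_range
    lo = max(lo, set_min)
    hi = min(hi, set_max)
    if len(background) < set_max:
        raise ValueError(
            f"universe too small: need >= {set_max} unperturbed genes, "
            f"have {len(background)}"
        )
    rng = np.random.default_rng(seed)
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    truth.perturbed_sets_up = []
    truth.perturbed_sets_down = []

    def planted_set(pool: list) -> frozenset:
        size = int(rng.integers(lo, hi + 1))
        n_sig = min(max(int(round(signal_frac * size)), min(5, len(pool))),
                    max_signal, len(pool), size)
        sig = rng.choice(len(pool), size=n_sig, replace=False)
        filler = rng.choice(len(background), size=size - n_sig, replace=False)
        return frozenset([pool[i] for i in sig] + [background[i] for i in filler])

    if pool_up:
        name = "PW_UP_01"
        sets[name] = planted_set(pool_up)
        descriptions[name] = "planted up-regulated pathway"
        truth.perturbed_sets_up.append(name)
    for k in range(1, n_down_sets + 1):
        name = f"PW_DOWN_{k:02d}"
        sets[name] = planted_set(pool_down)
        descriptions[name] = "planted down-regulated pathway"
        truth.perturbed_sets_down.append(name)
    for k in range(1, n_null_sets + 1):
        name = f"PW_NULL_{k:02d}"
        size = int(rng.integers(set_min, set_max + 1))
        idx = rng.choice(len(background), size=size, replace=False)
        sets[name] = frozenset(background[i] for i in idx)
        descriptions[name] = "random null pathway"
    if near_duplicate:
        if not any(n.startswith("PW_NULL_") for n in sets):
            raise ValueError("near-duplicate requires at least one null set")
        src = "PW_NULL_01"
        members = sorted(sets[src])
        n_swap = max(1, len(members) // 5)
        drop = set(rng.choice(len(members), size=n_swap, replace=False))
        kept = [m for i, m in enumerate(members) if i not in drop]
        extra_pool = [g for g in background if g not in sets[src]]
        add = rng.choice(len(extra_pool), size=n_swap, replace=False)
        dup = frozenset(kept + [extra_pool[i] for i in add])
        sets["PW_NULL_01_DUP"] = dup
        descriptions["PW_NULL_01_DUP"] = f"near-duplicate of {src}"

    if not near_duplicate:
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = len(sets[a] & sets[b])
                union = len(sets[a] | sets[b])
                if union and inter / union >= overlap_threshold:
                    raise AssertionError(
                        f"generated sets {a} and {b} exceed the overlap "
                        "threshold; reduce signal_frac or set sizes"
                    )
    return GeneSetCollection(sets, descriptions)


def generate_reference_profile(
    truth: SimTruth,
    universe: Sequence[str],
    mode: str,
    noise_sd: float = 1.0,
    seed=None,
    signal: float = 3.0,
) -> RankedProfile:
    """Reference ranked profile mimicking, reversing or ignoring the truth.

    Every universe gene receives statistic = signal + Gaussian noise.  In
    ``mimic`` mode the shared up-regulated genes get +``signal`` and the
    shared down-regulated genes -``signal`` (a treatment-like profile);
    ``reverse`` negates the whole statistic vector (a tumor-vs-normal-like
    profile, exactly the mirror of ``mimic`` under the same seed); ``null``
    is pure noise.
    """
    if mode not in ("mimic", "reverse", "null"):
        raise ValueError(f"unknown mode {mode!r}; expected mimic/reverse/null")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    universe = list(universe)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(universe))
    base = np.zeros(len(universe))
    if mode != "null":
        up = truth.shared_up
        down = truth.shared_down
        for i, g in enumerate(universe):
            if g in up:
                base[i] = signal
            elif g in down:
                base[i] = -signal
    stats = base + noise
    if mode == "reverse":
        stats = -stats
    return RankedProfile.from_unsorted(universe, stats)


def write_truth(truth: SimTruth, path) -> None:
    """Write the planted truth as a (name, kind, role) TSV for harnesses."""
    rows = []
    for g in sorted(truth.shared_up):
        rows.append((g, "gene", "shared_up"))
    for g in sorted(truth.shared_down):
        rows.append((g, "gene", "shared_down"))
    for cond in sorted(truth.specific):
        up, down = truth.specific[cond]
        for g in sorted(up):
            rows.append((g, "gene", f"specific_up_{cond}"))
        for g in sorted(down):
            rows.append((g, "gene", f"specific_down_{cond}"))
    for s in truth.perturbed_sets_up:
        rows.append((s, "set", "perturbed_up"))
    for s in truth.perturbed_sets_down:
        rows.append((s, "set", "perturbed_down"))
    pd.DataFrame(rows, columns=["name", "kind", "role"]).to_csv(
        path, sep="\t", index=False
    )
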