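"""End-to-end orchestration of the in-silico analysis.

One call runs the whole chain — simulate (or accept) counts, filter, rank
by the NB Wald statistic per contrast, call and intersect DEGs, extract
75/75 query signatures, run pre-ranked enrichment with redundancy pruning
and cross-contrast consistency selection, and score the query signatures
against mimic / reverse / null reference profiles.

Everything is a pure function of (inputs, configuration, seed): stage
seeds are spawned from the single master seed, so repeated runs write
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import connectivity_panel
from .containers import CountMatrix, GeneSetCollection, RankedProfile
from .diffexpr import differential_test, estimate_size_factors, filter_low_counts
from .gsea import (
    consistent_pathways,
    enrich_collection,
    filter_gene_sets,
    leading_edge_common,
    remove_redundant,
)
from .io import (
    RunConfig,
    write_count_matrix,
    write_de_table,
    write_gmt,
    write_ranked_profile,
    write_signature,
)
from .signature import (
    annotate_overlap,
    call_degs,
    extract_query_signature,
    intersect_common,
)
from .simulate import (
    SimConfig,
    SimTruth,
    generate_counts,
    generate_gene_sets,
    generate_reference_profile,
    write_truth,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_simulated_pipeline", "analyze_counts"]

#: consistent pathways kept after ranking by mean |NES| (display budget)
CONSISTENT_TOP_N = 25


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    counts: CountMatrix
    filtered: CountMatrix
    truth: SimTruth | None
    de: dict                      # contrast -> DEResult
    calls: dict                   # contrast -> (up, down)
    common: object                # CommonSignature
    signatures: dict              # contrast -> GeneSignature
    collection: GeneSetCollection
    enrichment: dict              # contrast -> DataFrame
    pruned: dict                  # contrast -> DataFrame (post redundancy)
    consistent: pd.DataFrame
    leading_edge: pd.DataFrame
    reference_profiles: dict      # name -> RankedProfile
    connectivity: pd.DataFrame
    overlap_report: pd.DataFrame | None = None


def _seed_int(child: np.random.SeedSequence) -> int:
    return int(child.generate_state(1)[0] % (2 ** 31))


def analyze_counts(
    counts: CountMatrix,
    control: str,
    collection: GeneSetCollection,
    reference_profiles: Mapping[str, RankedProfile],
    run: RunConfig,
    truth: SimTruth | None = None,
    annotation: Mapping[str, str] | None = None,
    seed_sequence: np.random.SeedSequence | None = None,
) -> PipelineResult:
    """Run every analysis stage on an existing count matrix.

    ``control`` names the reference condition; every other condition label
    becomes one contrast.  ``reference_profiles`` maps profile names to
    ranked profiles for the connectivity stage.
    """
    ss = seed_sequence or np.random.SeedSequence(run.seed)
    conditions = [c for c in counts.condition_labels() if c != control]
    if not conditions:
        raise ValueError(f"no condition other than control {control!r}")
    n_children = len(conditions) + 2
    children = ss.spawn(n_children)
    gsea_seeds = children[:len(conditions)]
    conn_seed, _spare = children[len(conditions):]

    filtered = filter_low_counts(counts)
    logger.info("%d / %d genes pass the low-count filter",
                filtered.n_genes, counts.n_genes)
    size_factors = estimate_size_factors(filtered)

    de, calls, signatures, enrichment = {}, {}, {}, {}
    universe = filtered.gene_ids
    sets = filter_gene_sets(collection, universe, run.set_min, run.set_max)
    for cond, gsea_seed in zip(conditions, gsea_seeds):
        result = differential_test(filtered, cond, control, size_factors=size_factors)
        contrast = result.name
        de[contrast] = result
        calls[contrast] = call_degs(result, fdr_threshold=run.fdr_deg)
        signatures[contrast] = extract_query_signature(result, k=run.signature_k)
        enrichment[contrast] = enrich_collection(
            result.ranked_profile(), sets,
            n_perm=run.n_perm, seed=gsea_seed, weight=run.gsea_weight,
        )
    common = intersect_common(calls)
    logger.info("common signature: %d up, %d down", len(common.up), len(common.down))

    pruned = remove_redundant(enrichment, sets, overlap_threshold=run.overlap_threshold)
    consistent = consistent_pathways(
        pruned, fdr_threshold=run.fdr_pathway, top_n=CONSISTENT_TOP_N
    )
    leading = leading_edge_common(consistent, pruned, common)

    panel = connectivity_panel(
        list(signatures.values()), dict(reference_profiles),
        n_perm=run.n_perm, seed=conn_seed,
    )

    overlap = None
    if annotation is not None:
        overlap = annotate_overlap(
            sorted(common.up), sorted(common.down), annotation
        )

    return PipelineResult(
        counts=counts, filtered=filtered, truth=truth,
        de=de, calls=calls, common=common, signatures=signatures,
        collection=sets, enrichment=enrichment, pruned=pruned,
        consistent=consistent, leading_edge=leading,
        reference_profiles=dict(reference_profiles), connectivity=panel,
        overlap_report=overlap,
    )


def run_simulated_pipeline(
    run: RunConfig,
    sim: SimConfig | None = None,
    outdir=None,
    annotation: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Simulate a five-condition experiment and analyze it end to end.

    The master seed in ``run`` drives simulation and analysis alike; the
    ``seed`` field of ``sim`` is overridden so the whole run is a function
    of the run configuration only.  When ``outdir`` is given, every stage
    output is written there as TSV/GMT plus a plain-text log.
    """
    sim = sim or SimConfig()
    ss = np.random.SeedSequence(run.seed)
    sim_seed, sets_seed, prof_seed, analysis_seed = ss.spawn(4)
    sim = dataclasses.replace(sim, seed=_seed_int(sim_seed))
    counts, truth = generate_counts(sim)

    # gene sets and reference profiles live on the post-filter universe
    filtered_preview = filter_low_counts(counts)
    universe = filtered_preview.gene_ids
    truth_universe = set(universe) | set(truth.all_planted)
    collection = generate_gene_sets(
        truth, sorted(truth_universe),
        set_min=run.set_min, set_max=run.set_max,
        overlap_threshold=run.overlap_threshold, seed=sets_seed,
    )
    mimic_seed, reverse_seed, null_seed = prof_seed.spawn(3)
    profiles = {
        "mimic": generate_reference_profile(
            truth, universe, "mimic", seed=mimic_seed),
        "reverse": generate_reference_profile(
            truth, universe, "reverse", seed=reverse_seed),
        "null": generate_reference_profile(
            truth, universe, "null", seed=null_seed),
    }

    result = analyze_counts(
        counts, sim.control, collection, profiles, run,
        truth=truth, annotation=annotation, seed_sequence=analysis_seed,
    )

    if outdir is not None:
        write_outputs(result, run, sim, Path(outdir))
    return result


def write_outputs(result: PipelineResult, run: RunConfig,
                  sim: SimConfig | None, outdir: Path) -> None:
    """Write every stage output of a pipeline run under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_matrix(result.counts, outdir / "counts.tsv", outdir / "conditions.tsv")
    if result.truth is not None:
        write_truth(result.truth, outdir / "truth.tsv")
    write_gmt(result.collection, outdir / "gene_sets.gmt")
    for contrast, de in result.de.items():
        write_de_table(de.table, outdir / f"de_{contrast}.tsv")
        write_ranked_profile(de.ranked_profile(), outdir / f"ranked_{contrast}.tsv")
        stats = de.table["stat"].to_dict()
        write_signature(result.signatures[contrast],
                        outdir / f"signature_{contrast}.tsv", stats=stats)
        enr = result.enrichment[contrast].copy()
        enr["leading_edge"] = [",".join(le) for le in enr["leading_edge"]]
        enr.to_csv(outdir / f"enrichment_{contrast}.tsv", sep="\t")
    common_rows = [(g, "up") for g in sorted(result.common.up)]
    common_rows += [(g, "down") for g in sorted(result.common.down)]
    pd.DataFrame(common_rows, columns=["gene", "direction"]).to_csv(
        outdir / "common_signature.tsv", sep="\t", index=False)
    result.consistent.to_csv(outdir / "consistent_pathways.tsv", sep="\t")
    result.leading_edge.to_csv(outdir / "leading_edge.tsv", sep="\t", index=False)
    for name, profile in result.reference_profiles.items():
        write_ranked_profile(profile, outdir / f"ref_{name}.tsv")
    result.connectivity.to_csv(outdir / "connectivity.tsv", sep="\t", index=False)
    if result.overlap_report is not None:
        result.overlap_report.to_csv(outdir / "overlap_report.tsv", sep="\t", index=False)
    run.to_yaml(outdir / "run_config.yaml")
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"txsig {__version__}\n")
        fh.write(f"python {platform.python_version()}\n")
        fh.write(f"numpy {np.__version__}\npandas {pd.__version__}\n")
        fh.write(f"seed {run.seed}\n")
        for k, v in dataclasses.asdict(run).items():
            fh.write(f"run.{k} = {v}\n")
        if sim is not None:
            for k, v in dataclasses.asdict(sim).items():
                fh.write(f"sim.{k} = {v}\n")
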