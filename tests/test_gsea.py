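"""Enrichment running sum vs brute-force oracle, permutation NES,
redundancy pruning, consistency selection and leading-edge extraction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import es_brute
from txsig import (
    GeneSetCollection,
    RankedProfile,
    consistent_pathways,
    display_score,
    enrich_collection,
    enrichment_score,
    filter_gene_sets,
    leading_edge_common,
    permutation_nes,
    remove_redundant,
)
from txsig.gsea import _es_from_positions
from txsig.signature import CommonSignature


def profile_of(stats, prefix="g"):
    genes = [f"{prefix}{i:04d}" for i in range(len(stats))]
    return RankedProfile.from_unsorted(genes, stats)


class TestEnrichmentScore:
    def test_unweighted_top_block_saturates(self):
        prof = profile_of(np.arange(10, 0, -1, dtype=float))
        es, leading = enrichment_score(prof, set(prof.genes[:3]), weight=0.0)
        assert es == pytest.approx(1.0)
        assert leading == list(prof.genes[:3])

    def test_weighted_worked_example(self):
        prof = profile_of([5, 4, 3, 2, 1, -1, -2, -3, -4, -5])
        hits = {prof.genes[0], prof.genes[3]}
        es, _ = enrichment_score(prof, hits, weight=1.0)
        assert es == pytest.approx(0.75)  # (5+2)/7 - 2/8 at rank 4

    def test_bottom_block_negative_with_bottom_leading_edge(self):
        prof = profile_of(np.arange(10, 0, -1, dtype=float))
        bottom = set(prof.genes[-3:])
        es, leading = enrichment_score(prof, bottom, weight=0.0)
        assert es < 0
        assert set(leading) == bottom

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_exhaustive_small_instances_match_oracle(self, weight):
        rng = np.random.default_rng(7)
        for n in range(3, 13):
            stats = np.sort(rng.normal(0, 2, n))[::-1]
            prof = profile_of(stats)
            for t in range(1, min(4, n - 1) + 1):
                for members in itertools.combinations(prof.genes, t):
                    es, leading = enrichment_score(prof, set(members), weight)
                    ref_es, ref_lead = es_brute(
                        prof.genes, prof.stats, members, weight
                    )
                    assert es == pytest.approx(ref_es, abs=1e-12)
                    if abs(es) > 1e-9:  # extremum well-defined
                        assert leading == ref_lead

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_random_large_instances_match_oracle(self, weight):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(100, 1000))
            stats = rng.normal(0, 2, n)
            prof = profile_of(stats)
            t = int(rng.integers(5, 50))
            members = set(rng.choice(prof.genes, size=t, replace=False))
            es, _ = enrichment_score(prof, members, weight)
            ref, _ = es_brute(prof.genes, prof.stats, members, weight)
            assert es == pytest.approx(ref, abs=1e-12)
            assert -1.0 <= es <= 1.0

    def test_unweighted_negation_symmetry(self):
        rng = np.random.default_rng(13)
        checked = 0
        for _ in range(200):
            if checked >= 100:
                break
            n = int(rng.integers(20, 200))
            stats = rng.normal(0, 1, n)
            prof = profile_of(stats)
            members = set(rng.choice(prof.genes, size=5, replace=False))
            # with weight 0 the step sizes are rational, so the positive
            # and negative extrema can tie exactly; the tie rule then
            # deliberately breaks the symmetry -> skip those instances
            hit = np.array([g in members for g in prof.genes])
            dev = np.cumsum(np.where(hit, 1 / hit.sum(), 0.0)) - np.cumsum(~hit) / (~hit).sum()
            if abs(dev.max() + dev.min()) < 1e-9:
                continue
            es_fwd, _ = enrichment_score(prof, members, weight=0.0)
            es_rev, _ = enrichment_score(prof.reversed(), members, weight=0.0)
            assert es_fwd == pytest.approx(-es_rev, abs=1e-12)
            checked += 1
        assert checked >= 80

    def test_degenerate_sets_rejected(self):
        prof = profile_of([3.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            enrichment_score(prof, set(), weight=1.0)
        with pytest.raises(ValueError):
            enrichment_score(prof, set(prof.genes), weight=1.0)

    def test_fast_path_equals_reference_path(self):
        rng = np.random.default_rng(17)
        n = 400
        prof = profile_of(rng.normal(0, 2, n))
        w = np.abs(prof.stats_array())
        pos_to_gene = np.array(prof.genes, dtype=object)
        for t in (5, 20, 80):
            pos = np.sort(
                np.stack([rng.choice(n, size=t, replace=False) for _ in range(50)]),
                axis=1,
            )
            fast = _es_from_positions(pos, w, n)
            for row, es_fast in zip(pos, fast):
                es_ref, _ = enrichment_score(prof, set(pos_to_gene[row]), 1.0)
                assert es_fast == pytest.approx(es_ref, abs=1e-12)

    def test_matches_gseapy_prerank(self):
        """Independent cross-check against gseapy's pre-ranked ES."""
        import gseapy

        rng = np.random.default_rng(3)
        prof = profile_of(np.round(rng.normal(0, 2, 200), 4))
        sets = {
            f"S{k}": list(rng.choice(prof.genes, size=25, replace=False))
            for k in range(5)
        }
        rnk = pd.DataFrame({"gene": prof.genes, "stat": prof.stats})
        res = gseapy.prerank(
            rnk=rnk, gene_sets=sets, permutation_num=10, min_size=5,
            max_size=100, weight=1.0, seed=1, outdir=None, no_plot=True,
        ).res2d
        for name, members in sets.items():
            mine, _ = enrichment_score(prof, members, weight=1.0)
            theirs = float(res.loc[res.Term == name, "ES"].iloc[0])
            assert mine == pytest.approx(theirs, abs=1e-9)


class TestFilterGeneSets:
    def test_size_bounds_inclusive_on_effective_size(self):
        universe = [f"g{i}" for i in range(400)]
        coll = GeneSetCollection(
            {
                "too_small": set(universe[:14]),
                "at_min": set(universe[:15]),
                "at_max": set(universe[:250]),
                "raw_large_effective_ok": set(universe[100:300]) | {"alien%d" % i for i in range(100)},
                "too_large": set(universe[:251]),
            }
        )
        kept = filter_gene_sets(coll, universe, 15, 250)
        assert set(kept.names) == {"at_min", "at_max", "raw_large_effective_ok"}
        assert len(kept["raw_large_effective_ok"]) == 200

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            filter_gene_sets(GeneSetCollection({}), [], 15, 250)


class TestPermutationNES:
    def test_zero_es_gives_null_result(self):
        # symmetric profile, set at exact alternating positions -> tiny es,
        # but build the exact-zero case directly: set with all-zero stats
        prof = profile_of([1.0, 0.0, 0.0, -1.0])
        es, _ = enrichment_score(prof, {prof.genes[1], prof.genes[2]}, 1.0)
        nes, p, _ = permutation_nes(
            prof, {prof.genes[1], prof.genes[2]}, n_perm=100, seed=0, weight=1.0
        )
        if es == 0.0:
            assert nes == 0.0 and p == 1.0

    def test_top_block_attains_minimum_p(self):
        prof = profile_of(np.arange(500, 0, -1, dtype=float))
        members = set(prof.genes[:20])
        nes, p, null = permutation_nes(prof, members, n_perm=1000, seed=1,
                                       weight=0.0)
        same_sign = int((null > 0).sum())
        assert p == pytest.approx(1.0 / (1 + same_sign))
        assert nes > 1.0

    def test_sign_consistency_and_determinism(self):
        rng = np.random.default_rng(5)
        prof = profile_of(rng.normal(0, 1, 300))
        members = set(rng.choice(prof.genes, 25, replace=False))
        es, _ = enrichment_score(prof, members, 1.0)
        r1 = permutation_nes(prof, members, n_perm=200, seed=9)
        r2 = permutation_nes(prof, members, n_perm=200, seed=9)
        assert r1[0] == r2[0] and r1[1] == r2[1]
        if es != 0:
            assert np.sign(r1[0]) == np.sign(es)

    def test_planted_set_significant_across_seeds(self):
        """A top-loaded set in a 500-gene profile reaches p < 0.01 in at
        least 99 of 100 permutation seeds."""
        rng = np.random.default_rng(2)
        prof = profile_of(np.sort(rng.normal(0, 1, 500))[::-1])
        members = set(prof.genes[:15])
        hits = 0
        for seed in range(100):
            _, p, _ = permutation_nes(prof, members, n_perm=1000, seed=seed)
            hits += p < 0.01
        assert hits >= 99

    def test_null_pvalues_superuniform(self):
        """Type-I error of the permutation p at alpha=0.05 stays within
        the binomial 95% envelope over 200 random null sets."""
        rng = np.random.default_rng(21)
        prof = profile_of(rng.normal(0, 1, 800))
        rejected = 0
        for i in range(200):
            t = int(rng.integers(10, 40))
            members = set(rng.choice(prof.genes, t, replace=False))
            _, p, _ = permutation_nes(prof, members, n_perm=199, seed=1000 + i)
            rejected += p < 0.05
        from scipy.stats import binom
        lo, hi = binom.ppf([0.025, 0.975], 200, 0.05)
        assert lo <= rejected <= hi


class TestRedundancyAndConsistency:
    def _tables(self, data, contrasts=("c1",)):
        # data: dict set -> (es, nes, p, fdr)
        out = {}
        for c in contrasts:
            rows = {
                name: dict(es=v[0], nes=v[1], p=v[2], fdr=v[3], size=20,
                           leading_edge=())
                for name, v in data.items()
            }
            out[c] = pd.DataFrame(rows).T[["es", "nes", "p", "fdr", "size",
                                           "leading_edge"]]
        return out

    def test_identical_sets_keep_better_p(self):
        coll = GeneSetCollection({"A": {"x", "y", "z"}, "B": {"x", "y", "z"}})
        tables = self._tables({"A": (0.5, 1.5, 0.01, 0.02),
                               "B": (0.5, 1.4, 0.02, 0.03)})
        pruned = remove_redundant(tables, coll, 0.5)
        assert list(pruned["c1"].index) == ["A"]

    def test_disjoint_sets_both_survive(self):
        coll = GeneSetCollection({"A": {"x", "y"}, "B": {"u", "v"}})
        tables = self._tables({"A": (0.5, 1.5, 0.01, 0.02),
                               "B": (0.4, 1.2, 0.03, 0.04)})
        pruned = remove_redundant(tables, coll, 0.5)
        assert set(pruned["c1"].index) == {"A", "B"}

    def test_greedy_trace_matches_hand_run(self):
        # Jaccard(A,B)=2/6=0.33, Jaccard(A,C)=3/5=0.6, Jaccard(B,D)=4/4=1,
        # Jaccard(A,E)=0; visit order by p: A(0.001), B(0.002), C(0.003),
        # D(0.004), E(0.005) -> accept A, B (0.33<0.5), reject C (0.6 vs A),
        # reject D (1.0 vs B), accept E.
        coll = GeneSetCollection(
            {
                "A": {"1", "2", "3", "4"},
                "B": {"3", "4", "5", "6"},
                "C": {"1", "2", "3"},
                "D": {"3", "4", "5", "6"},
                "E": {"7", "8"},
            }
        )
        tables = self._tables(
            {
                "A": (0.5, 1.5, 0.001, 0.01),
                "B": (0.5, 1.5, 0.002, 0.01),
                "C": (0.5, 1.5, 0.003, 0.01),
                "D": (0.5, 1.5, 0.004, 0.01),
                "E": (0.5, 1.5, 0.005, 0.01),
            }
        )
        pruned = remove_redundant(tables, coll, 0.5)
        assert set(pruned["c1"].index) == {"A", "B", "E"}

    def test_pruned_output_jaccard_below_threshold(self):
        rng = np.random.default_rng(23)
        pool = [f"g{i}" for i in range(120)]
        sets = {
            f"S{k}": frozenset(rng.choice(pool, size=20, replace=False))
            for k in range(15)
        }
        coll = GeneSetCollection(dict(sets))
        data = {name: (0.5, 1.0, float(rng.uniform(0, 1)), 0.5)
                for name in sets}
        pruned = remove_redundant(self._tables(data), coll, 0.3)
        names = list(pruned["c1"].index)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                jac = len(coll[a] & coll[b]) / len(coll[a] | coll[b])
                assert jac < 0.3

    def test_consistency_rules(self):
        contrasts = ("c1", "c2", "c3", "c4")
        data = {}
        tables = {c: [] for c in contrasts}
        rows = {
            "all_up": ([1.2, 1.1, 1.3, 1.0], [0.01] * 4),
            "flip": ([1.2, 1.1, 1.3, -1.0], [0.01] * 4),
            "weak_fdr": ([1.2, 1.1, 1.3, 1.0], [0.01, 0.01, 0.2, 0.01]),
            "all_down": ([-2.0, -2.1, -1.9, -2.2], [0.01] * 4),
        }
        per_contrast = {}
        for i, c in enumerate(contrasts):
            per_contrast[c] = pd.DataFrame(
                {
                    name: dict(
                        es=np.sign(nes[i]) * 0.5, nes=nes[i], p=0.005,
                        fdr=fdr[i], size=20, leading_edge=(),
                    )
                    for name, (nes, fdr) in rows.items()
                }
            ).T[["es", "nes", "p", "fdr", "size", "leading_edge"]]
        out = consistent_pathways(per_contrast, fdr_threshold=0.1, top_n=25)
        assert list(out.index) == ["all_down", "all_up"]  # by mean |nes|
        assert out.loc["all_down", "direction"] == "down"
        assert out.loc["all_up", "direction"] == "up"

    def test_disjoint_universes_rejected(self):
        a = pd.DataFrame({"S1": dict(es=0.5, nes=1.0, p=0.01, fdr=0.01,
                                     size=10, leading_edge=())}).T
        b = pd.DataFrame({"S2": dict(es=0.5, nes=1.0, p=0.01, fdr=0.01,
                                     size=10, leading_edge=())}).T
        with pytest.raises(ValueError, match="universe"):
            consistent_pathways({"c1": a, "c2": b})


class TestDisplayScore:
    def test_examples(self):
        assert display_score(0.5, 0.01) == pytest.approx(1.0)
        assert display_score(-0.8, 0.1) == pytest.approx(-0.8)
        assert display_score(0.0, 0.5) == 0.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            display_score(0.5, 0.0)
        with pytest.raises(ValueError):
            display_score(0.5, 1.5)


class TestLeadingEdgeCommon:
    def test_no_consistent_pathways_empty(self):
        consistent = pd.DataFrame(columns=["direction"])
        common = CommonSignature(frozenset({"b"}), frozenset())
        out = leading_edge_common(consistent, {}, common)
        assert out.empty

    def test_intersection_with_common(self):
        consistent = pd.DataFrame({"direction": ["up"]}, index=["S"])
        tab = pd.DataFrame(
            {"S": dict(es=0.5, nes=1.0, p=0.01, fdr=0.01, size=3,
                       leading_edge=("a", "b", "c"))}
        ).T
        common = CommonSignature(frozenset({"b"}), frozenset({"q"}))
        out = leading_edge_common(consistent, {"c1": tab}, common)
        assert list(out["gene"]) == ["b"]
        assert list(out["direction"]) == ["up"]
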