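"""Subfamily splitting, NJ trees, 1/m node weighting, weighted KDE and
peak calling."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import grow_resolved_family
from paleoks.distribution import (WeightedKsDistribution,
                                  build_paranome_distribution, detect_peaks,
                                  kde_density, midpoint_root, nj_tree,
                                  split_subfamilies, subfamily_distribution,
                                  weight_duplication_nodes)
from paleoks.distribution import Subfamily, _pair_key
from paleoks.ks import KsEstimate
from paleoks.seqio import PipelineConfig
from paleoks.simulate import SimulationConfig, simulate_paranome


def _est(a, b, ks):
    return KsEstimate(gene_a=a, gene_b=b, ks=ks, ka=ks / 4, syn_sites=70.0,
                      nonsyn_sites=230.0, codons_used=100,
                      saturated=not math.isfinite(ks))


def _estmap(*triples):
    return {_pair_key(a, b): _est(a, b, ks) for a, b, ks in triples}


class TestSplitSubfamilies:
    def test_pair_below_bound_stays_together(self):
        subs = split_subfamilies("F", ["a", "b"], _estmap(("a", "b", 0.8)))
        assert len(subs) == 1 and subs[0].member_ids == ("a", "b")

    def test_pair_above_bound_splits(self):
        subs = split_subfamilies("F", ["a", "b"], _estmap(("a", "b", 7.0)))
        assert [s.member_ids for s in subs] == [("a",), ("b",)]

    def test_single_linkage_chain(self):
        est = _estmap(("a", "b", 4.0), ("b", "c", 4.0), ("a", "c", 6.0))
        subs = split_subfamilies("F", ["a", "b", "c"], est)
        assert len(subs) == 1 and subs[0].member_ids == ("a", "b", "c")
        # The above-bound chained pair stays available for tree building.
        assert subs[0].estimates[("a", "c")].ks == 6.0

    def test_saturated_pairs_do_not_link(self):
        est = _estmap(("a", "b", math.inf))
        subs = split_subfamilies("F", ["a", "b"], est)
        assert len(subs) == 2


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(d, ["a", "b", "c"])
        # Three-point formulas: la = (dab + dac - dbc)/2 etc.
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(2.0)
        assert lengths["b"] == pytest.approx(3.0)
        assert lengths["c"] == pytest.approx(7.0)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # Tree: ((a:2,b:3):1,(c:4,d:5)) -> additive distances.
        d = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0]], float)
        tree = nj_tree(d, ["a", "b", "c", "d"])
        for x, y, expected in [("a", "b", 5), ("a", "c", 7), ("a", "d", 8),
                               ("b", "c", 8), ("b", "d", 9), ("c", "d", 9)]:
            tx = tree.find(x)
            assert tx.distance(tree.find(y)) == pytest.approx(expected)

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            # Build a random ultrametric-ish additive matrix from a random
            # tree by simulating leaf depths via random caterpillar merges.
            from skbio import TreeNode
            import io
            names = [f"t{i}" for i in range(n)]
            newick = names[0]
            for k in range(1, n):
                newick = f"({newick}:{rng.uniform(0.1, 2):.4f}," \
                         f"{names[k]}:{rng.uniform(0.1, 2):.4f})"
            tree = TreeNode.read(io.StringIO(newick + ";"))
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    dist = tree.find(names[i]).distance(tree.find(names[j]))
                    d[i, j] = d[j, i] = dist
            out = nj_tree(d, names)
            for i in range(n):
                for j in range(i + 1, n):
                    got = out.find(names[i]).distance(out.find(names[j]))
                    assert got == pytest.approx(d[i, j]), (i, j)

    def test_two_taxa_single_edge(self):
        tree = nj_tree(np.array([[0, 0.8], [0.8, 0]]), ["a", "b"])
        lengths = sorted(t.length for t in tree.tips())
        assert lengths == [pytest.approx(0.4)] * 2

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1], [2, 0]], float), ["a", "b"])


class TestMidpointRoot:
    def test_symmetric_four_leaf_tree_roots_on_central_edge(self):
        d = np.array([
            [0, 2, 6, 6],
            [2, 0, 6, 6],
            [6, 6, 0, 2],
            [6, 6, 2, 0]], float)
        rooted = midpoint_root(nj_tree(d, ["a", "b", "c", "d"]))
        children = rooted.children
        assert len(children) == 2
        sides = [sorted(t.name for t in c.tips(include_self=True))
                 for c in children]
        assert sorted(sides) == [["a", "b"], ["c", "d"]]

    def test_rooted_tree_has_n_minus_one_internal_nodes(self):
        rng = np.random.default_rng(45)
        fam = grow_resolved_family(6, rng, length_codons=100)
        from paleoks.distribution import family_ks_estimates
        est = family_ks_estimates(fam, PipelineConfig())
        ids = sorted(x.id for x in fam)
        sub = Subfamily("S", "F", tuple(ids), est)
        entries, nodes, tree = subfamily_distribution(sub)
        internal = [x for x in tree.postorder() if not x.is_tip()]
        assert len(internal) == len(ids) - 1


class TestWeightDuplicationNodes:
    def test_pair_family_weight_one(self):
        tree = nj_tree(np.array([[0, 0.8], [0.8, 0]]), ["a", "b"])
        entries, nodes = weight_duplication_nodes(tree, _estmap(("a", "b", 0.8)))
        assert len(entries) == 1
        assert entries[0]["weight"] == 1.0
        assert nodes[0].m == 1

    def test_three_leaf_rule_applied_literally(self):
        """Tree ((A,B),C): the {A,B} node has m=1, weight 1; the root has
        m=2 with pairs (A,C),(B,C) at weight 1/2 each; total mass 2."""
        d = np.array([[0, 0.2, 1.0], [0.2, 0, 1.0], [1.0, 1.0, 0]], float)
        tree = midpoint_root(nj_tree(d, ["A", "B", "C"]))
        est = _estmap(("A", "B", 0.2), ("A", "C", 1.0), ("B", "C", 1.0))
        entries, nodes = weight_duplication_nodes(tree, est)
        total = sum(e["weight"] for e in entries)
        assert total == pytest.approx(2.0)
        weights = sorted(e["weight"] for e in entries)
        assert weights == [pytest.approx(0.5), pytest.approx(0.5),
                           pytest.approx(1.0)]

    def test_caterpillar_six_leaves_mass_five(self):
        rng = np.random.default_rng(46)
        fam = grow_resolved_family(6, rng, length_codons=150)
        from paleoks.distribution import family_ks_estimates
        est = family_ks_estimates(fam, PipelineConfig())
        sub = Subfamily("S", "F", tuple(sorted(x.id for x in fam)), est)
        entries, nodes, _ = subfamily_distribution(sub)
        assert sum(e["weight"] for e in entries) == pytest.approx(5.0)

    def test_node_weights_sum_to_one(self):
        rng = np.random.default_rng(47)
        fam = grow_resolved_family(5, rng, length_codons=150)
        from paleoks.distribution import family_ks_estimates
        est = family_ks_estimates(fam, PipelineConfig())
        sub = Subfamily("S", "F", tuple(sorted(x.id for x in fam)), est)
        entries, nodes, _ = subfamily_distribution(sub)
        df = pd.DataFrame(entries)
        for node_id, grp in df.groupby("node_id"):
            assert grp["weight"].sum() == pytest.approx(1.0, abs=1e-12)


class TestBuildParanomeDistribution:
    def test_retention_one_recovers_one_entry_per_pair(self):
        cfg = SimulationConfig(n_base_genes=30, gene_len_codons=150,
                               wgd_retention=1.0, ssd_rate=0.0, seed=48)
        genes, _ = simulate_paranome(cfg)
        dist = build_paranome_distribution(genes, PipelineConfig())
        assert len(dist.entries) >= 0.95 * 30
        assert np.allclose(dist.entries["weight"], 1.0)

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError):
            build_paranome_distribution([], PipelineConfig())

    def test_rerun_determinism(self, tmp_path, paranome_run, pipeline_config):
        dist2 = build_paranome_distribution(paranome_run["genes"],
                                            pipeline_config)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        paranome_run["distribution"].write_tsv(p1)
        dist2.write_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()


def _single_entry_distribution(ks, weight=1.0):
    df = pd.DataFrame([{"gene_a": "a", "gene_b": "b", "ks": ks,
                        "weight": weight, "subfamily_id": "S",
                        "node_id": "n", "family_id": "F"}])
    return WeightedKsDistribution(entries=df)


class TestKdeDensity:
    def test_single_entry_mode(self):
        curve = kde_density(_single_entry_distribution(0.8), bandwidth=0.05)
        assert curve.mode == pytest.approx(0.8, abs=0.01)

    def test_doubling_weights_doubles_curve(self):
        c1 = kde_density(_single_entry_distribution(0.8, 1.0), bandwidth=0.05)
        c2 = kde_density(_single_entry_distribution(0.8, 2.0), bandwidth=0.05)
        assert np.allclose(c2.density, 2 * c1.density)

    def test_grid_integral_matches_total_weight(self, paranome_run):
        curve = kde_density(paranome_run["distribution"])
        integral = float(np.trapezoid(curve.density, curve.grid))
        assert abs(integral - curve.total_weight) <= 0.01 * curve.total_weight

    def test_entries_below_cutoff_excluded(self):
        curve = kde_density(_single_entry_distribution(0.8))
        df = pd.DataFrame([
            {"gene_a": "a", "gene_b": "b", "ks": 0.01, "weight": 5.0,
             "subfamily_id": "S", "node_id": "n1", "family_id": "F"},
            {"gene_a": "c", "gene_b": "d", "ks": 0.8, "weight": 1.0,
             "subfamily_id": "S", "node_id": "n2", "family_id": "F"},
        ])
        curve2 = kde_density(WeightedKsDistribution(entries=df))
        assert curve2.total_weight == 1.0  # the near-zero mass is dropped

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            kde_density(_single_entry_distribution(0.8), bandwidth=0.0)


class TestDetectPeaks:
    def test_flat_background_has_no_narrow_dominant_peak(self):
        """A uniform SSD-only background may show a broad hump, but never
        the narrow high-mass burst that marks a WGD."""
        cfg = SimulationConfig(n_base_genes=40, gene_len_codons=150,
                               wgd_retention=0.0, ssd_rate=1.0,
                               ssd_ks_range=(0.1, 3.0), seed=49)
        genes, _ = simulate_paranome(cfg)
        dist = build_paranome_distribution(genes, PipelineConfig())
        curve = kde_density(dist, bandwidth=0.25)
        peaks = detect_peaks(curve, dist)
        total = dist.density_entries()["weight"].sum()
        for p in peaks:
            width = p.interval[1] - p.interval[0]
            if width < 0.5:
                assert p.mass < 0.2 * total

    def test_wgd_simulation_yields_major_peak_at_planted_age(self, paranome_run):
        dist = paranome_run["distribution"]
        curve = kde_density(dist)
        peaks = detect_peaks(curve, dist)
        assert peaks
        major = max(peaks, key=lambda p: p.mass)
        lo, hi = major.interval
        assert lo <= 0.8 <= hi

    def test_two_planted_wgds_give_two_separated_peaks(self):
        entries = []
        rng = np.random.default_rng(50)
        for i, centre in enumerate([0.4] * 60 + [1.6] * 60):
            entries.append({"gene_a": f"a{i}", "gene_b": f"b{i}",
                            "ks": centre + rng.normal(0, 0.05),
                            "weight": 1.0, "subfamily_id": "S",
                            "node_id": f"n{i}", "family_id": "F"})
        dist = WeightedKsDistribution(entries=pd.DataFrame(entries))
        curve = kde_density(dist, bandwidth=0.08)
        peaks = detect_peaks(curve, dist)
        modes = sorted(p.mode_ks for p in peaks if p.mass > 10)
        assert len(modes) == 2
        assert abs(modes[0] - 0.4) < 0.1 and abs(modes[1] - 1.6) < 0.16
        p1, p2 = sorted(peaks, key=lambda p: p.mode_ks)[:2]
        assert p1.interval[1] < p2.interval[0]


class TestRedundancyAccounting:
    def test_correction_shrinks_large_family_mass_by_pair_count_ratio(self):
        """An n=20 star family (one duplication burst) carries ~190 raw
        pairwise estimates but only ~19 units of corrected mass."""
        rng = np.random.default_rng(51)
        from paleoks.seqio import CodingSequence
        from paleoks.simulate import evolve_to_ks, random_cds
        base = random_cds(200, rng)
        members = [CodingSequence.from_nt(f"m{i:02d}",
                                          evolve_to_ks(base, 0.4, rng=rng).nt)
                   for i in range(20)]
        from paleoks.distribution import family_ks_estimates
        est = family_ks_estimates(members, PipelineConfig())
        assert len(est) == 190  # n(n-1)/2 raw estimates
        sub = Subfamily("S", "F", tuple(sorted(m.id for m in members)), est)
        entries, nodes, _ = subfamily_distribution(sub)
        corrected = sum(e["weight"] for e in entries)
        assert corrected == pytest.approx(19.0)  # n - 1 events
        ratio = len(est) / corrected
        assert abs(ratio - 10.0) / 10.0 < 0.2
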