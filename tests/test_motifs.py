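"""Motif counting oracles, degree-preserving rewiring and pairwise Z-scores."""

from __future__ import annotations

import math

import numpy as np
import pytest

from _oracles import (
    oracle_count_bifan,
    oracle_count_ppi_bifan,
    oracle_count_ppi_delta,
    oracle_count_v,
    random_bipartite,
)
from ohnomir.model import DuplicatePair, PpiNetwork, RegulatoryNetwork
from ohnomir.motifs import (
    MotifType,
    bin_counts,
    count_bifan,
    count_ppi_bifan,
    count_ppi_delta,
    count_v,
    enrichment_run,
    pairwise_z,
    rewire,
)


def P(a, b, origin="WGD"):
    return DuplicatePair(a, b, origin)


class TestCounting:
    def test_v_set_intersection(self):
        net = RegulatoryNetwork(
            [("a", g) for g in ("g1", "g2", "g3")] + [("b", g) for g in ("g2", "g3", "g4")]
        )
        assert count_v(P("a", "b"), net) == 2

    def test_v_disjoint_targets(self):
        net = RegulatoryNetwork([("a", "g1"), ("b", "g2")])
        assert count_v(P("a", "b"), net) == 0

    def test_bifan_zero_without_common_targets(self):
        net = RegulatoryNetwork([("a", "g1"), ("b", "g2")])
        assert count_bifan(P("a", "b"), net, [P("g1", "g2")]) == 0

    def test_bifan_counts_cotargeted_pairs_matching_origin(self):
        edges = [(m, g) for m in ("a", "b") for g in ("g1", "g2", "g3")]
        net = RegulatoryNetwork(edges)
        tps = [P("g1", "g2", "WGD"), P("g2", "g3", "SSD"), P("g1", "g3", "WGD")]
        assert count_bifan(P("a", "b", "WGD"), net, tps) == 2
        assert count_bifan(P("a", "b", "WGD"), net, tps, match_origin=False) == 3

    def test_target_pairs_deduplicated(self):
        edges = [(m, g) for m in ("a", "b") for g in ("g1", "g2")]
        net = RegulatoryNetwork(edges)
        tps = [P("g1", "g2"), P("g2", "g1")]  # same unordered pair twice
        assert count_bifan(P("a", "b"), net, tps) == 1

    def test_ppi_bifan_requires_ppi_edge(self):
        edges = [(m, g) for m in ("a", "b") for g in ("g1", "g2", "g3")]
        net = RegulatoryNetwork(edges)
        tps = [P("g1", "g2"), P("g1", "g3")]
        ppi = PpiNetwork([("g1", "g2")])
        assert count_ppi_bifan(P("a", "b"), net, tps, ppi) == 1

    def test_ppi_delta_minimal_case(self):
        net = RegulatoryNetwork([("a", "g1"), ("a", "g2")])
        ppi = PpiNetwork([("g1", "g2")])
        assert count_ppi_delta("a", net, [P("g1", "g2")], ppi) == 1
        assert count_ppi_delta("a", net, [P("g1", "g2")], PpiNetwork([])) == 0

    def test_single_target_mirna_has_no_delta(self):
        net = RegulatoryNetwork([("a", "g1")])
        assert count_ppi_delta("a", net, [P("g1", "g2")], PpiNetwork([("g1", "g2")])) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_all_counts_match_enumeration_oracles(self, seed):
        """V/bifan/PPI-bifan/PPI-delta equal brute-force enumeration (<=50 nodes)."""
        rng = np.random.default_rng(seed)
        net = random_bipartite(rng, n_mirnas=10, n_targets=30, p_edge=0.15)
        targets = sorted(net.target_nodes)
        tps = []
        for _ in range(12):
            g, h = rng.choice(len(targets), size=2, replace=False)
            tps.append(P(targets[g], targets[h], str(rng.choice(["WGD", "SSD"]))))
        ppi = PpiNetwork(
            [tp.key for tp in tps if rng.random() < 0.5] or [tps[0].key]
        )
        mirnas = sorted(net.mirna_nodes)
        for _ in range(10):
            i, j = rng.choice(len(mirnas), size=2, replace=False)
            pair = P(mirnas[i], mirnas[j], str(rng.choice(["WGD", "SSD"])))
            assert count_v(pair, net) == oracle_count_v(pair, net)
            assert count_bifan(pair, net, tps) == oracle_count_bifan(pair, net, tps)
            assert count_ppi_bifan(pair, net, tps, ppi) == oracle_count_ppi_bifan(pair, net, tps, ppi)
        for m in mirnas:
            assert count_ppi_delta(m, net, tps, ppi) == oracle_count_ppi_delta(m, net, tps, ppi)

    def test_bifan_bounded_by_v_choose_2(self, rng):
        net = random_bipartite(rng, 8, 25, 0.2)
        targets = sorted(net.target_nodes)
        tps = [
            P(targets[i], targets[j], "WGD")
            for i, j in rng.choice(len(targets), size=(15, 2))
            if i != j
        ]
        ppi = PpiNetwork([tp.key for tp in tps[:7]])
        mirnas = sorted(net.mirna_nodes)
        for i in range(len(mirnas) - 1):
            pair = P(mirnas[i], mirnas[i + 1], "WGD")
            v = count_v(pair, net)
            b = count_bifan(pair, net, tps)
            pb = count_ppi_bifan(pair, net, tps, ppi)
            assert pb <= b <= math.comb(v, 2)


class TestRewire:
    def test_degrees_bipartiteness_edges_preserved(self, rng):
        net = random_bipartite(rng, 20, 60, 0.08)
        out0, in0 = net.degree_sequence()
        for rep in range(5):
            rw = rewire(net, np.random.default_rng(rep), swaps_per_edge=10)
            out1, in1 = rw.degree_sequence()
            assert out1 == out0 and in1 == in0
            assert rw.n_edges == net.n_edges
            assert rw.mirna_nodes == net.mirna_nodes and rw.target_nodes == net.target_nodes

    def test_randomization_actually_moves_edges(self, rng):
        net = random_bipartite(rng, 40, 200, 0.12)  # ~1000 edges
        rw = rewire(net, np.random.default_rng(0), swaps_per_edge=10)
        jaccard = len(net.edges & rw.edges) / len(net.edges | rw.edges)
        assert jaccard < 0.5

    def test_deterministic_given_seed(self, rng):
        net = random_bipartite(rng, 15, 40, 0.1)
        r1 = rewire(net, np.random.default_rng(42), 10)
        r2 = rewire(net, np.random.default_rng(42), 10)
        assert r1.edges == r2.edges


class TestPairwiseZ:
    def test_direct_formula(self):
        res = pairwise_z(10, [4 - 2, 4 + 2] * 50)  # mean 4, population sd 2
        assert res.z == pytest.approx(3.0)
        assert res.status == "ok"

    def test_constant_nonzero_null_discarded(self):
        res = pairwise_z(5, [5] * 100)
        assert res.status == "discarded_sd_zero" and res.z is None

    def test_double_zero_rule_sets_z_zero(self):
        res = pairwise_z(0, [0] * 1000)
        assert res.status == "zero_zero" and res.z == 0.0

    def test_empty_null_counts_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            pairwise_z(1, [])


class TestEnrichmentRun:
    def _setup(self, rng):
        net = random_bipartite(rng, 12, 40, 0.15)
        mirnas = sorted(net.mirna_nodes)
        targets = sorted(net.target_nodes)
        catalog = [
            P(mirnas[0], mirnas[1], "WGD"),
            P(mirnas[2], mirnas[3], "SSD"),
            P("ghost1", "ghost2", "SSD"),  # absent from network
        ]
        tps = [P(targets[0], targets[1], "WGD"), P(targets[2], targets[3], "SSD")]
        ppi = PpiNetwork([tps[0].key, tps[1].key])
        return net, catalog, tps, ppi

    def test_reproducible_given_seed(self, rng):
        net, catalog, tps, ppi = self._setup(rng)
        t1, s1 = enrichment_run(catalog, net, MotifType.V, tps, ppi, n_replicates=20, seed=5)
        t2, s2 = enrichment_run(catalog, net, MotifType.V, tps, ppi, n_replicates=20, seed=5)
        assert t1.equals(t2) and s1 == s2

    def test_absent_pairs_flagged(self, rng):
        net, catalog, tps, ppi = self._setup(rng)
        table, summary = enrichment_run(catalog, net, MotifType.V, tps, ppi, n_replicates=10, seed=1)
        assert (table.status == "absent_from_network").sum() == 1
        assert summary["n_absent_from_network"] == 1

    def test_ppi_delta_subjects_are_single_mirnas_with_wgd_priority(self, rng):
        net, catalog, tps, ppi = self._setup(rng)
        catalog.append(P(catalog[0].member_a, sorted(net.mirna_nodes)[4], "SSD"))
        table, _ = enrichment_run(catalog, net, MotifType.PPI_DELTA, tps, ppi, n_replicates=5, seed=2)
        row = table[table.subject == catalog[0].member_a]
        assert row.origin.tolist() == ["WGD"]
        assert not table.subject.str.contains(r"\|").any()

    def test_z_invariant_under_target_relabeling(self, rng):
        net, catalog, tps, ppi = self._setup(rng)
        relabel = {t: f"X{t}" for t in net.target_nodes}
        net2 = RegulatoryNetwork([(m, relabel[t]) for m, t in net.edges])
        tps2 = [P(relabel[tp.member_a], relabel[tp.member_b], tp.origin) for tp in tps]
        t1, _ = enrichment_run(catalog[:2], net, MotifType.BIFAN, tps, None, n_replicates=15, seed=3)
        t2, _ = enrichment_run(catalog[:2], net2, MotifType.BIFAN, tps2, None, n_replicates=15, seed=3)
        for col in ("n", "null_mean", "null_sd", "status"):
            assert t1[col].tolist() == t2[col].tolist()

    def test_planted_recovery_small_scale(self):
        """Planted WGD overlap shows higher median V-motif Z than unplanted SSD."""
        from ohnomir.synthetic import SyntheticConfig, generate_annotations, generate_regulatory_network, generate_sequences

        cfg = SyntheticConfig(
            n_mirna_genes=120,
            n_target_genes=600,
            n_wgd_pairs=25,
            n_ssd_pairs=25,
            dice_wgd=0.3,
            dice_ssd=0.05,
            frac_intragenic=0.0,
            n_rbh_decoys=0,
            n_background_target_pairs=40,
            n_background_ppi_edges=60,
            rng_seed=8,
        )
        b = generate_annotations(cfg)
        mats = generate_sequences(cfg, b)
        nb = generate_regulatory_network(cfg, b, mats)
        net = RegulatoryNetwork(nb.gene_edges)
        table, summary = enrichment_run(
            b.mirna_pairs, net, MotifType.V, nb.target_pairs, None, n_replicates=30, seed=4
        )
        assert summary["median_z_by_origin"]["WGD"] > summary["median_z_by_origin"]["SSD"]


def test_bin_counts_classes():
    assert bin_counts([0, 1, 50, 51, 200], MotifType.V) == {"0": 1, "1-50": 2, ">50": 2}
    assert bin_counts([0, 0, 1, 7], MotifType.BIFAN) == {"0": 2, ">=1": 2}
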