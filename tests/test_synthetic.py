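"""Planted structure, determinism and contracts of the data generator."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from ohnomir import io as oio
from ohnomir.model import wgd_priority_labels
from ohnomir.synthetic import (
    SizingError,
    SyntheticConfig,
    generate_annotations,
    generate_expression,
    generate_regulatory_network,
    generate_sequences,
    mature_to_gene_map,
)

SEED_LO, SEED_HI = 2, 8  # default 7mer window


def tiny(**kw) -> SyntheticConfig:
    base = dict(
        n_mirna_genes=40,
        n_target_genes=200,
        n_wgd_pairs=5,
        n_ssd_pairs=5,
        n_background_target_pairs=10,
        n_background_ppi_edges=20,
        n_rbh_decoys=0,
        rng_seed=11,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="frac_intragenic"):
            tiny(frac_intragenic=1.5)

    def test_too_many_pairs_is_a_sizing_error(self):
        with pytest.raises(SizingError):
            tiny(n_mirna_genes=10, n_wgd_pairs=10, n_ssd_pairs=10)


class TestAnnotations:
    def test_no_intragenic_when_fraction_zero(self):
        b = generate_annotations(tiny(frac_intragenic=0.0))
        assert not b.host_genes and not b.host_assignments
        hosts = list(b.host_genes.values())
        for m in b.mirna_genes.values():
            assert not any(m.contained_in(h.chrom, h.start, h.end) for h in hosts)

    def test_full_intragenic_plants_exactly_n_wgd_pairs(self):
        b = generate_annotations(tiny(frac_intragenic=1.0))
        wgd_planted = {k for k in b.planted_intragenic if k[0].startswith("MIR-W")}
        assert len(wgd_planted) == 5
        # recoverable by interval containment
        hosts = b.host_genes
        for pair in b.mirna_pairs:
            if pair.key not in b.planted_intragenic:
                continue
            for member in pair.members:
                m = b.mirna_genes[member]
                assert any(
                    m.contained_in(h.chrom, h.start, h.end) for h in hosts.values()
                ), member

    def test_planted_pairs_conserve_relative_strand(self):
        b = generate_annotations(tiny(frac_intragenic=1.0))
        rel = {a.mirna_gene_id: a.relative_strand for a in b.host_assignments}
        for pair in b.mirna_pairs:
            if pair.key in b.planted_intragenic:
                assert rel[pair.member_a] == rel[pair.member_b]

    def test_wgd_priority_overlap_lists(self):
        cfg = tiny(n_label_overlap=2)
        b = generate_annotations(cfg)
        overlap_keys = {p.key for p in b.ssd_list} & {p.key for p in b.wgd_list}
        assert len(overlap_keys) == 2
        labels = wgd_priority_labels(b.wgd_list + b.ssd_list)
        for k in overlap_keys:
            assert labels[k[0]] == labels[k[1]] == "WGD"

    def test_deterministic_output_files(self, tmp_path: Path):
        def render(sub: str) -> dict[str, bytes]:
            cfg = tiny()
            b = generate_annotations(cfg)
            paths = oio.write_annotation_files(b, tmp_path / sub)
            return {k: p.read_bytes() for k, p in paths.items()}

        assert render("a") == render("b")


class TestSequences:
    def test_lengths_and_alphabet(self, small_config, small_matures):
        for prods in small_matures.values():
            assert 1 <= len(prods) <= 2
            for m in prods:
                assert 19 <= len(m.sequence) <= 25
                assert set(m.sequence) <= set("ACGU")

    def test_perfect_seed_conservation_forces_identical_seeds(self):
        cfg = tiny(seed_conservation_wgd=1.0)
        b = generate_annotations(cfg)
        mats = generate_sequences(cfg, b)
        for p in b.mirna_pairs:
            if p.origin != "WGD":
                continue
            seeds_a = {m.sequence[SEED_LO - 1 : SEED_HI] for m in mats[p.member_a]}
            seeds_b = {m.sequence[SEED_LO - 1 : SEED_HI] for m in mats[p.member_b]}
            assert seeds_a & seeds_b, p.key

    def test_seed_conservation_rate_matches_binomial(self):
        cfg = SyntheticConfig(
            n_mirna_genes=1000,
            n_wgd_pairs=0,
            n_ssd_pairs=500,
            seed_conservation_ssd=0.25,
            frac_intragenic=0.0,
            n_rbh_decoys=0,
            rng_seed=5,
        )
        b = generate_annotations(cfg)
        mats = generate_sequences(cfg, b)
        matches = trials = 0
        for p in b.mirna_pairs:
            a5 = next(m for m in mats[p.member_a] if m.arm == "5p")
            b5 = next(m for m in mats[p.member_b] if m.arm == "5p")
            for x, y in zip(
                a5.sequence[SEED_LO - 1 : SEED_HI], b5.sequence[SEED_LO - 1 : SEED_HI]
            ):
                matches += x == y
                trials += 1
        rate = matches / trials
        se = np.sqrt(0.25 * 0.75 / trials)
        assert abs(rate - 0.25) < 3 * se, rate

    def test_shared_mature_when_fully_conserved(self):
        cfg = tiny(seed_conservation_wgd=1.0, nonseed_conservation_wgd=1.0)
        b = generate_annotations(cfg)
        mats = generate_sequences(cfg, b)
        m2g = mature_to_gene_map(mats)
        shared = [m for m, parents in m2g.items() if len(parents) == 2]
        # every WGD pair's matures are identical -> shared ids
        n_wgd_matures = sum(len(mats[p.member_a]) for p in b.mirna_pairs if p.origin == "WGD")
        assert len(shared) == n_wgd_matures


class TestRegulatoryNetwork:
    def test_no_duplicate_edge_rows(self, small_netbundle):
        df = small_netbundle.interactions
        assert not df.duplicated(subset=["mirna_mature", "target_gene"]).any()

    def test_dice_one_plants_identical_target_sets(self):
        cfg = tiny(dice_wgd=1.0)
        b = generate_annotations(cfg)
        mats = generate_sequences(cfg, b)
        nb = generate_regulatory_network(cfg, b, mats)
        by_gene: dict[str, set[str]] = {}
        for m, t in nb.gene_edges:
            by_gene.setdefault(m, set()).add(t)
        for p in b.mirna_pairs:
            if p.origin == "WGD":
                assert by_gene[p.member_a] == by_gene[p.member_b]
                assert nb.realized_dice[p.key] == 1.0

    def test_bifan_plant_rate_binomial(self):
        cfg = SyntheticConfig(
            n_mirna_genes=400,
            n_target_genes=3000,
            n_wgd_pairs=100,
            n_ssd_pairs=100,
            bifan_plant_rate=0.5,
            frac_intragenic=0.0,
            n_rbh_decoys=0,
            rng_seed=3,
        )
        b = generate_annotations(cfg)
        mats = generate_sequences(cfg, b)
        nb = generate_regulatory_network(cfg, b, mats)
        n = len(nb.bifan_planted)
        se = np.sqrt(100 * 0.5 * 0.5)
        assert abs(n - 50) < 3 * se
        # planted bifans really are co-targeting quadruples
        by_gene: dict[str, set[str]] = {}
        for m, t in nb.gene_edges:
            by_gene.setdefault(m, set()).add(t)
        for key in nb.bifan_planted:
            g, h = nb.planted_target_pairs[key]
            for member in key:
                assert {g, h} <= by_gene[member]

    def test_ppi_couple_zero_leaves_planted_pairs_unlinked(self):
        cfg = tiny(ppi_couple_prob=0.0, bifan_plant_rate=1.0)
        b = generate_annotations(cfg)
        mats = generate_sequences(cfg, b)
        nb = generate_regulatory_network(cfg, b, mats)
        assert nb.planted_target_pairs and not nb.ppi_coupled
        linked = set(zip(nb.ppi["gene_a"], nb.ppi["gene_b"]))
        for g, h in nb.planted_target_pairs.values():
            assert (g, h) not in linked and (h, g) not in linked

    def test_realized_dice_tracks_planted_value(self, small_config, small_netbundle):
        vals = {
            k: v
            for k, v in small_netbundle.realized_dice.items()
            if k[0].startswith("MIR-W")
        }
        assert abs(np.mean(list(vals.values())) - small_config.dice_wgd) < 0.1


class TestExpression:
    def test_shape_and_nonnegative(self, small_config, small_expression):
        raw, iso_map, labels = small_expression
        assert raw.shape[1] == small_config.n_tissues
        assert (raw.values >= 0).all()
        assert set(iso_map) == set(raw.index)

    def test_wgd_shift_orders_medians_in_every_tissue(self):
        cfg = SyntheticConfig(
            n_mirna_genes=200,
            n_wgd_pairs=50,
            n_ssd_pairs=50,
            expr_shift_wgd=1.0,
            n_tissues=10,
            frac_intragenic=0.0,
            n_rbh_decoys=0,
            rng_seed=2,
        )
        b = generate_annotations(cfg)
        mats = generate_sequences(cfg, b)
        raw, iso_map, labels = generate_expression(cfg, b, mats)
        grp = {m: labels.get(iso_map[m]) for m in raw.index}
        wgd_rows = [m for m, g in grp.items() if g == "WGD"]
        ssd_rows = [m for m, g in grp.items() if g == "SSD"]
        for col in raw.columns:
            assert raw.loc[wgd_rows, col].median() > raw.loc[ssd_rows, col].median(), col

    def test_null_shift_does_not_order_all_tissues(self):
        cfg = SyntheticConfig(
            n_mirna_genes=200,
            n_wgd_pairs=50,
            n_ssd_pairs=50,
            expr_shift_wgd=0.0,
            n_tissues=10,
            frac_intragenic=0.0,
            n_rbh_decoys=0,
            rng_seed=2,
        )
        b = generate_annotations(cfg)
        mats = generate_sequences(cfg, b)
        raw, iso_map, labels = generate_expression(cfg, b, mats)
        grp = {m: labels.get(iso_map[m]) for m in raw.index}
        wgd_rows = [m for m, g in grp.items() if g == "WGD"]
        ssd_rows = [m for m, g in grp.items() if g == "SSD"]
        wins = sum(
            raw.loc[wgd_rows, col].median() > raw.loc[ssd_rows, col].median()
            for col in raw.columns
        )
        assert 0 < wins < 10  # coin-flip behaviour, not a systematic ordering

    def test_determinism(self):
        cfg = tiny()
        b = generate_annotations(cfg)
        mats = generate_sequences(cfg, b)
        r1, _, _ = generate_expression(cfg, b, mats)
        r2, _, _ = generate_expression(cfg, b, mats)
        assert r1.equals(r2)
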