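"""End-to-end orchestration: simulate/ingest -> align -> catalog -> curate ->
enrich -> similarity/expression -> report.

A single :class:`RunConfig` (YAML-serializable) drives the whole analysis;
all randomness flows from one recorded seed, and a rerun with the same
config produces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import ohnomir
from ohnomir import io as oio
from ohnomir.alignment import AlignmentParams, pair_similarity
from ohnomir.catalog import (
    FunnelReport,
    find_intragenic_candidates,
    label_pairs,
    rbh_filter,
    stratify_pairs,
)
from ohnomir.motifs import MotifType, enrichment_run
from ohnomir.network import (
    EvidenceFilter,
    collapse_to_gene_level,
    drop_indistinguishable_pairs,
    filter_interactions,
    load_ppi,
    restrict_to_network,
)
from ohnomir.similarity import (
    distance_by_motif_context,
    group_expression_summary,
    normalize_expression,
    pair_dice_table,
    pair_expression_distances,
)
from ohnomir.synthetic import (
    SyntheticConfig,
    attach_matures,
    generate_annotations,
    generate_expression,
    generate_regulatory_network,
    generate_sequences,
    mature_to_gene_map,
)

logger = logging.getLogger(__name__)

DEFAULT_EVIDENCE_FILTER = EvidenceFilter(
    allowed_categories=frozenset({"Normal", "Primary"}),
    require_direct_evidence=True,
    require_high_throughput=True,
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for a reproducible end-to-end run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    motifs: tuple[str, ...] = ("V", "BIFAN", "PPI_BIFAN", "PPI_DELTA")
    n_replicates: int = 100
    swaps_per_edge: int = 10
    ppi_min_confidence: float = 960.0
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig, outdir: Path) -> dict:
    """Run the full synthetic-data analysis; writes artifacts, returns the report."""
    outdir = Path(outdir)
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": ohnomir.__version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "funnel": {},
        "catalog": {},
        "enrichment": {},
        "similarity": {},
        "expression": {},
    }

    # --- simulate ---------------------------------------------------------
    scfg = dataclasses.replace(config.synthetic, rng_seed=config.seed)
    bundle = generate_annotations(scfg)
    matures = generate_sequences(scfg, bundle, (config.alignment.seed_start, config.alignment.seed_end))
    netbundle = generate_regulatory_network(scfg, bundle, matures)
    expr_raw, iso_map, expr_labels = generate_expression(scfg, bundle, matures)

    oio.write_annotation_files(bundle, outdir / "inputs")
    oio.write_fasta(
        (m for prods in matures.values() for m in prods), outdir / "inputs" / "matures.fasta"
    )
    oio.write_mature_map(matures, outdir / "inputs" / "mature_to_gene.tsv")
    netbundle.interactions.to_csv(outdir / "inputs" / "interactions.tsv", sep="\t", index=False)
    netbundle.ppi.to_csv(outdir / "inputs" / "ppi.tsv", sep="\t", index=False)
    expr_raw.to_csv(outdir / "inputs" / "expression.tsv", sep="\t")
    oio.write_pairs_tsv(netbundle.target_pairs, outdir / "inputs" / "target_pairs.tsv")
    oio.write_truth_manifest(
        {
            "planted_intragenic": sorted(map(list, bundle.planted_intragenic)),
            "bifan_planted": sorted(map(list, netbundle.bifan_planted)),
            "ppi_coupled": sorted(map(list, netbundle.ppi_coupled)),
            "realized_dice": {"|".join(k): v for k, v in sorted(netbundle.realized_dice.items())},
        },
        outdir / "inputs" / "truth.json",
    )

    # --- catalog ----------------------------------------------------------
    catalog = label_pairs(bundle.wgd_list, bundle.ssd_list)
    genes = attach_matures(bundle, matures)
    funnel = FunnelReport()
    candidates, funnel = find_intragenic_candidates(
        bundle.host_pairs, bundle.host_genes, genes, funnel
    )
    retained, funnel = rbh_filter(candidates, genes, config.alignment, funnel=funnel)
    strata = stratify_pairs(catalog)
    report["funnel"] = funnel.counts
    report["catalog"] = {
        "n_pairs": len(catalog),
        "n_wgd": sum(p.origin == "WGD" for p in catalog),
        "n_ssd": sum(p.origin == "SSD" for p in catalog),
        "n_intragenic_retained": len(retained),
        "strata_sizes": {k: len(v) for k, v in strata.items()},
    }

    # --- alignment scores for the catalog ---------------------------------
    align_rows = []
    for p in catalog:
        score, ma, mb = pair_similarity(genes[p.member_a], genes[p.member_b], config.alignment)
        align_rows.append(
            {
                "gene_a": p.member_a,
                "gene_b": p.member_b,
                "origin": p.origin,
                "best_score": score,
                "mature_a": ma,
                "mature_b": mb,
            }
        )
    align_df = pd.DataFrame(align_rows).sort_values(["gene_a", "gene_b"])
    align_df.to_csv(outdir / "alignment_scores.tsv", sep="\t", index=False)
    report["alignment"] = {
        "median_score_wgd": float(align_df[align_df.origin == "WGD"].best_score.median()),
        "median_score_ssd": float(align_df[align_df.origin == "SSD"].best_score.median()),
    }

    # --- network curation --------------------------------------------------
    filtered = filter_interactions(netbundle.interactions, DEFAULT_EVIDENCE_FILTER)
    net = collapse_to_gene_level(filtered, mature_to_gene_map(matures))
    analyzable, indistinct = drop_indistinguishable_pairs(net, catalog)
    analyzable, dropped_absent = restrict_to_network(analyzable, net)
    ppi = load_ppi(netbundle.ppi, config.ppi_min_confidence)
    report["network"] = {
        "n_mirna_nodes": len(net.mirna_nodes),
        "n_target_nodes": len(net.target_nodes),
        "n_edges": net.n_edges,
        "n_indistinguishable_excluded": len(indistinct),
        "n_absent_dropped": len(dropped_absent),
        "n_ppi_edges": ppi.n_edges,
    }

    # --- motif enrichment ---------------------------------------------------
    enrichment_tables = {}
    for motif_name in config.motifs:
        motif = MotifType[motif_name]
        table, summary = enrichment_run(
            analyzable,
            net,
            motif,
            target_pairs=netbundle.target_pairs,
            ppi=ppi,
            n_replicates=config.n_replicates,
            swaps_per_edge=config.swaps_per_edge,
            seed=config.seed,
        )
        table.to_csv(outdir / f"enrichment_{motif.value.lower()}.tsv", sep="\t", index=False)
        report["enrichment"][motif.value] = summary
        enrichment_tables[motif.value] = table

    # --- similarity & expression -------------------------------------------
    dice_df = pair_dice_table(analyzable, net)
    dice_df.to_csv(outdir / "dice.tsv", sep="\t", index=False)
    by_origin = dice_df.dropna(subset=["dice"]).groupby("origin")["dice"].mean()
    report["similarity"] = {f"mean_dice_{k.lower()}": float(v) for k, v in by_origin.items()}

    expr = normalize_expression(expr_raw, iso_map)
    expr_summary = group_expression_summary(expr, expr_labels)
    expr_summary.to_csv(outdir / "expression_summary.tsv", sep="\t", index=False)
    report["expression"] = {
        "n_tissues": int(len(expr_summary)),
        "wgd_median_higher_in_all_tissues": bool(
            (expr_summary.median_wgd > expr_summary.median_ssd).all()
        ),
    }
    distances = pair_expression_distances(
        [p for p in analyzable if p.member_a in expr.index and p.member_b in expr.index], expr
    )
    bifan_tbl = enrichment_tables.get("BIFAN")
    if distances and bifan_tbl is not None:
        ctx = bifan_tbl.assign(
            member_a=bifan_tbl.subject.str.split("|").str[0],
            member_b=bifan_tbl.subject.str.split("|").str[1],
        )
        strat = distance_by_motif_context(distances, ctx)
        strat.to_csv(outdir / "expression_distance_by_context.tsv", sep="\t", index=False)
        report["expression"]["n_pairs_with_distance"] = int(len(strat))

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report


def compare_sources(report_a: dict, report_b: dict) -> dict:
    """Robustness summary between two runs over alternative input sources.

    Compares the sign of the median enrichment Z per motif and origin, and
    the binned count classes, between two run reports.
    """
    out: dict = {"sign_agreement": {}, "bins": {}}
    motifs = sorted(set(report_a.get("enrichment", {})) & set(report_b.get("enrichment", {})))
    if not motifs:
        out["warning"] = "no common motifs between the two reports"
        return out
    n_agree = n_total = 0
    for motif in motifs:
        za = report_a["enrichment"][motif]["median_z_by_origin"]
        zb = report_b["enrichment"][motif]["median_z_by_origin"]
        agree = {}
        for origin in ("WGD", "SSD"):
            a, b = za.get(origin), zb.get(origin)
            if a is None or b is None:
                agree[origin] = None
                continue
            same = bool(np.sign(a) == np.sign(b))
            agree[origin] = same
            n_agree += same
            n_total += 1
        out["sign_agreement"][motif] = agree
        out["bins"][motif] = {
            "a": report_a["enrichment"][motif]["bins_by_origin"],
            "b": report_b["enrichment"][motif]["bins_by_origin"],
        }
    out["sign_agreement_fraction"] = n_agree / n_total if n_total else None
    return out
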