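"""Building the labeled catalog of duplicate miRNA pairs.

Combines WGD/SSD pair lists into a disjoint catalog (WGD has priority for
pairs reported by both sources), detects intragenic duplicate miRNA pairs
hosted on duplicate protein-coding genes (interval containment + relative
strand conservation), resolves multi-miRNA hosts with a reciprocal
best-alignment-hit (RBH) filter, and stratifies pairs by duplication round
(pre-2R vs post-2R via last-common-ancestor age) and subgenome class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

from ohnomir.alignment import AlignmentParams, DEFAULT_PARAMS, pair_similarity
from ohnomir.model import DuplicatePair, HostAssignment, MirnaGene
from ohnomir.synthetic import GeneInterval

logger = logging.getLogger(__name__)

# Oldest-to-youngest clade ordering used to date duplications relative to
# the vertebrate whole-genome duplications. "Pre-2R" means the pair's last
# common ancestor is strictly older than Vertebrata.
DEFAULT_CLADE_ORDER = (
    "Eukaryota",
    "Opisthokonta",
    "Metazoa",
    "Eumetazoa",
    "Bilateria",
    "Deuterostomia",
    "Chordata",
    "Olfactores",
    "Vertebrata",
    "Gnathostomata",
    "Euteleostomi",
    "Sarcopterygii",
    "Tetrapoda",
    "Amniota",
    "Mammalia",
    "Theria",
    "Eutheria",
    "Euarchontoglires",
    "Primates",
    "Homo sapiens",
)


def label_pairs(
    wgd_list: Iterable[DuplicatePair], ssd_list: Iterable[DuplicatePair]
) -> list[DuplicatePair]:
    """Merge WGD and SSD pair lists into a disjoint catalog.

    A pair reported by both sources is kept once with origin WGD; the SSD
    list is purged of such pairs. (Per-miRNA WGD-priority labels, used for
    single-miRNA analyses, are derived separately by
    :func:`ohnomir.model.wgd_priority_labels`.)
    """
    wgd = list(wgd_list)
    wgd_keys = {p.key for p in wgd}
    out = list(wgd)
    seen = set(wgd_keys)
    for p in ssd_list:
        if p.key in wgd_keys:
            logger.info("pair %s reported by both sources; labeled WGD", p.key)
            continue
        if p.key in seen:
            continue
        seen.add(p.key)
        out.append(p if p.origin == "SSD" else replace(p, origin="SSD"))
    return out


@dataclass
class FunnelReport:
    """Per-stage retention counts of the intragenic-pair pipeline."""

    counts: dict[str, int] = field(default_factory=dict)

    def log(self, stage: str, n: int) -> None:
        self.counts[stage] = n
        logger.info("funnel %-30s %d", stage, n)


def _relative_strand(mirna: MirnaGene, host: GeneInterval) -> str:
    return "same" if mirna.strand == host.strand else "opposite"


def find_intragenic_candidates(
    host_pairs: Sequence[DuplicatePair],
    host_genes: Mapping[str, GeneInterval],
    mirna_genes: Mapping[str, MirnaGene],
    funnel: FunnelReport | None = None,
    assembly_chroms: set[str] | None = None,
) -> tuple[list[tuple[DuplicatePair, HostAssignment, HostAssignment]], FunnelReport]:
    """Candidate intragenic duplicate miRNA pairs on duplicate host genes.

    For each duplicate host-gene pair, every cross product of bona-fide
    miRNAs fully contained in each host is a candidate; candidates whose
    members do not conserve the strand orientation relative to their hosts
    are dropped. Candidate pairs inherit the host pair's origin label.
    Returns (candidates, funnel) where each candidate carries its two host
    assignments.
    """
    funnel = funnel or FunnelReport()
    if assembly_chroms is not None:
        for label, chrom in [(h.gene_id, h.chrom) for h in host_genes.values()] + [
            (m.gene_id, m.chrom) for m in mirna_genes.values()
        ]:
            if chrom not in assembly_chroms:
                raise ValueError(f"{label} on chromosome {chrom!r} unknown to the assembly")
    # containment index: host -> contained bona-fide miRNAs
    contained: dict[str, list[MirnaGene]] = {}
    for hid, host in host_genes.items():
        inside = [
            m
            for m in mirna_genes.values()
            if m.bona_fide and m.contained_in(host.chrom, host.start, host.end)
        ]
        contained[hid] = sorted(inside, key=lambda m: m.gene_id)

    funnel.log("host_pairs", len(host_pairs))
    both_hosting = [
        hp
        for hp in host_pairs
        if contained.get(hp.member_a) and contained.get(hp.member_b)
    ]
    funnel.log("host_pairs_both_hosting", len(both_hosting))

    cross = []
    for hp in both_hosting:
        for ma in contained[hp.member_a]:
            for mb in contained[hp.member_b]:
                if ma.gene_id == mb.gene_id:
                    continue
                ha = HostAssignment(ma.gene_id, hp.member_a, _relative_strand(ma, host_genes[hp.member_a]))
                hb = HostAssignment(mb.gene_id, hp.member_b, _relative_strand(mb, host_genes[hp.member_b]))
                cross.append((hp, ma, mb, ha, hb))
    funnel.log("candidate_cross_products", len(cross))

    candidates = []
    for hp, ma, mb, ha, hb in cross:
        if ha.relative_strand != hb.relative_strand:
            continue
        pair = DuplicatePair(
            ma.gene_id, mb.gene_id, hp.origin, provenance=f"intragenic:{hp.member_a}|{hp.member_b}"
        )
        candidates.append((pair, ha, hb))
    funnel.log("strand_conserved", len(candidates))
    return candidates, funnel


def rbh_filter(
    candidates: Sequence[tuple[DuplicatePair, HostAssignment, HostAssignment]],
    mirna_genes: Mapping[str, MirnaGene],
    params: AlignmentParams = DEFAULT_PARAMS,
    score_fn: Callable[[MirnaGene, MirnaGene], float] | None = None,
    funnel: FunnelReport | None = None,
) -> tuple[list[DuplicatePair], FunnelReport]:
    """Keep only reciprocal best alignment hits within each host-gene pair.

    Where a host (or both) carries several miRNAs, a candidate (x in host
    A, y in host B) survives iff y is x's best-scoring partner among host
    B's candidate miRNAs AND x is y's best among host A's, under the
    seed-weighted alignment gene-pair similarity. Tied best hits are
    discarded (both pairs), not broken arbitrarily.
    """
    funnel = funnel or FunnelReport()
    if score_fn is None:
        score_fn = lambda a, b: pair_similarity(a, b, params)[0]  # noqa: E731

    by_host_pair: dict[tuple[str, str], list[tuple[DuplicatePair, str, str]]] = {}
    for pair, ha, hb in candidates:
        key = (ha.host_gene_id, hb.host_gene_id)
        by_host_pair.setdefault(key, []).append((pair, ha.mirna_gene_id, hb.mirna_gene_id))

    retained: list[DuplicatePair] = []
    n_tie_dropped = 0
    for key, cands in sorted(by_host_pair.items()):
        scores: dict[tuple[str, str], float] = {}
        a_side = sorted({a for _, a, _ in cands})
        b_side = sorted({b for _, _, b in cands})
        for _, a, b in cands:
            scores[(a, b)] = score_fn(mirna_genes[a], mirna_genes[b])

        def best(partners: list[float]) -> tuple[float, bool]:
            top = max(partners)
            return top, partners.count(top) > 1

        for pair, a, b in cands:
            row = [scores[(a, bb)] for bb in b_side if (a, bb) in scores]
            col = [scores[(aa, b)] for aa in a_side if (aa, b) in scores]
            best_row, tie_row = best(row)
            best_col, tie_col = best(col)
            if scores[(a, b)] == best_row == best_col:
                if tie_row or tie_col:
                    n_tie_dropped += 1
                    logger.info("RBH tie for %s-%s in host pair %s; dropped", a, b, key)
                    continue
                retained.append(pair)
    funnel.log("rbh_retained", len(retained))
    if n_tie_dropped:
        funnel.log("rbh_tie_dropped", n_tie_dropped)
    return retained, funnel


def stratify_pairs(
    catalog: Iterable[DuplicatePair],
    clade_order: Sequence[str] = DEFAULT_CLADE_ORDER,
    reference_clade: str = "Vertebrata",
) -> dict[str, list[DuplicatePair]]:
    """Partition a catalog by duplication timing and subgenome class.

    A pair is "pre-2R" iff its last-common-ancestor clade is strictly older
    than the reference clade (Vertebrata) in the configured ordering;
    otherwise "post-2R"; pairs without an LCA label go to "unknown_round".
    Subgenome classes are passed through as-is. The timing partition is
    exhaustive and disjoint.
    """
    order = {c: i for i, c in enumerate(clade_order)}
    if reference_clade not in order:
        raise ValueError(f"reference clade {reference_clade!r} not in clade order")
    ref = order[reference_clade]
    out: dict[str, list[DuplicatePair]] = {"pre_2R": [], "post_2R": [], "unknown_round": []}
    for p in catalog:
        if p.lca_rank == "NA":
            out["unknown_round"].append(p)
            continue
        if p.lca_rank not in order:
            raise ValueError(f"unknown clade label {p.lca_rank!r} for pair {p.key}")
        out["pre_2R" if order[p.lca_rank] < ref else "post_2R"].append(p)
        out.setdefault(f"subgenome_{p.subgenomes}", []).append(p)
    return out


def manual_overrides(
    catalog: Sequence[DuplicatePair],
    overrides: Iterable[Mapping[str, str]],
    known_genes: Iterable[str] | None = None,
) -> list[DuplicatePair]:
    """Apply curated additions/removals after all automatic steps.

    Each override is a mapping with keys ``action`` ("add"/"remove"),
    ``gene_a``, ``gene_b``, ``origin`` (for add) and ``reason``. Added
    pairs carry provenance ``manual:<reason>``. Removing a pair that is
    not in the catalog, or referencing an unknown gene, is an error.
    """
    known = set(known_genes) if known_genes is not None else None
    out = {p.key: p for p in catalog}
    for ov in overrides:
        a, b = ov["gene_a"], ov["gene_b"]
        if known is not None and (a not in known or b not in known):
            raise KeyError(f"override references unknown gene(s): {a}, {b}")
        key = (a, b) if a <= b else (b, a)
        action = ov["action"].lower()
        if action == "add":
            out[key] = DuplicatePair(
                a, b, ov.get("origin", "WGD"), provenance=f"manual:{ov.get('reason', '')}"
            )
        elif action == "remove":
            if key not in out:
                raise KeyError(f"cannot remove non-existent pair {key}")
            del out[key]
        else:
            raise ValueError(f"unknown override action {ov['action']!r}")
    return list(out.values())
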