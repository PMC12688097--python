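"""Curation of miRNA-target and protein-protein interaction networks.

Raw interaction exports (TarBase/MirDIP-style tables at the mature-miRNA
level, STRING/PrePPI-style PPI tables) are filtered on evidence quality,
collapsed from mature miRNAs to miRNA genes, and cleaned of artifacts:
duplicate miRNA pairs whose gene-level nodes are indistinguishable
(identical target sets, an inevitable consequence of identical mature
sequences) are flagged and excluded from downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from ohnomir.model import DuplicatePair, PpiNetwork, RegulatoryNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidenceFilter:
    """Evidence-quality criteria applied to a raw mature-level edge table.

    Mirrors the knobs of curated interaction databases: restriction to
    normal/primary tissue categories, direct-interaction evidence,
    high-throughput methods, and a top-score-quantile cut (e.g. 0.01 keeps
    the best-scored 1% of rows, the "Very high" class of integrative
    scores). Any criterion set to None is inactive.
    """

    allowed_categories: frozenset[str] | None = None
    require_direct_evidence: bool = False
    require_high_throughput: bool = False
    min_score_quantile: float | None = None
    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "category": "category",
            "evidence": "evidence",
            "method": "method",
            "score": "score",
        }
    )

    def __post_init__(self) -> None:
        q = self.min_score_quantile
        if q is not None and not (0 < q <= 1):
            raise ValueError("min_score_quantile must be in (0, 1]")


def filter_interactions(raw: pd.DataFrame, filt: EvidenceFilter) -> pd.DataFrame:
    """Apply evidence filters to a raw mature-level interaction table.

    The score-quantile threshold is computed over the full input table
    (before any other criterion); rows tied with the threshold value are
    kept, so the cut is deterministic regardless of row order.
    """
    cols = filt.columns
    active = []
    if filt.allowed_categories is not None:
        active.append(cols["category"])
    if filt.require_direct_evidence:
        active.append(cols["evidence"])
    if filt.require_high_throughput:
        active.append(cols["method"])
    if filt.min_score_quantile is not None:
        active.append(cols["score"])
    missing = [c for c in active if c not in raw.columns]
    if missing:
        raise KeyError(f"configured filter columns missing from table: {missing}")

    keep = pd.Series(True, index=raw.index)
    if filt.allowed_categories is not None:
        keep &= raw[cols["category"]].isin(filt.allowed_categories)
    if filt.require_direct_evidence:
        keep &= raw[cols["evidence"]] == "direct"
    if filt.require_high_throughput:
        keep &= raw[cols["method"]] == "HT"
    if filt.min_score_quantile is not None:
        threshold = raw[cols["score"]].quantile(1 - filt.min_score_quantile)
        keep &= raw[cols["score"]] >= threshold
    out = raw[keep]
    logger.info("evidence filter kept %d/%d rows", len(out), len(raw))
    return out


def collapse_to_gene_level(
    mature_edges: pd.DataFrame,
    mature_to_gene: Mapping[str, Iterable[str]],
    mature_col: str = "mirna_mature",
    target_col: str = "target_gene",
) -> RegulatoryNetwork:
    """Map mature-level edges onto miRNA genes, building the gene-level network.

    A mature produced by more than one miRNA gene (identical products of
    duplicate loci) expands to one edge per parent gene, restoring the
    distinction the mature-level databases lose. Unmapped matures are
    dropped with a warning; duplicate gene-level edges merge.
    """
    edges: set[tuple[str, str]] = set()
    unmapped: set[str] = set()
    for mature, target in zip(mature_edges[mature_col], mature_edges[target_col]):
        genes = mature_to_gene.get(mature)
        if not genes:
            unmapped.add(mature)
            continue
        for g in genes:
            edges.add((g, target))
    if unmapped:
        logger.warning("dropped %d unmapped mature miRNAs: %s ...", len(unmapped), sorted(unmapped)[:3])
    net = RegulatoryNetwork(edges)
    return net


def drop_indistinguishable_pairs(
    net: RegulatoryNetwork, catalog: Iterable[DuplicatePair]
) -> tuple[list[DuplicatePair], list[DuplicatePair]]:
    """Split a pair catalog into (analyzable, excluded-as-indistinguishable).

    A pair whose two gene-level nodes have the exact same target set cannot
    be told apart in the network (typically because their matures are
    identical), so it is excluded from enrichment and similarity analyses.
    Network nodes are retained; only the pair list is partitioned. Pairs
    with a member absent from the network are left in the analyzable list
    (restrict_to_network handles absence).
    """
    kept, excluded = [], []
    for p in catalog:
        in_net = p.member_a in net.mirna_nodes and p.member_b in net.mirna_nodes
        if in_net and net.targets_of(p.member_a) == net.targets_of(p.member_b):
            excluded.append(p)
        else:
            kept.append(p)
    if excluded:
        logger.info("excluded %d indistinguishable pairs", len(excluded))
    return kept, excluded


def restrict_to_network(
    catalog: Iterable[DuplicatePair], net: RegulatoryNetwork
) -> tuple[list[DuplicatePair], list[DuplicatePair]]:
    """Drop pairs with one or both members absent from the miRNA node set."""
    kept, dropped = [], []
    for p in catalog:
        if p.member_a in net.mirna_nodes and p.member_b in net.mirna_nodes:
            kept.append(p)
        else:
            dropped.append(p)
    logger.info("restricted catalog to network: kept %d, dropped %d", len(kept), len(dropped))
    return kept, dropped


def load_ppi(
    raw: pd.DataFrame,
    min_confidence: float,
    gene_a_col: str = "gene_a",
    gene_b_col: str = "gene_b",
    confidence_col: str = "confidence",
) -> PpiNetwork:
    """Build an undirected PPI network from a scored edge table.

    Keeps rows with confidence strictly above ``min_confidence`` (the
    STRING-style high-confidence convention, e.g. >960), merges (a,b)/(b,a)
    duplicates, and silently drops self-loops and malformed rows.
    """
    edges = []
    n_bad = 0
    for a, b, c in zip(raw[gene_a_col], raw[gene_b_col], raw[confidence_col]):
        try:
            conf = float(c)
        except (TypeError, ValueError):
            n_bad += 1
            continue
        if pd.isna(a) or pd.isna(b) or a == b:
            n_bad += 1
            continue
        if conf > min_confidence:
            edges.append((str(a), str(b)))
    if n_bad:
        logger.warning("skipped %d malformed/self-loop PPI rows", n_bad)
    return PpiNetwork(edges)
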