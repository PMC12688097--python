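"""Network-motif counting and enrichment against degree-preserving nulls.

Four motifs are scored for duplicate miRNA pairs (or single miRNAs):

* V-motif    — both miRNAs of a duplicate pair target a common gene.
* Bifan      — both miRNAs target both members of a duplicate target-gene
               pair (by default of the same duplication origin).
* PPI-bifan  — a bifan whose duplicate target pair also shares a
               protein-protein interaction edge (origin match mandatory).
* PPI-delta  — a single miRNA targets both members of a duplicate gene
               pair that interact at the protein level.

Enrichment is quantified per subject with a pairwise Z-score: the subject's
node identities are held fixed, its motif count is recomputed on each of an
ensemble of degree-preserving rewirings of the bipartite network, and
Z = (n - mean_null) / sd_null. Degenerate ensembles follow explicit rules:
sd = 0 with mean != 0 makes Z unevaluable and the subject is discarded;
sd = 0 with mean = 0 sets Z = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ohnomir.model import DuplicatePair, PpiNetwork, RegulatoryNetwork, wgd_priority_labels

logger = logging.getLogger(__name__)


class MotifType(str, Enum):
    V = "V"
    BIFAN = "BIFAN"
    PPI_BIFAN = "PPI_BIFAN"
    PPI_DELTA = "PPI_DELTA"


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-subject motif count, null statistics and Z-score."""

    subject: tuple[str, ...]  # (a, b) for pair motifs, (mirna,) for PPI-delta
    motif: MotifType
    n: int
    null_mean: float
    null_sd: float
    z: float | None
    status: str  # ok | zero_zero | discarded_sd_zero | absent_from_network


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_v(pair: DuplicatePair, net: RegulatoryNetwork) -> int:
    """Number of common targets of the two miRNAs of a pair."""
    return len(net.targets_of(pair.member_a) & net.targets_of(pair.member_b))


def _dedup_target_pairs(
    target_pairs: Iterable[DuplicatePair],
) -> dict[tuple[str, str], str]:
    """Unordered-deduplicated target pairs -> origin (first listing wins)."""
    out: dict[tuple[str, str], str] = {}
    for tp in target_pairs:
        out.setdefault(tp.key, tp.origin)
    return out


def count_bifan(
    pair: DuplicatePair,
    net: RegulatoryNetwork,
    target_pairs: Iterable[DuplicatePair],
    match_origin: bool = True,
) -> int:
    """Distinct duplicate target pairs fully co-targeted by both miRNAs.

    With ``match_origin`` (default) only target pairs whose duplication
    origin equals the miRNA pair's origin are counted.
    """
    common = net.targets_of(pair.member_a) & net.targets_of(pair.member_b)
    if len(common) < 2:
        return 0
    count = 0
    for (g, h), origin in _dedup_target_pairs(target_pairs).items():
        if match_origin and origin != pair.origin:
            continue
        if g in common and h in common:
            count += 1
    return count


def count_ppi_bifan(
    pair: DuplicatePair,
    net: RegulatoryNetwork,
    target_pairs: Iterable[DuplicatePair],
    ppi: PpiNetwork,
) -> int:
    """Bifans whose target pair also shares a PPI edge (origin match mandatory)."""
    common = net.targets_of(pair.member_a) & net.targets_of(pair.member_b)
    if len(common) < 2:
        return 0
    count = 0
    for (g, h), origin in _dedup_target_pairs(target_pairs).items():
        if origin != pair.origin:
            continue
        if g in common and h in common and ppi.has_edge(g, h):
            count += 1
    return count


def count_ppi_delta(
    mirna: str,
    net: RegulatoryNetwork,
    target_pairs: Iterable[DuplicatePair],
    ppi: PpiNetwork,
) -> int:
    """Duplicate PPI-coupled target pairs both targeted by one miRNA."""
    targets = net.targets_of(mirna)
    if len(targets) < 2:
        return 0
    count = 0
    for (g, h) in _dedup_target_pairs(target_pairs):
        if g in targets and h in targets and ppi.has_edge(g, h):
            count += 1
    return count


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

def rewire(
    net: RegulatoryNetwork,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> RegulatoryNetwork:
    """Degree-preserving randomization of a bipartite network.

    Repeated double-edge swaps: two edges (m1,t1), (m2,t2) are replaced by
    (m1,t2), (m2,t1) unless the swap would create a duplicate edge or is a
    no-op. Every miRNA keeps its outdegree and every target its indegree
    exactly; failed proposals are skipped. The result depends only on the
    input network and the generator state.
    """
    edges = sorted(net.edges)  # stable order => reproducible given the rng
    edge_set = set(edges)
    n = len(edges)
    if n < 2:
        return RegulatoryNetwork(edges)
    n_attempts = swaps_per_edge * n
    picks = rng.integers(0, n, size=(n_attempts, 2))
    for i, j in picks:
        if i == j:
            continue
        m1, t1 = edges[i]
        m2, t2 = edges[j]
        if t1 == t2 or m1 == m2:
            continue
        e1, e2 = (m1, t2), (m2, t1)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.remove((m1, t1))
        edge_set.remove((m2, t2))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
    return RegulatoryNetwork(edge_set)


# ---------------------------------------------------------------------------
# Z-scores
# ---------------------------------------------------------------------------

def pairwise_z(
    n: int,
    null_counts: Sequence[int],
    subject: tuple[str, ...] = ("?",),
    motif: MotifType = MotifType.V,
    sd_ddof: int = 0,
) -> EnrichmentResult:
    """Z-score of a subject's real count against its null-ensemble counts.

    Z = (n - mean_null) / sd_null with the population (ddof=0) standard
    deviation by default. Degenerate ensembles: sd=0 & mean!=0 -> the
    subject is discarded (Z unevaluable); sd=0 & mean=0 -> Z = 0.
    """
    counts = np.asarray(null_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("null_counts must be non-empty")
    mean = float(counts.mean())
    sd = float(counts.std(ddof=sd_ddof))
    if sd > 0:
        return EnrichmentResult(subject, motif, n, mean, sd, (n - mean) / sd, "ok")
    if mean != 0:
        return EnrichmentResult(subject, motif, n, mean, sd, None, "discarded_sd_zero")
    return EnrichmentResult(subject, motif, n, mean, sd, 0.0, "zero_zero")


def _count_for_subject(
    subject: tuple[str, ...],
    motif: MotifType,
    net: RegulatoryNetwork,
    target_pairs: Sequence[DuplicatePair],
    ppi: PpiNetwork | None,
    pair_by_subject: dict[tuple[str, ...], DuplicatePair],
    match_origin: bool,
) -> int:
    if motif is MotifType.V:
        return count_v(pair_by_subject[subject], net)
    if motif is MotifType.BIFAN:
        return count_bifan(pair_by_subject[subject], net, target_pairs, match_origin)
    if motif is MotifType.PPI_BIFAN:
        return count_ppi_bifan(pair_by_subject[subject], net, target_pairs, ppi)
    if motif is MotifType.PPI_DELTA:
        raise AssertionError("PPI-delta handled separately")
    raise ValueError(f"unknown motif {motif}")


V_BINS = ((0, 0, "0"), (1, 50, "1-50"), (51, None, ">50"))


def bin_counts(counts: Iterable[int], motif: MotifType) -> dict[str, int]:
    """Motif-count class tallies: {0, 1-50, >50} for V, {0, >=1} otherwise."""
    counts = list(counts)
    if motif is MotifType.V:
        out = {}
        for lo, hi, label in V_BINS:
            out[label] = sum(1 for c in counts if c >= lo and (hi is None or c <= hi))
        return out
    return {"0": sum(1 for c in counts if c == 0), ">=1": sum(1 for c in counts if c >= 1)}


def enrichment_run(
    catalog: Sequence[DuplicatePair],
    net: RegulatoryNetwork,
    motif: MotifType,
    target_pairs: Sequence[DuplicatePair] = (),
    ppi: PpiNetwork | None = None,
    n_replicates: int = 1000,
    swaps_per_edge: int = 10,
    seed: int = 0,
    match_origin: bool = True,
    sd_ddof: int = 0,
    max_discard_fraction: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Per-subject motif enrichment against a degree-preserving null ensemble.

    Subjects are duplicate pairs, except for PPI-delta where each distinct
    miRNA of the catalog is a subject labeled with WGD priority. Subjects
    with a member absent from the network are reported with status
    ``absent_from_network``. Null counts are streamed replicate by
    replicate; each replicate's rewiring is seeded from a spawn of ``seed``
    so runs are reproducible.

    Returns the per-subject result table and a summary dict with binned
    count classes per origin group and discard bookkeeping.
    """
    if motif in (MotifType.PPI_BIFAN, MotifType.PPI_DELTA) and ppi is None:
        raise ValueError(f"{motif.value} requires a PPI network")

    if motif is MotifType.PPI_DELTA:
        labels = wgd_priority_labels(catalog)
        subjects = [((m,), origin) for m, origin in sorted(labels.items())]
    else:
        seen: dict[tuple[str, str], str] = {}
        for p in catalog:
            seen.setdefault(p.key, p.origin)
        subjects = [(k, origin) for k, origin in seen.items()]
    pair_by_subject = {p.key: p for p in catalog}

    def present(subject: tuple[str, ...]) -> bool:
        return all(m in net.mirna_nodes for m in subject)

    def real_count(subject: tuple[str, ...], network: RegulatoryNetwork) -> int:
        if motif is MotifType.PPI_DELTA:
            return count_ppi_delta(subject[0], network, target_pairs, ppi)
        return _count_for_subject(
            subject, motif, network, target_pairs, ppi, pair_by_subject, match_origin
        )

    live = [(s, o) for s, o in subjects if present(s)]
    absent = [(s, o) for s, o in subjects if not present(s)]

    n_real = {s: real_count(s, net) for s, _ in live}
    null_counts: dict[tuple[str, ...], list[int]] = {s: [] for s, _ in live}

    child_seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    for child in child_seeds:
        replicate = rewire(net, np.random.default_rng(child), swaps_per_edge)
        for s, _ in live:
            null_counts[s].append(real_count(s, replicate))

    rows = []
    for s, origin in live:
        res = pairwise_z(n_real[s], null_counts[s], s, motif, sd_ddof)
        rows.append(
            {
                "subject": "|".join(s),
                "origin": origin,
                "motif": motif.value,
                "n": res.n,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "z": res.z,
                "status": res.status,
            }
        )
    for s, origin in absent:
        rows.append(
            {
                "subject": "|".join(s),
                "origin": origin,
                "motif": motif.value,
                "n": 0,
                "null_mean": np.nan,
                "null_sd": np.nan,
                "z": None,
                "status": "absent_from_network",
            }
        )
    table = pd.DataFrame(rows)
    table["z"] = pd.to_numeric(table["z"])

    evaluable = table[table.status.isin(["ok", "zero_zero", "discarded_sd_zero"])]
    n_discarded = int((table.status == "discarded_sd_zero").sum())
    discard_fraction = n_discarded / len(evaluable) if len(evaluable) else 0.0
    if discard_fraction > max_discard_fraction:
        logger.warning(
            "discarded %.1f%% of subjects (sd=0, mean!=0), above the %.1f%% warning level",
            100 * discard_fraction,
            100 * max_discard_fraction,
        )

    summary: dict = {
        "motif": motif.value,
        "n_subjects": len(subjects),
        "n_absent_from_network": len(absent),
        "n_discarded_sd_zero": n_discarded,
        "discard_fraction": discard_fraction,
        "bins_by_origin": {},
        "median_z_by_origin": {},
    }
    for origin in ("WGD", "SSD"):
        grp = evaluable[evaluable.origin == origin]
        summary["bins_by_origin"][origin] = bin_counts(grp["n"], motif)
        z = grp["z"].dropna()
        summary["median_z_by_origin"][origin] = float(z.median()) if len(z) else None
    return table, summary
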