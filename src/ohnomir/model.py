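"""Core domain types shared across the analysis modules."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

VALID_ORIGINS = frozenset({"WGD", "SSD"})
VALID_ARMS = frozenset({"5p", "3p", "unknown"})


@dataclass(frozen=True)
class MatureMirna:
    """A processed ~19-25 nt mature miRNA (one arm of a precursor hairpin)."""

    mature_id: str
    sequence: str
    arm: str = "unknown"
    parent_gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"mature {self.mature_id!r} has an empty sequence")
        if self.arm not in VALID_ARMS:
            raise ValueError(f"unknown arm {self.arm!r} for {self.mature_id!r}")


@dataclass(frozen=True)
class MirnaGene:
    """A miRNA gene locus with its mature products.

    Coordinates are 0-based, half-open (BED convention).
    """

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    matures: tuple[MatureMirna, ...] = ()
    bona_fide: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    def contained_in(self, chrom: str, start: int, end: int) -> bool:
        """True if this gene's interval lies fully within [start, end) on chrom."""
        return self.chrom == chrom and start <= self.start and self.end <= end


@dataclass(frozen=True)
class DuplicatePair:
    """An unordered pair of duplicate genes (miRNA or protein-coding).

    ``origin`` records the duplication mode (WGD = whole-genome duplication,
    SSD = small-scale duplication); ``round`` the WGD round (1R/2R) when
    known; ``subgenomes`` the parental-subgenome class of the allotetraploid
    2R event. Members are stored in sorted order so pair identity is
    order-free.
    """

    member_a: str
    member_b: str
    origin: str
    round: str = "NA"
    subgenomes: str = "NA"
    lca_rank: str = "NA"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.member_a == self.member_b:
            raise ValueError(f"self-pair {self.member_a!r} rejected")
        if self.origin not in VALID_ORIGINS:
            raise ValueError(f"origin must be WGD or SSD, got {self.origin!r}")
        a, b = self.member_a, self.member_b
        if a > b:
            object.__setattr__(self, "member_a", b)
            object.__setattr__(self, "member_b", a)

    @property
    def members(self) -> frozenset[str]:
        return frozenset((self.member_a, self.member_b))

    @property
    def key(self) -> tuple[str, str]:
        return (self.member_a, self.member_b)


@dataclass(frozen=True)
class HostAssignment:
    """A miRNA gene contained inside a host protein-coding gene."""

    mirna_gene_id: str
    host_gene_id: str
    relative_strand: str  # "same" | "opposite"

    def __post_init__(self) -> None:
        if self.relative_strand not in {"same", "opposite"}:
            raise ValueError(f"relative_strand must be same/opposite, got {self.relative_strand!r}")


class RegulatoryNetwork:
    """Bipartite gene-level miRNA -> target network (unweighted, deduplicated)."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        adj: dict[str, set[str]] = {}
        edge_set: set[tuple[str, str]] = set()
        for m, t in edges:
            edge_set.add((m, t))
            adj.setdefault(m, set()).add(t)
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)
        self._adj = {m: frozenset(ts) for m, ts in adj.items()}
        self.mirna_nodes: frozenset[str] = frozenset(self._adj)
        self.target_nodes: frozenset[str] = frozenset(t for _, t in edge_set)
        overlap = self.mirna_nodes & self.target_nodes
        if overlap:
            raise ValueError(f"network is not bipartite; shared node ids: {sorted(overlap)[:5]}")

    def targets_of(self, mirna: str) -> frozenset[str]:
        return self._adj.get(mirna, frozenset())

    def outdegree(self, mirna: str) -> int:
        return len(self._adj.get(mirna, ()))

    def degree_sequence(self) -> tuple[Mapping[str, int], Mapping[str, int]]:
        """Per-node degrees as (miRNA outdegrees, target indegrees)."""
        out = {m: len(ts) for m, ts in self._adj.items()}
        indeg: dict[str, int] = {}
        for _, t in self.edges:
            indeg[t] = indeg.get(t, 0) + 1
        return out, indeg

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, node: str) -> bool:
        return node in self.mirna_nodes or node in self.target_nodes

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegulatoryNetwork) and self.edges == other.edges

    def __hash__(self) -> int:
        return hash(self.edges)


class PpiNetwork:
    """Undirected protein-protein interaction network (no self-loops)."""

    def __init__(self, edges: Iterable[tuple[str, str]]):
        edge_set: set[tuple[str, str]] = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop {a!r} rejected")
            edge_set.add((a, b) if a <= b else (b, a))
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)
        self.nodes: frozenset[str] = frozenset(n for e in edge_set for n in e)

    def has_edge(self, a: str, b: str) -> bool:
        return ((a, b) if a <= b else (b, a)) in self.edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def wgd_priority_labels(pairs: Iterable[DuplicatePair]) -> dict[str, str]:
    """Per-miRNA duplication label with WGD priority.

    A miRNA appearing in both a WGD pair and an SSD pair is labeled WGD, so
    the per-miRNA WGD and SSD sets stay disjoint.
    """
    labels: dict[str, str] = {}
    for p in pairs:
        for m in (p.member_a, p.member_b):
            if p.origin == "WGD" or labels.get(m) is None:
                labels[m] = p.origin
    return labels
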