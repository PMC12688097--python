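"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: the alignment
oracle enumerates every monotone position matching (equivalent to
enumerating all global alignments, since gap ordering does not affect the
score), and the motif oracles enumerate node triples/quadruples directly.
"""

from __future__ import annotations

import itertools

import numpy as np

from ohnomir.alignment import AlignmentParams
from ohnomir.model import DuplicatePair, PpiNetwork, RegulatoryNetwork


def oracle_align_score(a: str, b: str, params: AlignmentParams) -> int:
    """Maximum score over all global alignments, by exhaustive enumeration.

    A global alignment is a monotone matching of positions (matched pairs
    are substitution columns; every unmatched character is a gap column),
    so the maximum over alignments is the maximum over matchings of
    sum(column scores) + gap_penalty * (len(a) + len(b) - 2k).
    """
    m, n = len(a), len(b)
    S = np.empty((m, n), dtype=int)
    for i in range(m):
        for j in range(n):
            S[i, j] = params.column_score(a[i], b[j], i + 1, j + 1)
    gap = params.gap_penalty
    best = gap * (m + n)  # the all-gap alignment (k = 0)
    for k in range(1, min(m, n) + 1):
        base = gap * (m + n - 2 * k)
        combos_b = np.array(list(itertools.combinations(range(n), k)))
        idx = np.arange(k)
        for ai in itertools.combinations(range(m), k):
            vals = S[np.asarray(ai)][idx, combos_b].sum(axis=1)
            cand = base + int(vals.max())
            if cand > best:
                best = cand
    return best


def oracle_count_v(pair: DuplicatePair, net: RegulatoryNetwork) -> int:
    """V-motifs by enumerating every target node."""
    return sum(
        1
        for t in net.target_nodes
        if t in net.targets_of(pair.member_a) and t in net.targets_of(pair.member_b)
    )


def oracle_count_bifan(
    pair: DuplicatePair,
    net: RegulatoryNetwork,
    target_pairs: list[DuplicatePair],
    match_origin: bool = True,
) -> int:
    """Bifans by enumerating all (miRNA pair) x (target pair) quadruples."""
    seen: set[tuple[str, str]] = set()
    count = 0
    for tp in target_pairs:
        if tp.key in seen:
            continue
        seen.add(tp.key)
        if match_origin and tp.origin != pair.origin:
            continue
        g, h = tp.key
        if all(
            t in net.targets_of(m)
            for t in (g, h)
            for m in (pair.member_a, pair.member_b)
        ):
            count += 1
    return count


def oracle_count_ppi_bifan(
    pair: DuplicatePair,
    net: RegulatoryNetwork,
    target_pairs: list[DuplicatePair],
    ppi: PpiNetwork,
) -> int:
    seen: set[tuple[str, str]] = set()
    count = 0
    for tp in target_pairs:
        if tp.key in seen:
            continue
        seen.add(tp.key)
        if tp.origin != pair.origin:
            continue
        g, h = tp.key
        if ppi.has_edge(g, h) and all(
            t in net.targets_of(m)
            for t in (g, h)
            for m in (pair.member_a, pair.member_b)
        ):
            count += 1
    return count


def oracle_count_ppi_delta(
    mirna: str,
    net: RegulatoryNetwork,
    target_pairs: list[DuplicatePair],
    ppi: PpiNetwork,
) -> int:
    seen: set[tuple[str, str]] = set()
    count = 0
    for tp in target_pairs:
        if tp.key in seen:
            continue
        seen.add(tp.key)
        g, h = tp.key
        if g in net.targets_of(mirna) and h in net.targets_of(mirna) and ppi.has_edge(g, h):
            count += 1
    return count


def random_bipartite(
    rng: np.random.Generator, n_mirnas: int, n_targets: int, p_edge: float
) -> RegulatoryNetwork:
    mirnas = [f"m{i}" for i in range(n_mirnas)]
    targets = [f"t{i}" for i in range(n_targets)]
    edges = [
        (m, t) for m in mirnas for t in targets if rng.random() < p_edge
    ]
    # keep every miRNA present
    for m in mirnas:
        if not any(e[0] == m for e in edges):
            edges.append((m, targets[int(rng.integers(n_targets))]))
    return RegulatoryNetwork(edges)
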