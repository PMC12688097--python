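"""Seed-weighted global alignment of mature miRNA sequences.

Target recognition by a miRNA is dominated by its seed region (nucleotides
2-8 from the 5' end in the canonical 7mer definition), so when scoring the
similarity of two mature miRNAs a substitution inside the seed should count
far more than one outside it. This module implements a Needleman-Wunsch
global alignment whose match/mismatch weight depends on whether the column
touches the seed window of either sequence: +/-5 in seed, +/-1 outside, by
default, with a uniform gap penalty.

Gene-pair similarity is the maximum alignment score over the Cartesian
product of the two genes' mature products.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ohnomir.model import MirnaGene

_RNA = frozenset("ACGU")

GAP, UP, LEFT, DIAG = 0, 1, 2, 3  # traceback codes (DIAG preferred)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for the seed-weighted global alignment.

    Positions are 1-based from the 5' end of each mature. A substitution
    column is "in seed" if the consumed nucleotide of either sequence lies
    in [seed_start, seed_end] of its own sequence. In-seed columns score
    +/-in_seed_weight (match/mismatch), out-of-seed columns
    +/-out_seed_weight, and every gap column scores gap_penalty (end gaps
    included).
    """

    seed_start: int = 2
    seed_end: int = 8
    in_seed_weight: int = 5
    out_seed_weight: int = 1
    gap_penalty: int = -2

    def __post_init__(self) -> None:
        if self.seed_start > self.seed_end:
            raise ValueError("seed_start must be <= seed_end")
        if self.seed_start < 1:
            raise ValueError("seed positions are 1-based")
        if self.in_seed_weight <= 0 or self.out_seed_weight <= 0:
            raise ValueError("weights must be positive magnitudes")
        if self.gap_penalty > 0:
            raise ValueError("gap_penalty must be <= 0")

    def in_seed(self, pos: int) -> bool:
        """Whether 1-based position ``pos`` lies in the seed window."""
        return self.seed_start <= pos <= self.seed_end

    def column_score(self, a: str | None, b: str | None, pos_a: int, pos_b: int) -> int:
        """Score of one alignment column.

        ``a``/``b`` are the consumed nucleotides (None for a gap);
        ``pos_a``/``pos_b`` the 1-based consumed positions (ignored on the
        gapped side).
        """
        if a is None or b is None:
            return self.gap_penalty
        w = (
            self.in_seed_weight
            if self.in_seed(pos_a) or self.in_seed(pos_b)
            else self.out_seed_weight
        )
        return w if a == b else -w


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment with its score and per-column classification."""

    score: int
    aligned_a: str
    aligned_b: str
    column_classes: tuple[str, ...]  # "seed" | "out" | "gap" per column

    def recompute_score(self, params: AlignmentParams) -> int:
        """Re-derive the score from the aligned strings (consistency check)."""
        total = 0
        ia = ib = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
            total += params.column_score(
                None if ca == "-" else ca, None if cb == "-" else cb, ia, ib
            )
        return total


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; reject non-nucleotide characters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - _RNA
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)} in sequence {seq!r}")
    return s


def align_matures(
    seq_a: str, seq_b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> AlignmentResult:
    """Optimal seed-weighted global alignment of two mature miRNA sequences.

    Returns the maximum-score global alignment; among co-optimal tracebacks
    the diagonal move is preferred over consuming ``seq_a`` (up) over
    consuming ``seq_b`` (left), which fixes a deterministic alignment
    without affecting the score.
    """
    a = normalize_rna(seq_a)
    b = normalize_rna(seq_b)
    m, n = len(a), len(b)
    gap = params.gap_penalty

    score = np.empty((m + 1, n + 1), dtype=np.int64)
    move = np.zeros((m + 1, n + 1), dtype=np.int8)
    score[0, :] = gap * np.arange(n + 1)
    score[:, 0] = gap * np.arange(m + 1)
    move[0, 1:] = LEFT
    move[1:, 0] = UP

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = score[i - 1, j - 1] + params.column_score(a[i - 1], b[j - 1], i, j)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            best = max(sub, up, left)
            score[i, j] = best
            move[i, j] = DIAG if best == sub else (UP if best == up else LEFT)

    out_a: list[str] = []
    out_b: list[str] = []
    classes: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == DIAG:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            classes.append("seed" if params.in_seed(i) or params.in_seed(j) else "out")
            i -= 1
            j -= 1
        elif mv == UP:
            out_a.append(a[i - 1])
            out_b.append("-")
            classes.append("gap")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            classes.append("gap")
            j -= 1

    return AlignmentResult(
        score=int(score[m, n]),
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        column_classes=tuple(reversed(classes)),
    )


def pair_similarity(
    gene_a: MirnaGene, gene_b: MirnaGene, params: AlignmentParams = DEFAULT_PARAMS
) -> tuple[int, str, str]:
    """Best alignment score over all mature x mature combinations of two genes.

    Returns ``(best_score, mature_id_a, mature_id_b)``. The result is
    symmetric in the gene arguments; ties on score are broken by mature id
    so the reported argmax pair is deterministic.
    """
    if not gene_a.matures or not gene_b.matures:
        empty = gene_a.gene_id if not gene_a.matures else gene_b.gene_id
        raise ValueError(f"gene {empty!r} has no mature sequences")
    best: tuple[int, str, str] | None = None
    for ma, mb in itertools.product(gene_a.matures, gene_b.matures):
        s = align_matures(ma.sequence, mb.sequence, params).score
        cand = (s, ma.mature_id, mb.mature_id)
        if best is None or s > best[0] or (s == best[0] and cand[1:] < best[1:]):
            best = cand
    return best


SEED_WINDOWS = {6: (2, 7), 7: (2, 8), 8: (2, 9)}


def sensitivity_sweep(
    gene_pairs: Sequence[tuple[MirnaGene, MirnaGene]],
    seed_lengths: Iterable[int] = (6, 7, 8),
    in_seed_weights: Iterable[int] = (3, 4, 5, 6),
    base_params: AlignmentParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Score each gene pair under every (seed length, in-seed weight) setting.

    Seed lengths map to 1-based windows 6mer=2-7, 7mer=2-8, 8mer=2-9.
    Returns a long-format table with one row per (pair, setting).
    """
    rows = []
    for k in seed_lengths:
        if k not in SEED_WINDOWS:
            raise ValueError(f"unsupported seed length {k}; choose from {sorted(SEED_WINDOWS)}")
        start, end = SEED_WINDOWS[k]
        for w in in_seed_weights:
            params = replace(base_params, seed_start=start, seed_end=end, in_seed_weight=w)
            for ga, gb in gene_pairs:
                s, ma, mb = pair_similarity(ga, gb, params)
                rows.append(
                    {
                        "gene_a": ga.gene_id,
                        "gene_b": gb.gene_id,
                        "seed_length": k,
                        "in_seed_weight": w,
                        "score": s,
                        "mature_a": ma,
                        "mature_b": mb,
                    }
                )
    return pd.DataFrame(rows)


def sweep_rank_correlation(sweep: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of pair scores between every pair of settings.

    Quantifies how stable the pair ranking is across seed-length / weight
    choices; returns a square matrix indexed by "(seed_length)mer/±(weight)"
    labels.
    """
    from scipy.stats import spearmanr

    pivot = sweep.assign(
        setting=lambda d: d.seed_length.astype(str) + "mer/w" + d.in_seed_weight.astype(str)
    ).pivot_table(index=["gene_a", "gene_b"], columns="setting", values="score")
    settings = list(pivot.columns)
    mat = pd.DataFrame(np.eye(len(settings)), index=settings, columns=settings)
    for s1, s2 in itertools.combinations(settings, 2):
        rho = spearmanr(pivot[s1], pivot[s2]).statistic
        mat.loc[s1, s2] = mat.loc[s2, s1] = rho
    return mat
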