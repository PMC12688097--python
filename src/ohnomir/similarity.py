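"""Target-set and expression similarity between duplicate miRNAs.

Target overlap is measured with the Sørensen-Dice coefficient
S(A,B) = 2|A∩B| / (|A|+|B|) over gene-level target sets. Expression
similarity uses 1 - cosine similarity between per-sample-normalized
expression vectors, after summing mature isoforms into their precursor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ohnomir.model import DuplicatePair, RegulatoryNetwork


def dice(targets_a: set | frozenset, targets_b: set | frozenset) -> float:
    """Sørensen-Dice coefficient 2|A∩B|/(|A|+|B|).

    0 when the target sets are disjoint, 1 when identical. With exactly one
    empty set the formula is well defined and returns 0; with both sets
    empty the coefficient is undefined and NaN is returned (reported as
    missing downstream).
    """
    na, nb = len(targets_a), len(targets_b)
    if na == 0 and nb == 0:
        return math.nan
    return 2.0 * len(set(targets_a) & set(targets_b)) / (na + nb)


def pair_dice_table(pairs: Iterable[DuplicatePair], net: RegulatoryNetwork) -> pd.DataFrame:
    """Dice coefficient of every pair's target sets in a curated network.

    Pairs with a member absent from the network get status
    ``absent_from_network`` and a missing coefficient.
    """
    rows = []
    for p in pairs:
        present = p.member_a in net.mirna_nodes and p.member_b in net.mirna_nodes
        rows.append(
            {
                "member_a": p.member_a,
                "member_b": p.member_b,
                "origin": p.origin,
                "round": p.round,
                "dice": dice(net.targets_of(p.member_a), net.targets_of(p.member_b))
                if present
                else math.nan,
                "status": "ok" if present else "absent_from_network",
            }
        )
    return pd.DataFrame(rows)


def normalize_expression(
    raw: pd.DataFrame, isoform_to_precursor: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Collapse mature isoforms into precursors and normalize per sample.

    Rows are mature isoforms (or precursors if no map is given), columns are
    samples. Isoform rows mapping to the same precursor are summed, then
    each column is divided by its total so every sample sums to 1.
    """
    if (raw.values < 0).any():
        raise ValueError("expression counts must be non-negative")
    mat = raw
    if isoform_to_precursor is not None:
        missing = [r for r in raw.index if r not in isoform_to_precursor]
        if missing:
            raise KeyError(f"isoforms without a precursor mapping: {missing[:5]}")
        mat = raw.groupby([isoform_to_precursor[r] for r in raw.index]).sum()
    totals = mat.sum(axis=0)
    zero_cols = totals.index[totals == 0].tolist()
    if zero_cols:
        raise ValueError(f"cannot normalize all-zero sample columns: {zero_cols[:5]}")
    return mat / totals


@dataclass(frozen=True)
class PairDistance:
    """1 - cosine similarity between two miRNAs' expression vectors."""

    member_a: str
    member_b: str
    distance: float  # NaN when a vector is all-zero (cosine undefined)
    context: str = "all"


def expression_distance(vec_a: Sequence[float], vec_b: Sequence[float]) -> float:
    """1 - cosine similarity; in [0, 1] for non-negative vectors.

    Returns NaN if either vector is all-zero (the angle is undefined);
    callers report those pairs as missing rather than maximally distant.
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("expression vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return math.nan
    return float(1.0 - (a @ b) / (na * nb))


def pair_expression_distances(
    pairs: Iterable[DuplicatePair], expr: pd.DataFrame, context: str = "all"
) -> list[PairDistance]:
    """Expression distance for each pair whose members are both in the matrix."""
    out = []
    for p in pairs:
        if p.member_a not in expr.index or p.member_b not in expr.index:
            continue
        d = expression_distance(expr.loc[p.member_a].values, expr.loc[p.member_b].values)
        out.append(PairDistance(p.member_a, p.member_b, d, context))
    return out


def group_expression_summary(
    expr: pd.DataFrame,
    labels: Mapping[str, str],
    tissue_of_sample: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-tissue median expression of the WGD vs SSD groups.

    ``labels`` maps miRNA id -> {"WGD", "SSD"} (WGD-priority labels keep
    the groups disjoint). miRNAs missing from the matrix are skipped with
    a count in the output attrs. A Kolmogorov-Smirnov two-sample statistic
    is reported per tissue when both groups have >= 2 members.
    """
    present = {m: g for m, g in labels.items() if m in expr.index}
    skipped = len(labels) - len(present)
    wgd = [m for m, g in present.items() if g == "WGD"]
    ssd = [m for m, g in present.items() if g == "SSD"]
    if tissue_of_sample is None:
        tissue_of_sample = {c: c for c in expr.columns}
    rows = []
    tissues = sorted(set(tissue_of_sample.values()))
    for tissue in tissues:
        cols = [c for c in expr.columns if tissue_of_sample[c] == tissue]
        wgd_vals = expr.loc[wgd, cols].values.ravel()
        ssd_vals = expr.loc[ssd, cols].values.ravel()
        row = {
            "tissue": tissue,
            "median_wgd": float(np.median(wgd_vals)) if len(wgd_vals) else math.nan,
            "median_ssd": float(np.median(ssd_vals)) if len(ssd_vals) else math.nan,
            "n_wgd": len(wgd),
            "n_ssd": len(ssd),
        }
        if len(wgd) >= 2 and len(ssd) >= 2:
            ks = stats.ks_2samp(wgd_vals, ssd_vals)
            row["ks_statistic"] = float(ks.statistic)
            row["ks_pvalue"] = float(ks.pvalue)
        else:
            row["ks_statistic"] = math.nan
            row["ks_pvalue"] = math.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_label_missing_from_matrix"] = skipped
    return out


def distance_by_motif_context(
    distances: Iterable[PairDistance], enrichment: pd.DataFrame
) -> pd.DataFrame:
    """Stratify pair expression distances by motif involvement.

    ``enrichment`` is a per-subject motif table (columns ``member_a``,
    ``member_b``, ``motif``, ``n``). Each distance row is tagged with a
    boolean per motif type: whether the pair participates in >= 1 motif of
    that type. Strata are therefore subsets of the full pair set.
    """
    base = pd.DataFrame(
        [
            {"member_a": d.member_a, "member_b": d.member_b, "distance": d.distance}
            for d in distances
        ]
    )
    if base.empty:
        return base
    for motif in sorted(enrichment["motif"].unique()):
        sub = enrichment[(enrichment["motif"] == motif) & (enrichment["n"] >= 1)]
        involved = set(zip(sub["member_a"], sub["member_b"]))
        base[f"in_{motif.lower()}"] = [
            (a, b) in involved or (b, a) in involved
            for a, b in zip(base["member_a"], base["member_b"])
        ]
    return base
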