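"""Synthetic data generator with planted, recoverable structure.

Emulates the five input classes of the analysis — genome annotations with
intragenic miRNAs, mature sequences, mature-level miRNA-target exports,
PPI edge tables and expression matrices — with the statistical structure
the real data exhibit planted under explicit control:

* heavy-tailed miRNA outdegrees (discrete power law),
* higher seed conservation and target overlap (Sørensen-Dice) for WGD
  pairs than SSD pairs,
* planted bifans whose duplicate target pairs can carry PPI edges,
* a positive log-scale expression shift for WGD-derived miRNAs,
* a configured fraction of duplicate miRNA pairs placed inside duplicate
  host-gene pairs with matching relative strand.

Every planted feature is recorded in a ground-truth manifest so each
downstream stage has an exact recovery oracle. All randomness flows from
``rng_seed``; each generation stage draws from its own named substream, so
outputs are reproducible and independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ohnomir.model import DuplicatePair, HostAssignment, MatureMirna, MirnaGene

NUCLEOTIDES = np.array(list("ACGU"))

# genome layout constants: one chromosome per 50 host genes, fixed spacing,
# so containment queries are trivial and deterministic
HOST_LEN = 10_000
HOST_GAP = 5_000
HOSTS_PER_CHROM = 50
MIRNA_LEN = 100
MIRNA_OFFSET = 2_000
DECOY_OFFSET = 6_000
INTERGENIC_PER_CHROM = 100
INTERGENIC_SPACING = 1_000

# stage constants for independent rng substreams
_STAGE_ANNOTATIONS, _STAGE_SEQUENCES, _STAGE_NETWORK, _STAGE_EXPRESSION = 11, 12, 13, 14

WGD_LCA_POOL = ("Olfactores", "Vertebrata", "Gnathostomata")
SSD_LCA_POOL = ("Bilateria", "Chordata", "Vertebrata", "Euteleostomi", "Mammalia", "Eutheria")
SUBGENOME_CLASSES = ("alpha-alpha", "beta-beta", "alpha-beta")


class SizingError(ValueError):
    """A configuration that cannot be packed into the synthetic genome."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study conditions.

    Defaults reproduce the qualitative orderings of the real data: WGD
    pairs more seed-conserved, higher target overlap, bifan-planted and
    more expressed than SSD pairs.
    """

    n_mirna_genes: int = 450
    n_target_genes: int = 2000
    n_wgd_pairs: int = 100
    n_ssd_pairs: int = 100
    frac_intragenic: float = 0.15
    seed_conservation_wgd: float = 0.95
    seed_conservation_ssd: float = 0.5
    nonseed_conservation_wgd: float = 0.75
    nonseed_conservation_ssd: float = 0.35
    dice_wgd: float = 0.3
    dice_ssd: float = 0.05
    outdegree_exponent: float = 2.2
    outdegree_min: int = 10
    outdegree_max: int = 300
    bifan_plant_rate: float = 0.5
    ppi_couple_prob: float = 0.8
    expr_shift_wgd: float = 1.0
    expr_log_mean: float = 4.0
    expr_log_sd: float = 1.0
    n_tissues: int = 10
    n_label_overlap: int = 3
    n_rbh_decoys: int = 5
    n_background_target_pairs: int = 150
    n_background_ppi_edges: int = 400
    frac_decoy_rows: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "frac_intragenic": self.frac_intragenic,
            "seed_conservation_wgd": self.seed_conservation_wgd,
            "seed_conservation_ssd": self.seed_conservation_ssd,
            "nonseed_conservation_wgd": self.nonseed_conservation_wgd,
            "nonseed_conservation_ssd": self.nonseed_conservation_ssd,
            "dice_wgd": self.dice_wgd,
            "dice_ssd": self.dice_ssd,
            "bifan_plant_rate": self.bifan_plant_rate,
            "ppi_couple_prob": self.ppi_couple_prob,
            "frac_decoy_rows": self.frac_decoy_rows,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("n_mirna_genes", "n_target_genes", "n_tissues"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.outdegree_min < 1 or self.outdegree_max < self.outdegree_min:
            raise ValueError("outdegree bounds must satisfy 1 <= min <= max")
        if self.n_mirna_genes < 2 * (self.n_wgd_pairs + self.n_ssd_pairs):
            raise SizingError(
                f"n_mirna_genes={self.n_mirna_genes} cannot host "
                f"{self.n_wgd_pairs} WGD + {self.n_ssd_pairs} SSD pairs"
            )
        if MIRNA_OFFSET + MIRNA_LEN > HOST_LEN:
            raise SizingError("miRNA does not fit inside a host gene")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([stage, self.rng_seed])


@dataclass(frozen=True)
class GeneInterval:
    """A plain genomic interval (0-based, half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class AnnotationBundle:
    """Host/miRNA annotations plus the planted-truth bookkeeping."""

    host_genes: dict[str, GeneInterval]
    mirna_genes: dict[str, MirnaGene]
    mirna_pairs: list[DuplicatePair]  # disjoint catalog (WGD-priority applied)
    wgd_list: list[DuplicatePair]  # raw input lists, possibly overlapping
    ssd_list: list[DuplicatePair]
    host_pairs: list[DuplicatePair]
    host_assignments: list[HostAssignment]
    planted_intragenic: set[tuple[str, str]]  # miRNA pair keys
    rbh_decoy_genes: set[str] = field(default_factory=set)


def generate_annotations(config: SyntheticConfig) -> AnnotationBundle:
    """Generate host genes, miRNA genes and labeled duplicate-pair lists.

    A ``frac_intragenic`` fraction of duplicate miRNA pairs (per origin) is
    planted fully inside duplicate host-gene pairs with matching relative
    strand; the rest are intergenic. The first ``n_label_overlap`` WGD
    pairs are also listed in the SSD input list to exercise WGD-priority
    relabeling downstream.
    """
    rng = config.rng(_STAGE_ANNOTATIONS)

    def make_pairs(prefix: str, n: int, origin: str) -> list[DuplicatePair]:
        pairs = []
        for i in range(n):
            a, b = f"MIR-{prefix}{i:03d}-A", f"MIR-{prefix}{i:03d}-B"
            if origin == "WGD":
                rnd = str(rng.choice(["1R", "2R"]))
                sub = str(rng.choice(SUBGENOME_CLASSES))
                lca = str(rng.choice(WGD_LCA_POOL))
            else:
                rnd, sub = "NA", "NA"
                lca = str(rng.choice(SSD_LCA_POOL))
            pairs.append(
                DuplicatePair(a, b, origin, round=rnd, subgenomes=sub, lca_rank=lca, provenance="synthetic")
            )
        return pairs

    wgd_pairs = make_pairs("W", config.n_wgd_pairs, "WGD")
    ssd_pairs = make_pairs("S", config.n_ssd_pairs, "SSD")
    # overlap: the first few WGD pairs are also reported by the SSD source
    overlap = [
        replace(p, origin="SSD", round="NA", subgenomes="NA", provenance="synthetic-overlap")
        for p in wgd_pairs[: config.n_label_overlap]
    ]
    ssd_list = ssd_pairs + overlap
    catalog = wgd_pairs + ssd_pairs  # disjoint ground truth

    n_singletons = config.n_mirna_genes - 2 * (config.n_wgd_pairs + config.n_ssd_pairs)
    singleton_ids = [f"MIR-X{i:03d}" for i in range(n_singletons)]
    singleton_bona_fide = rng.random(n_singletons) > 0.2

    # choose which pairs are intragenic, per origin
    def choose_intragenic(pairs: list[DuplicatePair]) -> list[DuplicatePair]:
        k = round(config.frac_intragenic * len(pairs))
        idx = sorted(rng.permutation(len(pairs))[:k])
        return [pairs[i] for i in idx]

    intragenic_pairs = choose_intragenic(wgd_pairs) + choose_intragenic(ssd_pairs)
    planted_keys = {p.key for p in intragenic_pairs}

    host_genes: dict[str, GeneInterval] = {}
    host_pairs: list[DuplicatePair] = []
    host_assignments: list[HostAssignment] = []
    mirna_genes: dict[str, MirnaGene] = {}
    rbh_decoys: set[str] = set()

    host_slot = 0

    def place_host(host_id: str, strand: str) -> GeneInterval:
        nonlocal host_slot
        chrom = f"chr{1 + host_slot // HOSTS_PER_CHROM}"
        slot = host_slot % HOSTS_PER_CHROM
        start = HOST_GAP + slot * (HOST_LEN + HOST_GAP)
        host_slot += 1
        iv = GeneInterval(host_id, chrom, start, start + HOST_LEN, strand)
        host_genes[host_id] = iv
        return iv

    decoy_budget = config.n_rbh_decoys
    decoy_idx = 0
    for p in intragenic_pairs:
        hid_a = f"HOST-{p.member_a.removeprefix('MIR-')}"
        hid_b = f"HOST-{p.member_b.removeprefix('MIR-')}"
        rel = str(rng.choice(["same", "opposite"]))
        plant_decoy = p.origin == "WGD" and decoy_budget > 0
        for mid, hid in ((p.member_a, hid_a), (p.member_b, hid_b)):
            host_strand = str(rng.choice(["+", "-"]))
            host = place_host(hid, host_strand)
            mir_strand = host_strand if rel == "same" else ("-" if host_strand == "+" else "+")
            mirna_genes[mid] = MirnaGene(
                gene_id=mid,
                name=mid,
                chrom=host.chrom,
                start=host.start + MIRNA_OFFSET,
                end=host.start + MIRNA_OFFSET + MIRNA_LEN,
                strand=mir_strand,
            )
            host_assignments.append(HostAssignment(mid, hid, rel))
            if plant_decoy:
                # an unrelated extra miRNA in the same host, for RBH stress
                did = f"MIR-D{decoy_idx:03d}"
                decoy_idx += 1
                mirna_genes[did] = MirnaGene(
                    gene_id=did,
                    name=did,
                    chrom=host.chrom,
                    start=host.start + DECOY_OFFSET,
                    end=host.start + DECOY_OFFSET + MIRNA_LEN,
                    strand=mir_strand,
                )
                host_assignments.append(HostAssignment(did, hid, rel))
                rbh_decoys.add(did)
                plant_decoy = False  # one decoy per pair, on the first host
        if p.origin == "WGD" and decoy_budget > 0:
            decoy_budget -= 1
        host_pairs.append(
            DuplicatePair(hid_a, hid_b, p.origin, provenance="synthetic-host")
        )

    # intergenic placement for everything else
    intergenic_ids = [
        m for p in catalog for m in (p.member_a, p.member_b) if m not in mirna_genes
    ] + singleton_ids
    for k, mid in enumerate(intergenic_ids):
        chrom = f"chrU{1 + k // INTERGENIC_PER_CHROM}"
        start = INTERGENIC_SPACING + (k % INTERGENIC_PER_CHROM) * INTERGENIC_SPACING
        bona_fide = True
        if mid in singleton_ids:
            bona_fide = bool(singleton_bona_fide[singleton_ids.index(mid)])
        mirna_genes[mid] = MirnaGene(
            gene_id=mid,
            name=mid,
            chrom=chrom,
            start=start,
            end=start + MIRNA_LEN,
            strand=str(rng.choice(["+", "-"])),
            bona_fide=bona_fide,
        )

    return AnnotationBundle(
        host_genes=host_genes,
        mirna_genes=mirna_genes,
        mirna_pairs=catalog,
        wgd_list=wgd_pairs,
        ssd_list=ssd_list,
        host_pairs=host_pairs,
        host_assignments=host_assignments,
        planted_intragenic=planted_keys,
        rbh_decoy_genes=rbh_decoys,
    )


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def _mutate(
    rng: np.random.Generator,
    seq: str,
    seed_window: tuple[int, int],
    p_seed: float,
    p_nonseed: float,
) -> str:
    """Copy ``seq`` conserving each position i.i.d. with the given probabilities."""
    lo, hi = seed_window
    out = []
    for pos, base in enumerate(seq, start=1):
        p = p_seed if lo <= pos <= hi else p_nonseed
        if rng.random() < p:
            out.append(base)
        else:
            out.append(str(rng.choice(NUCLEOTIDES[NUCLEOTIDES != base])))
    return "".join(out)


def generate_sequences(
    config: SyntheticConfig, bundle: AnnotationBundle, seed_window: tuple[int, int] = (2, 8)
) -> dict[str, tuple[MatureMirna, ...]]:
    """Generate 1-2 mature sequences (19-25 nt) per miRNA gene.

    Paired genes carry matching arms; the second member's sequence is a
    per-position conserved copy of the first member's, with seed positions
    kept at ``seed_conservation_<origin>`` and non-seed positions at the
    (lower) ``nonseed_conservation_<origin>``. If a derived mature ends up
    byte-identical to its template, both genes share a single mature id —
    emulating duplicate loci whose products the mature-level databases
    cannot tell apart.
    """
    rng = config.rng(_STAGE_SEQUENCES)
    matures: dict[str, tuple[MatureMirna, ...]] = {}

    paired = {m for p in bundle.mirna_pairs for m in (p.member_a, p.member_b)}
    for p in bundle.mirna_pairs:
        p_seed = config.seed_conservation_wgd if p.origin == "WGD" else config.seed_conservation_ssd
        p_non = (
            config.nonseed_conservation_wgd
            if p.origin == "WGD"
            else config.nonseed_conservation_ssd
        )
        arms = ["5p"] + (["3p"] if rng.random() < 0.5 else [])
        prods_a, prods_b = [], []
        for arm in arms:
            length = int(rng.integers(19, 26))
            seq_a = _random_rna(rng, length)
            seq_b = _mutate(rng, seq_a, seed_window, p_seed, p_non)
            if seq_b == seq_a:
                shared_id = f"{p.member_a}|{p.member_b}-{arm}"
                prods_a.append(MatureMirna(shared_id, seq_a, arm, p.member_a))
                prods_b.append(MatureMirna(shared_id, seq_b, arm, p.member_b))
            else:
                prods_a.append(MatureMirna(f"{p.member_a}-{arm}", seq_a, arm, p.member_a))
                prods_b.append(MatureMirna(f"{p.member_b}-{arm}", seq_b, arm, p.member_b))
        matures[p.member_a] = tuple(prods_a)
        matures[p.member_b] = tuple(prods_b)

    for gid in sorted(bundle.mirna_genes):
        if gid in paired or gid in matures:
            continue
        arms = ["5p"] + (["3p"] if rng.random() < 0.5 else [])
        matures[gid] = tuple(
            MatureMirna(f"{gid}-{arm}", _random_rna(rng, int(rng.integers(19, 26))), arm, gid)
            for arm in arms
        )
    return matures


def attach_matures(
    bundle: AnnotationBundle, matures: Mapping[str, tuple[MatureMirna, ...]]
) -> dict[str, MirnaGene]:
    """Gene records with their mature products attached."""
    return {
        gid: replace(gene, matures=matures.get(gid, ()))
        for gid, gene in bundle.mirna_genes.items()
    }


def mature_to_gene_map(matures: Mapping[str, tuple[MatureMirna, ...]]) -> dict[str, list[str]]:
    """mature id -> list of parent gene ids (shared matures map to several)."""
    out: dict[str, list[str]] = {}
    for gid in sorted(matures):
        for m in matures[gid]:
            parents = out.setdefault(m.mature_id, [])
            if gid not in parents:
                parents.append(gid)
    return out


def _powerlaw_degrees(
    rng: np.random.Generator, n: int, exponent: float, kmin: int, kmax: int
) -> np.ndarray:
    ks = np.arange(kmin, kmax + 1)
    p = ks.astype(float) ** (-exponent)
    p /= p.sum()
    return rng.choice(ks, size=n, p=p)


@dataclass
class NetworkBundle:
    """Mature-level interaction export, PPI table, target pairs and truth."""

    interactions: pd.DataFrame  # mirna_mature, target_gene, category, evidence, method, score
    ppi: pd.DataFrame  # gene_a, gene_b, confidence
    target_pairs: list[DuplicatePair]
    gene_edges: set[tuple[str, str]]  # planted gene-level truth
    bifan_planted: set[tuple[str, str]]  # miRNA pair keys given a planted bifan
    planted_target_pairs: dict[tuple[str, str], tuple[str, str]]  # miRNA pair -> target pair
    ppi_coupled: set[tuple[str, str]]  # planted target pairs that received a PPI edge
    realized_dice: dict[tuple[str, str], float]


def generate_regulatory_network(
    config: SyntheticConfig,
    bundle: AnnotationBundle,
    matures: Mapping[str, tuple[MatureMirna, ...]],
) -> NetworkBundle:
    """Plant a mature-level miRNA-target export and a coupled PPI table.

    Outdegrees follow the configured bounded power law. For each duplicate
    pair, shared targets are allocated first so the planted Sørensen-Dice
    matches ``dice_<origin>`` in expectation (clamped to min degree when a
    degree draw makes the exact value infeasible), then each member fills
    its remaining degree independently. A ``bifan_plant_rate`` fraction of
    WGD pairs additionally co-target both members of a dedicated duplicate
    target-gene pair, which receives a high-confidence PPI edge with
    probability ``ppi_couple_prob``. Decoy rows carrying failing evidence
    attributes are appended so evidence filtering is non-trivial.
    """
    rng = config.rng(_STAGE_NETWORK)
    targets = [f"TG{i:05d}" for i in range(config.n_target_genes)]
    kmax = min(config.outdegree_max, max(config.outdegree_min, config.n_target_genes // 4))

    gene_ids = sorted(bundle.mirna_genes)
    degrees = dict(
        zip(
            gene_ids,
            _powerlaw_degrees(
                rng, len(gene_ids), config.outdegree_exponent, config.outdegree_min, kmax
            ),
        )
    )

    # duplicate target-gene pairs: planted (for bifans) come first, then background
    target_pairs: list[DuplicatePair] = []
    used_target_idx = 0

    def fresh_target_pair(origin: str, provenance: str) -> DuplicatePair:
        nonlocal used_target_idx
        if used_target_idx + 2 > config.n_target_genes:
            raise SizingError("not enough target genes for the requested duplicate target pairs")
        g, h = targets[used_target_idx], targets[used_target_idx + 1]
        used_target_idx += 2
        tp = DuplicatePair(g, h, origin, provenance=provenance)
        target_pairs.append(tp)
        return tp

    bifan_planted: set[tuple[str, str]] = set()
    planted_tp: dict[tuple[str, str], tuple[str, str]] = {}
    wgd_keys = [p.key for p in bundle.mirna_pairs if p.origin == "WGD"]
    plant_draws = rng.random(len(wgd_keys))
    for key, draw in zip(wgd_keys, plant_draws):
        if draw < config.bifan_plant_rate:
            tp = fresh_target_pair("WGD", "synthetic-planted")
            bifan_planted.add(key)
            planted_tp[key] = tp.key

    for _ in range(config.n_background_target_pairs):
        fresh_target_pair(str(rng.choice(["WGD", "SSD"])), "synthetic-background")

    # PPI edges on planted target pairs
    ppi_rows: list[tuple[str, str, float]] = []
    ppi_coupled: set[tuple[str, str]] = set()
    for key in sorted(planted_tp):
        g, h = planted_tp[key]
        if rng.random() < config.ppi_couple_prob:
            ppi_rows.append((g, h, float(rng.uniform(965, 1000))))
            ppi_coupled.add((g, h))

    # background PPI edges avoid planted target pairs entirely
    planted_combos = set(planted_tp.values())
    n_bg = 0
    while n_bg < config.n_background_ppi_edges:
        g, h = rng.choice(len(targets), size=2, replace=False)
        a, b = targets[min(g, h)], targets[max(g, h)]
        if (a, b) in planted_combos or any(r[0] == a and r[1] == b for r in ppi_rows[-50:]):
            continue
        ppi_rows.append((a, b, float(rng.uniform(850, 1000))))
        n_bg += 1

    # plant gene-level edges
    pool = np.array(targets)
    gene_edges: set[tuple[str, str]] = set()
    realized_dice: dict[tuple[str, str], float] = {}
    paired_genes: set[str] = set()

    for p in bundle.mirna_pairs:
        a, b = p.member_a, p.member_b
        paired_genes.update((a, b))
        d = config.dice_wgd if p.origin == "WGD" else config.dice_ssd
        ka, kb = int(degrees[a]), int(degrees[b])
        forced: list[str] = []
        if p.key in planted_tp:
            forced = list(planted_tp[p.key])
        if d >= 1.0:
            # identical target sets by construction (the indistinguishable case)
            ka = kb = s = max(ka, kb, len(forced), 1)
        else:
            s = int(round(d * (ka + kb) / 2))
            s = max(min(s, ka, kb), len(forced))
            # keep >= 1 private target per member so the planted pair stays
            # distinguishable at the gene level
            ka, kb = max(ka, s + 1), max(kb, s + 1)
        candidates = pool[~np.isin(pool, forced)]
        shared = forced + list(rng.choice(candidates, size=s - len(forced), replace=False))
        remaining = pool[~np.isin(pool, shared)]
        extras = rng.choice(remaining, size=(ka - s) + (kb - s), replace=False)
        set_a = set(shared) | set(extras[: ka - s])
        set_b = set(shared) | set(extras[ka - s :])
        for t in set_a:
            gene_edges.add((a, t))
        for t in set_b:
            gene_edges.add((b, t))
        realized_dice[p.key] = 2 * len(set_a & set_b) / (len(set_a) + len(set_b))

    for gid in gene_ids:
        if gid in paired_genes:
            continue
        for t in rng.choice(pool, size=int(degrees[gid]), replace=False):
            gene_edges.add((gid, t))

    # mature-level export: each gene edge is reported for one of its matures
    rows = []
    for gid, t in sorted(gene_edges):
        prods = matures.get(gid, ())
        if not prods:
            continue
        m = prods[int(rng.integers(len(prods)))]
        rows.append(
            {
                "mirna_mature": m.mature_id,
                "target_gene": t,
                "category": str(rng.choice(["Normal", "Primary"])),
                "evidence": "direct",
                "method": "HT",
                "score": float(rng.uniform(0.9, 1.0)),
            }
        )
    real = pd.DataFrame(rows).drop_duplicates(subset=["mirna_mature", "target_gene"])

    # decoy rows fail every evidence criterion
    n_decoys = int(config.frac_decoy_rows * len(real))
    all_matures = sorted({m.mature_id for prods in matures.values() for m in prods})
    seen = set(zip(real["mirna_mature"], real["target_gene"]))
    decoys = []
    while len(decoys) < n_decoys:
        m = all_matures[int(rng.integers(len(all_matures)))]
        t = targets[int(rng.integers(len(targets)))]
        if (m, t) in seen:
            continue
        seen.add((m, t))
        decoys.append(
            {
                "mirna_mature": m,
                "target_gene": t,
                "category": str(rng.choice(["cancer", "other"])),
                "evidence": "indirect",
                "method": "LT",
                "score": float(rng.uniform(0.0, 0.5)),
            }
        )
    interactions = pd.concat([real, pd.DataFrame(decoys)], ignore_index=True)
    interactions = interactions.sort_values(["mirna_mature", "target_gene"]).reset_index(drop=True)

    ppi = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "confidence"])
    ppi = ppi.drop_duplicates(subset=["gene_a", "gene_b"]).reset_index(drop=True)

    return NetworkBundle(
        interactions=interactions,
        ppi=ppi,
        target_pairs=target_pairs,
        gene_edges=gene_edges,
        bifan_planted=bifan_planted,
        planted_target_pairs=planted_tp,
        ppi_coupled=ppi_coupled,
        realized_dice=realized_dice,
    )


def generate_expression(
    config: SyntheticConfig,
    bundle: AnnotationBundle,
    matures: Mapping[str, tuple[MatureMirna, ...]],
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Log-normal mature x tissue count matrix with a WGD expression shift.

    Returns ``(raw_counts, isoform_to_precursor, gene_labels)``. Counts are
    log-normal with log-mean ``expr_log_mean`` (+``expr_shift_wgd`` for
    matures of WGD-labeled genes, WGD-priority applied). Matures shared by
    two genes are ambiguous at the precursor level and are excluded, as a
    real mature-level atlas cannot attribute them either.
    """
    from ohnomir.model import wgd_priority_labels

    rng = config.rng(_STAGE_EXPRESSION)
    labels = wgd_priority_labels(bundle.mirna_pairs)
    m2g = mature_to_gene_map(matures)
    row_ids = sorted(m for m, parents in m2g.items() if len(parents) == 1)
    iso_map = {m: m2g[m][0] for m in row_ids}
    cols = [f"tissue{t:02d}" for t in range(1, config.n_tissues + 1)]
    shift = np.array(
        [config.expr_shift_wgd if labels.get(iso_map[m]) == "WGD" else 0.0 for m in row_ids]
    )
    log_vals = rng.normal(
        loc=config.expr_log_mean + shift[:, None],
        scale=config.expr_log_sd,
        size=(len(row_ids), len(cols)),
    )
    counts = np.rint(np.exp(log_vals)).astype(np.int64)
    raw = pd.DataFrame(counts, index=row_ids, columns=cols)
    return raw, iso_map, labels
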