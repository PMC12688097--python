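"""Readers and writers for the analysis' file formats.

GFF3 (1-based, closed), BED (0-based, half-open), FASTA (RNA alphabet,
via Biopython), TSV tables (pandas) and the JSON planted-truth manifest.
All writers emit deterministically ordered content so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ohnomir.model import DuplicatePair, MatureMirna, MirnaGene
from ohnomir.synthetic import AnnotationBundle, GeneInterval

PAIR_COLUMNS = ["gene_a", "gene_b", "origin", "round", "subgenomes", "lca", "source"]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_gff3(records: Iterable[tuple], path: Path) -> None:
    """Write (seqid, type, start0, end0, strand, attrs) records as GFF3.

    Input coordinates are 0-based half-open; GFF3 output is 1-based closed.
    """
    lines = ["##gff-version 3"]
    for seqid, ftype, start, end, strand, attrs in records:
        attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
        lines.append(
            f"{seqid}\tohnomir-sim\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_str}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(records: Iterable[tuple], path: Path) -> None:
    """Write (chrom, start0, end0, name, strand) records as 6-column BED."""
    lines = [f"{c}\t{s}\t{e}\t{name}\t0\t{strand}" for c, s, e, name, strand in records]
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(matures: Iterable[MatureMirna], path: Path) -> None:
    seen = set()
    records = []
    for m in sorted(matures, key=lambda m: m.mature_id):
        if m.mature_id in seen:
            continue
        seen.add(m.mature_id)
        records.append(SeqRecord(Seq(m.sequence), id=m.mature_id, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_pairs_tsv(pairs: Iterable[DuplicatePair], path: Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_a": p.member_a,
                "gene_b": p.member_b,
                "origin": p.origin,
                "round": p.round,
                "subgenomes": p.subgenomes,
                "lca": p.lca_rank,
                "source": p.provenance,
            }
            for p in pairs
        ],
        columns=PAIR_COLUMNS,
    )
    df.sort_values(["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def write_annotation_files(bundle: AnnotationBundle, outdir: Path) -> dict[str, Path]:
    """Write the annotation bundle as GFF3/BED/TSV files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hosts_gff3": outdir / "host_genes.gff3",
        "mirnas_gff3": outdir / "mirna_genes.gff3",
        "mirnas_bed": outdir / "mirna_genes.bed",
        "mirna_pairs_wgd": outdir / "mirna_pairs_wgd.tsv",
        "mirna_pairs_ssd": outdir / "mirna_pairs_ssd.tsv",
        "host_pairs": outdir / "host_pairs.tsv",
    }
    write_gff3(
        (
            (h.chrom, "gene", h.start, h.end, h.strand, {"ID": h.gene_id, "Name": h.gene_id})
            for h in sorted(bundle.host_genes.values(), key=lambda h: h.gene_id)
        ),
        paths["hosts_gff3"],
    )
    genes = sorted(bundle.mirna_genes.values(), key=lambda g: g.gene_id)
    write_gff3(
        (
            (
                g.chrom,
                "miRNA_gene",
                g.start,
                g.end,
                g.strand,
                {"ID": g.gene_id, "Name": g.name, "bona_fide": str(g.bona_fide).lower()},
            )
            for g in genes
        ),
        paths["mirnas_gff3"],
    )
    write_bed(((g.chrom, g.start, g.end, g.gene_id, g.strand) for g in genes), paths["mirnas_bed"])
    write_pairs_tsv(bundle.wgd_list, paths["mirna_pairs_wgd"])
    write_pairs_tsv(bundle.ssd_list, paths["mirna_pairs_ssd"])
    write_pairs_tsv(bundle.host_pairs, paths["host_pairs"])
    return paths


def write_mature_map(matures: Mapping[str, tuple[MatureMirna, ...]], path: Path) -> None:
    rows = []
    for gid in sorted(matures):
        for m in matures[gid]:
            rows.append({"mature_id": m.mature_id, "gene_id": gid, "arm": m.arm})
    pd.DataFrame(rows).sort_values(["mature_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def write_truth_manifest(truth: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_gene_intervals_gff3(path: Path) -> dict[str, GeneInterval]:
    """Read gene records from GFF3 into 0-based half-open intervals."""
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    out = {}
    for feat in db.all_features():
        gid = feat.attributes.get("ID", [feat.id])[0]
        out[gid] = GeneInterval(gid, feat.seqid, feat.start - 1, feat.end, feat.strand)
    return out


def read_mirna_genes(
    gff3_path: Path,
    fasta_path: Path | None = None,
    mature_map_path: Path | None = None,
) -> dict[str, MirnaGene]:
    """Assemble MirnaGene records from GFF3 + mature FASTA + mature->gene map."""
    db = gffutils.create_db(str(gff3_path), ":memory:", merge_strategy="create_unique")
    seqs: dict[str, str] = {}
    if fasta_path is not None:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    matures_by_gene: dict[str, list[MatureMirna]] = {}
    if mature_map_path is not None:
        mm = pd.read_csv(mature_map_path, sep="\t")
        for _, row in mm.iterrows():
            seq = seqs.get(row["mature_id"])
            if seq is None:
                continue
            matures_by_gene.setdefault(row["gene_id"], []).append(
                MatureMirna(row["mature_id"], seq, row.get("arm", "unknown"), row["gene_id"])
            )
    genes = {}
    for feat in db.all_features():
        gid = feat.attributes.get("ID", [feat.id])[0]
        bona = feat.attributes.get("bona_fide", ["true"])[0] == "true"
        genes[gid] = MirnaGene(
            gene_id=gid,
            name=feat.attributes.get("Name", [gid])[0],
            chrom=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand,
            matures=tuple(matures_by_gene.get(gid, ())),
            bona_fide=bona,
        )
    return genes


def read_pairs_tsv(path: Path, default_origin: str | None = None) -> list[DuplicatePair]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            DuplicatePair(
                row["gene_a"],
                row["gene_b"],
                row.get("origin", default_origin) or default_origin,
                round=row.get("round", "NA"),
                subgenomes=row.get("subgenomes", "NA"),
                lca_rank=row.get("lca", "NA"),
                provenance=row.get("source", ""),
            )
        )
    return pairs


def read_expression_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
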