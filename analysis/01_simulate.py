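#!/usr/bin/env python
"""Generate the synthetic study data and report what was planted.

Writes the full input bundle (annotations, sequences, interaction and PPI
exports, expression matrix, truth manifest) under scratch/study_inputs/
and a compact summary of the planted structure to results/.
"""

import json

from common import RESULTS, SCRATCH, build_study, ensure_dirs
from ohnomir import io as oio


def main() -> None:
    ensure_dirs()
    cfg, bundle, matures, genes, netbundle, (expr_raw, iso_map, labels) = build_study()

    outdir = SCRATCH / "study_inputs"
    oio.write_annotation_files(bundle, outdir)
    oio.write_fasta((m for prods in matures.values() for m in prods), outdir / "matures.fasta")
    oio.write_mature_map(matures, outdir / "mature_to_gene.tsv")
    netbundle.interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    netbundle.ppi.to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    expr_raw.to_csv(outdir / "expression.tsv", sep="\t")
    oio.write_pairs_tsv(netbundle.target_pairs, outdir / "target_pairs.tsv")

    summary = {
        "seed": cfg.rng_seed,
        "n_mirna_genes": len(bundle.mirna_genes),
        "n_wgd_pairs": cfg.n_wgd_pairs,
        "n_ssd_pairs": cfg.n_ssd_pairs,
        "n_planted_intragenic_pairs": len(bundle.planted_intragenic),
        "n_bifan_planted_wgd_pairs": len(netbundle.bifan_planted),
        "n_ppi_coupled_target_pairs": len(netbundle.ppi_coupled),
        "n_interaction_rows": int(len(netbundle.interactions)),
        "n_ppi_rows": int(len(netbundle.ppi)),
        "expression_shape": list(expr_raw.shape),
    }
    (RESULTS / "01_synthetic_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    print("Synthetic study generated.")
    print(json.dumps(summary, indent=1))
    print(f"Full input bundle under {outdir}")


if __name__ == "__main__":
    main()
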