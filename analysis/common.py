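"""Shared setup for the numbered analysis drivers.

All drivers regenerate the same deterministic synthetic study (seed 1),
so each can be run standalone; large intermediate artifacts go under
scratch/, small result tables under results/.
"""

from __future__ import annotations

from pathlib import Path

from ohnomir.model import RegulatoryNetwork
from ohnomir.network import drop_indistinguishable_pairs, load_ppi, restrict_to_network
from ohnomir.synthetic import (
    SyntheticConfig,
    attach_matures,
    generate_annotations,
    generate_expression,
    generate_regulatory_network,
    generate_sequences,
)

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"
SCRATCH = REPO / "scratch"

STUDY_SEED = 1


def study_config(seed: int = STUDY_SEED) -> SyntheticConfig:
    """The default study conditions (see docs/methods.md)."""
    return SyntheticConfig(rng_seed=seed)


def build_study(seed: int = STUDY_SEED):
    """Generate annotations, sequences, networks and expression for one seed."""
    cfg = study_config(seed)
    bundle = generate_annotations(cfg)
    matures = generate_sequences(cfg, bundle)
    netbundle = generate_regulatory_network(cfg, bundle, matures)
    expression = generate_expression(cfg, bundle, matures)
    genes = attach_matures(bundle, matures)
    return cfg, bundle, matures, genes, netbundle, expression


def curated_network(bundle, netbundle):
    """Gene-level network plus the analyzable pair catalog and curated PPI."""
    net = RegulatoryNetwork(netbundle.gene_edges)
    analyzable, indistinct = drop_indistinguishable_pairs(net, bundle.mirna_pairs)
    analyzable, absent = restrict_to_network(analyzable, net)
    ppi = load_ppi(netbundle.ppi, 960.0)
    return net, analyzable, indistinct, absent, ppi


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
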