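from __future__ import annotations

import pytest

from intronpos.models import GeneModel
from intronpos.synthetic_data import SynthParams, generate_genes


def make_gene(gene_id: str, intron_lengths, symbol=None) -> GeneModel:
    """Structure-free gene model (as read from a length table)."""
    return GeneModel(
        gene_id=gene_id,
        symbol=symbol or gene_id,
        transcript_id=None,
        strand="+",
        exons=[],
        intron_lengths=list(intron_lengths),
    )


@pytest.fixture(scope="session")
def genes_10k():
    """Default-parameter synthetic collection at calibration scale."""
    return generate_genes(SynthParams(n_genes=10_000, seed=1))


@pytest.fixture(scope="session")
def genes_2k():
    """Mid-size synthetic collection used as a set-comparison reference."""
    return generate_genes(SynthParams(n_genes=2_000, seed=11))


@pytest.fixture()
def toy_genes():
    """Six hand-built genes spanning intronless through many-intron cases."""
    return [
        make_gene("G1", []),                       # intronless
        make_gene("G2", [500]),                    # single intron
        make_gene("G3", [100, 900]),               # longest at last position
        make_gene("G4", [9000, 200, 300]),         # longest first, N=3
        make_gene("G5", [10, 10, 800, 20]),        # longest at middle, N=4
        make_gene("G6", [5, 6, 7, 8, 9, 10000]),   # longest last, N=6
    ]
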