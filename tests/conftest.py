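"""Shared fixtures: small synthetic tRNA pools and structures."""

import pytest

from trnaswitch.genetics import TRNAGene
from trnaswitch.stability import (
    SYNTHETIC_TRT2_REFERENCE,
    SYNTHETIC_TRT2_STRUCTURE,
    synthetic_trt2_variants,
)


@pytest.fixture(scope="session")
def trt2_structure() -> str:
    return SYNTHETIC_TRT2_STRUCTURE


@pytest.fixture(scope="session")
def trt2_variants() -> dict:
    return synthetic_trt2_variants()


@pytest.fixture(scope="session")
def thr_gene() -> TRNAGene:
    """A Thr-CGU tRNA gene with structure (the reference fixture)."""
    return TRNAGene(
        gene_id="tRNA-Thr-CGT-1-1",
        sequence=SYNTHETIC_TRT2_REFERENCE,
        structure=SYNTHETIC_TRT2_STRUCTURE,
    )


@pytest.fixture(scope="session")
def lys_gene(thr_gene) -> TRNAGene:
    """A Lys-CUU gene sharing the template body (anticodon CUU at 33-35)."""
    seq = list(thr_gene.sequence)
    seq[32:35] = "CUU"
    return TRNAGene(
        gene_id="tRNA-Lys-CTT-1-1",
        sequence="".join(seq),
        structure=thr_gene.structure,
    )


@pytest.fixture(scope="session")
def met_gene(thr_gene) -> TRNAGene:
    seq = list(thr_gene.sequence)
    seq[32:35] = "CAU"
    return TRNAGene(
        gene_id="tRNA-Met-CAT-1-1",
        sequence="".join(seq),
        structure=thr_gene.structure,
    )
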