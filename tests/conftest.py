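import numpy as np
import pytest

from p4sat.model import Component, ComponentHit, GeneRecord, Replicon


def build_replicon(
    n_genes: int = 60,
    replicon_id: str = "R1",
    topology: str = "linear",
    gene_bp: int = 900,
    gap_bp: int = 100,
) -> Replicon:
    genes = []
    pos = 0
    for i in range(1, n_genes + 1):
        start = pos + gap_bp + 1
        end = start + gene_bp - 1
        genes.append(
            GeneRecord(
                replicon_id=replicon_id,
                gene_index=i,
                start=start,
                end=end,
                strand="+",
                protein_id=f"{replicon_id}_{i:05d}",
                length_aa=gene_bp // 3 - 1,
            )
        )
        pos = end
    return Replicon(replicon_id, genes, pos + gap_bp, topology)


def place_hits(replicon: Replicon, placements) -> list[ComponentHit]:
    """Component hits at given (gene_index, Component) placements."""
    return [
        ComponentHit(
            component=c,
            gene=replicon.genes[i - 1],
            evalue=1e-20,
            profile_coverage=0.8,
            profile_id="synthetic",
        )
        for i, c in placements
    ]


@pytest.fixture
def replicon():
    return build_replicon()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
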