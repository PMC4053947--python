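import numpy as np
import pytest

from methylome_tdmr.core_io import (
    BetaMatrix,
    ProbeAnnotation,
    SampleDesign,
    SampleRecord,
)
from methylome_tdmr.synthetic_data import SimulationConfig, generate_dataset


@pytest.fixture
def tiny_annotation():
    """Ten probes on two chromosomes; two on chr2, one SNP-flagged."""
    probes = []
    for i in range(8):
        probes.append(
            ProbeAnnotation(
                probe_id=f"cg{i:03d}",
                chromosome="chr1",
                position=1000 + 200 * i,
                gene_entries=(("GENE1", "Body"),) if i < 4 else (),
                cgi_relation="Island" if i < 4 else "OpenSea",
                snp_flag=(i == 2),
            )
        )
    for i in range(2):
        probes.append(
            ProbeAnnotation(
                probe_id=f"cg{8 + i:03d}",
                chromosome="chr2",
                position=5000 + 300 * i,
                gene_entries=(("GENE2", "TSS200"),),
                cgi_relation="Shore",
            )
        )
    return probes


@pytest.fixture
def tiny_matrix(tiny_annotation):
    rng = np.random.default_rng(0)
    values = rng.uniform(0.1, 0.9, size=(10, 4))
    return BetaMatrix(
        [a.probe_id for a in tiny_annotation],
        ["s1", "s2", "s3", "s4"],
        values,
    )


@pytest.fixture
def tiny_design():
    return SampleDesign(
        [
            SampleRecord("s1", "liver", "liver", "ind1"),
            SampleRecord("s2", "liver", "liver", "ind2"),
            SampleRecord("s3", "brain", "brain", "ind1"),
            SampleRecord("s4", "brain", "brain", "ind2"),
        ]
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """One moderately sized simulated dataset shared across tests."""
    cfg = SimulationConfig(n_probes=800, seed=11)
    ann, design, bm, truth = generate_dataset(cfg)
    return cfg, ann, design, bm, truth
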