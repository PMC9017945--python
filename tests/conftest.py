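"""Shared fixtures: a tiny hand-built genome and a desk-scale simulated
dataset reused (session-scoped) by the integration-style tests."""

import pytest

from poetools import simulate as sim
from poetools.io import (AlignedRead, GenomeSequence, GenomicInterval,
                         SnpRecord, SnpTable)


@pytest.fixture
def tiny_genome():
    return GenomeSequence({"chr1": "ACGTACGTACGTACGTACGT",  # 20 bp
                           "chr2": "GGGGCCCCAAAATTTTGGCC"})


@pytest.fixture
def tiny_snps():
    # maternal genome carries the alt base (reference is paternal)
    return SnpTable([
        SnpRecord("chr1", 4, "A", "G", parent_of_ref="paternal"),
        SnpRecord("chr1", 12, "A", "T", parent_of_ref="paternal"),
        SnpRecord("chr2", 6, "C", "A", parent_of_ref="paternal"),
    ])


@pytest.fixture
def tiny_features():
    return [
        GenomicInterval("chr1", 0, 10, "+", "geneA", "gene"),
        GenomicInterval("chr1", 10, 20, "-", "teB", "TE"),
        GenomicInterval("chr2", 0, 20, ".", "geneC", "gene"),
    ]


def make_read(contig="chr1", start=0, seq="ACGT", strand="+", n_hits=1,
              read_id="r"):
    return AlignedRead(read_id, contig, start, strand, seq, n_hits)


@pytest.fixture(scope="session")
def sim_config():
    return sim.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def sim_truth(sim_config):
    _, _, _, truth = sim.simulate_genome_and_snps(sim_config)
    return truth


@pytest.fixture(scope="session")
def mrna_dataset(sim_truth):
    total, mat, pat = sim.simulate_mrna_counts(sim_truth)
    return total, mat, pat
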