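import pandas as pd
import pytest

from lncforge.annotation import Catalogue, Gene, GenomicInterval, Transcript
from lncforge.atlas import build_matrix
from lncforge.simulate import SimulationConfig, make_expression


def make_gene(gid, chrom, start, end, strand, biotype="lncRNA", source="test",
              exons=None):
    """Single-transcript gene helper; exons default to one spanning exon."""
    if exons is None:
        exons = [(start, end)]
    tx = Transcript(
        f"{gid}.t1", gid, [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    )
    return Gene(gid, biotype, source, [tx])


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def expression(sim_config):
    """(tissue-mean matrix, sample TPM, sample counts, ground truth)."""
    tpm, counts, truth = make_expression(sim_config)
    m = build_matrix(tpm, truth.sample_map)
    return m, tpm, counts, truth
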