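import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from etamseq import SimConfig, simulate_counts, simulate_transcriptome
from etamseq.model import GenomicSite, ReadObservation, SampleTable, SiteCount


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated transcriptome with truth, treated and IVT tables."""
    config = SimConfig(
        seed=11,
        n_transcripts=10,
        transcript_length=800,
        n_m6a_sites=60,
        coverage_distribution=("poisson", 60),
        editing_fraction=0.0,
    )
    sequences, truth = simulate_transcriptome(config)
    treated = simulate_counts(truth, config, "treated")
    ivt = simulate_counts(truth, config, "ivt")
    return config, sequences, truth, treated, ivt


@pytest.fixture
def toy_table():
    table = SampleTable(label="toy", role="treated")
    table.add(SiteCount(GenomicSite("chr1", 100, "+"), a_count=3, g_count=97))
    table.add(SiteCount(GenomicSite("chr1", 200, "+"), a_count=1, g_count=99))
    return table


def make_read(read_id="r1", contig="tx1", positions=(5, 9, 20), observed=("A", "G", "G"), strand="+", umi=None):
    return ReadObservation(
        read_id=read_id,
        umi=umi,
        contig=contig,
        strand=strand,
        ref_a_positions=list(positions),
        observed=list(observed),
    )
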