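import numpy as np
import pytest

from triodnm.simulate import SimConfig, make_toy_genome, simulate_cohort
from triodnm.transcripts import TranscriptModel


@pytest.fixture(scope="session")
def toy_genome():
    """Deterministic toy reference + transcript models (shared, read-only)."""
    return make_toy_genome(seed=11)


@pytest.fixture(scope="session")
def toy_models(toy_genome):
    return toy_genome[1]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140)


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = SimConfig.noise_free(n_trios=12, mu_dnm=3e-4, seed=5)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = SimConfig(n_trios=40, mu_dnm=3e-4, seed=9)
    return simulate_cohort(cfg)


def make_transcript(
    seq: str,
    exons,
    strand: str = "+",
    cds_start: int | None = None,
    cds_end: int | None = None,
    chrom: str = "chrT",
    gene: str = "TOY",
) -> TranscriptModel:
    """Hand-built transcript over an explicit contig sequence."""
    exons = tuple(tuple(e) for e in exons)
    return TranscriptModel(
        gene=gene,
        transcript_id=f"{gene}.t1",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=exons[0][0] if cds_start is None else cds_start,
        cds_end=exons[-1][1] if cds_end is None else cds_end,
        contig_seq=seq,
    )
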