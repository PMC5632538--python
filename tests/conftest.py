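import numpy as np
import pandas as pd
import pytest

from cernet.core import Config, ExpressionMatrix, GenomicInterval, TranscriptRecord
from cernet.simulate import SimulationParams, simulate_study

GROUPS_12 = {f"{g}{i}": g for g in "VQCR" for i in (1, 2, 3)}


@pytest.fixture
def cfg():
    return Config()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values, feature_ids=None, sample_ids=None, groups=None, kind="counts"):
    """Build an ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(n_feat)]
    sample_ids = sample_ids or list(GROUPS_12)[:n_samp]
    groups = groups or GROUPS_12
    df = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(df, groups, kind=kind)


def make_record(tid="t1", chrom="chr1", exon_spans=((100, 200), (300, 400)),
                strand="+", coverage=10.0, samples=("V1", "V2"), biotype="novel_candidate",
                attrs=None):
    exons = [GenomicInterval(chrom, a, b, strand) for a, b in exon_spans]
    interval = GenomicInterval(
        chrom, min(e.start for e in exons), max(e.end for e in exons), strand
    )
    return TranscriptRecord(
        transcript_id=tid, gene_id=tid, interval=interval, exons=exons,
        coverage=coverage, present_in_samples=set(samples), biotype=biotype,
        attrs=attrs or {},
    )


@pytest.fixture(scope="session")
def small_study():
    """A reduced but fully structured synthetic study shared across tests."""
    params = SimulationParams(
        n_mrna=300, n_lncrna=80, n_mirna=60, n_triads=30, seed=3
    )
    return simulate_study(params)
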