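import pytest

from genebuild import fixtures as fx
from genebuild.core import Exon, TranscriptModel


@pytest.fixture(scope="session")
def small_fixture():
    """A small planted genome shared by read-only tests."""
    params = fx.FixtureParams(n_genes=6, n_retro_copies=2, n_lincrnas=1)
    return fx.make_genome(6, seed=11, params=params)


@pytest.fixture(scope="session")
def small_evidence(small_fixture):
    return fx.make_evidence(small_fixture, seed=12)


def make_transcript(exon_spans, strand="+", region="chr1", cds=None,
                    tid="t1", **kwargs):
    """Terse transcript constructor for toy cases."""
    exons = [Exon(region, s, e, strand) for s, e in exon_spans]
    cds_start, cds_end = cds if cds else (None, None)
    return TranscriptModel(id=tid, exons=exons, cds_start=cds_start,
                          cds_end=cds_end, **kwargs)


@pytest.fixture
def transcript_factory():
    return make_transcript
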