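import pytest
from hypothesis import HealthCheck, settings

import isoscape as iso
from isoscape import collapse as collapse_mod
from isoscape.models import GenomicInterval, TranscriptModel

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_transcript(exons, tid="t1", strand="+", chrom="chr1", **kw):
    """Build a TranscriptModel from (start, end) tuples."""
    return TranscriptModel(
        transcript_id=tid,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        **kw,
    )


@pytest.fixture(scope="session")
def sim_cache():
    """Memoized simulator access so expensive datasets are built once."""
    cache = {}

    def get(seed, **kw):
        key = (seed, repr(sorted(kw.items())))
        if key not in cache:
            cache[key] = iso.simulate(iso.SimulationConfig(seed=seed, **kw))
        return cache[key]

    return get


@pytest.fixture(scope="session")
def dataset(sim_cache):
    """Default stated-world dataset at seed 1."""
    return sim_cache(1)


@pytest.fixture(scope="session")
def collapsed(dataset):
    kept, _ = collapse_mod.filter_alignments(dataset.transcripts)
    return collapse_mod.collapse_redundant(kept)


@pytest.fixture(scope="session")
def representatives(collapsed):
    return [g.representative_model for g in collapsed]
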