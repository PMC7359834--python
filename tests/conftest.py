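import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tempsel.datatypes import Locus, GenotypeSample

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def make_sample(genotypes, site="X", year=0, locus="L1", kind="microsatellite"):
    """One-locus sample from a list of allele pairs (None = missing)."""
    return GenotypeSample(
        site=site, year=year, loci=[Locus(locus, kind)], genotypes=[[g] for g in genotypes]
    )


@pytest.fixture
def sample_factory():
    return make_sample
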