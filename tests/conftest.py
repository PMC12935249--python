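import numpy as np
import pytest

from isoniche.sample_io import IsotopeSample, SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_sample(i: int = 0, **overrides) -> IsotopeSample:
    defaults = dict(
        sample_id=f"S{i:03d}",
        taxon="wildcat",
        region="Taunus",
        case_study=1,
        year=2010,
        month=4,
        sex="female",
        d13C_measured=-21.0 + 0.1 * i,
        d15N=4.0 + 0.05 * i,
        d34S=4.5,
        pctC=45.0,
        pctN=15.0,
        pctS=0.2,
    )
    defaults.update(overrides)
    return IsotopeSample(**defaults)


@pytest.fixture
def small_table() -> SampleTable:
    return SampleTable([make_sample(i) for i in range(6)], provenance="fixture")
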