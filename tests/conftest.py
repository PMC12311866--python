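import io as _io

import pytest

from hlaprofile import (
    load_profile_fixture,
    read_allele_frequencies,
    read_prevalence,
)


@pytest.fixture(scope="session")
def reference_profile():
    """The packaged 127-allele T1D reference profile."""
    return load_profile_fixture()


@pytest.fixture()
def small_freq_table():
    """Three alleles over four countries with uneven coverage."""
    csv = (
        "allele,country,frequency\n"
        "A*01:01,utopia,0.10\n"
        "A*01:01,arcadia,0.20\n"
        "A*01:01,erewhon,0.15\n"
        "A*01:01,atlantis,0.05\n"
        "B*07:02,utopia,0.05\n"
        "B*07:02,arcadia,0.08\n"
        "B*07:02,erewhon,0.02\n"
        "DQB1*03:02,utopia,0.12\n"
        "DQB1*03:02,arcadia,0.18\n"
    )
    return read_allele_frequencies(_io.StringIO(csv))


@pytest.fixture()
def small_prev_table():
    csv = (
        "country,cases,population\n"
        "utopia,5000,1000000\n"
        "arcadia,8000,2000000\n"
        "erewhon,3000,1500000\n"
        "atlantis,1000,500000\n"
    )
    return read_prevalence(_io.StringIO(csv))
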