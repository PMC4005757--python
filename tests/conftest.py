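import numpy as np
import pytest

from popstruct.core import ClockConfig

#: 8-locus placeholder dating panel with rates in the published father-son range
RATES8 = {
    "DYS19": 0.0015,
    "DYS389I": 0.0025,
    "DYS389b": 0.0030,
    "DYS390": 0.0021,
    "DYS391": 0.0026,
    "DYS392": 0.0004,
    "DYS393": 0.0011,
    "DYS437": 0.0012,
}
FOUNDER8 = {locus: 14 for locus in RATES8}


@pytest.fixture(scope="session")
def clock8() -> ClockConfig:
    return ClockConfig(
        locus_rates=dict(RATES8),
        generation_years=25.0,
        hvs_rate_years_per_mutation=20000.0,
        dating_loci=tuple(RATES8),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140430)
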