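import pytest

from qpi.chem import HEAVY_VAL
from qpi.simulate import SimulationConfig, simulate_spectrum_set

#: Human ubiquitin; valines at 17, 26 and 70 carry the heavy label in the
#: positional-isomer benchmarks.
UBIQUITIN = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

TOY_40 = "GASKVLTEYRGASKVLTEYRGASKVLTEYRGASKVLTEYR"


@pytest.fixture(scope="session")
def ubiquitin():
    return UBIQUITIN


@pytest.fixture(scope="session")
def toy40():
    return TOY_40


def make_two_isomer_config(
    ratio=1.0,
    sites=((17,), (70,)),
    seed=42,
    noise_cv=0.10,
    ppm_sd=1.0,
    dropout=0.10,
    decoy_density=2.0,
    **kwargs,
):
    a = ratio / (ratio + 1.0)
    return SimulationConfig(
        sequence=UBIQUITIN,
        modification=HEAVY_VAL,
        proteoforms=[(tuple(sites[0]), a), (tuple(sites[1]), 1.0 - a)],
        noise_cv=noise_cv,
        ppm_sd=ppm_sd,
        dropout=dropout,
        decoy_density=decoy_density,
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def noisy_two_isomer_set():
    """1:1 two-isomer ubiquitin mix with realistic noise; shared across
    tests that only read from it."""
    return simulate_spectrum_set(make_two_isomer_config())


@pytest.fixture(scope="session")
def clean_two_isomer_set():
    """Noise-free, dropout-free, decoy-free 1:1 mix."""
    return simulate_spectrum_set(
        make_two_isomer_config(noise_cv=0.0, ppm_sd=0.0, dropout=0.0, decoy_density=0.0)
    )
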