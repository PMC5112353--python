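import pytest

from imfid.memd import na_memd
from imfid.signals import NoiseSpec, generate_eq7_signal

SIM_SNR_DB = 20.0
REF_SNR_DB = 6.1
REF_CHANNELS = 15


@pytest.fixture(scope="session")
def sim_signal():
    """The 3-channel tone simulation at 20 dB in-signal SNR."""
    return generate_eq7_signal(SIM_SNR_DB, 1000, 1000.0, seed=1)


@pytest.fixture(scope="session")
def sim_decomp(sim_signal):
    """Noise-assisted decomposition of the simulation signal (15 white
    reference channels at 6.1 dB), shared across tests."""
    spec = NoiseSpec(kind="white", l=REF_CHANNELS, snr_db=REF_SNR_DB, seed=10001)
    return na_memd(sim_signal, spec)
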