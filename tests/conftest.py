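import numpy as np
import pytest

import hypoconn as hc


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def paradigm():
    return hc.ParadigmSpec()


@pytest.fixture()
def sine_recording():
    """4-channel, 10 s, 1,000 Hz recording of distinct sinusoids."""
    rate = 1000.0
    t = np.arange(int(10 * rate)) / rate
    freqs = [4.0, 10.0, 25.0, 60.0]
    samples = np.array([100.0 * np.sin(2 * np.pi * f * t) for f in freqs])
    return hc.Recording(
        samples=samples,
        rate=rate,
        channel_ids=["HPC1", "HPC2", "HPC3", "HPC4"],
        channel_geometry=[["HPC1", "HPC2", "HPC3", "HPC4"]],
    )


@pytest.fixture(scope="session")
def small_task_dataset():
    """A small task recording with a planted effect, shared across tests."""
    para = hc.ParadigmSpec()
    spec = hc.LFPEffectSpec(effect_z=1.5, learning_slope=0.0)
    rec, events, truth = hc.gen_task_lfp(spec, para, n_channels=6,
                                         n_trials_per_condition=12,
                                         rate_hz=125.0, seed=7)
    return rec, events, truth, para, spec
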