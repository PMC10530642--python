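import numpy as np
import pytest

from hfadyn import hfa, simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_config(seed=0, **overrides):
    """Compact two-region config used across tests: a sustained, stably
    coding sensory-like region and a transient frontal-like region."""
    base = dict(
        n_patients=1,
        electrodes_per_region={"VT": 12, "PFC": 8},
        region_profiles={
            "VT": simulate.CodingProfile(
                onset_latency_ms=120, rise_ms=80,
                transient_peak_amplitude=4.0, sustained_fraction=0.2,
                tuning_strength=0.6),
            "PFC": simulate.CodingProfile(
                onset_latency_ms=180, rise_ms=120,
                transient_peak_amplitude=2.0, sustained_fraction=0.0,
                tuning_strength=0.4),
        },
        durations_ms=(300, 900),
        n_exemplars_per_category={"face": 8, "watch": 8, "object": 6,
                                  "animal": 5},
        n_repetitions_per_exemplar=2,
        noise_sd=1.0,
        seed=seed,
    )
    base.update(overrides)
    return simulate.SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_config(seed=42)
    tensor, gt = simulate.generate_dataset(cfg)
    return tensor, gt


@pytest.fixture(scope="session")
def smoothed_dataset(small_dataset):
    tensor, gt = small_dataset
    return hfa.smooth_tensor(tensor, 50.0), gt
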