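import numpy as np
import pytest

from smnscreen import synth
from smnscreen.synth import Genotype, MeltCurve, SampleSpec, SimulationConfig


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    return SimulationConfig(rng_seed=7)


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(rng_seed=7, curve_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_mlpa_config() -> SimulationConfig:
    return SimulationConfig(rng_seed=7, mlpa_cv=0.0,
                            mlpa_sample_scale_log_sd=0.0,
                            mlpa_probe_efficiency_log_sd=0.0)


def logistic_curve(amplitude: float, width: float, tm: float,
                   baseline: float = 0.0, step: float = 0.2,
                   sample_id: str = "analytic") -> MeltCurve:
    """A single-transition melt curve built directly from the closed form."""
    t = 45.0 + step * np.arange(int(round(30.0 / step)) + 1)
    f = baseline + amplitude / (1.0 + np.exp(-(tm - t) / width))
    return MeltCurve(sample_id, t, f)


def specimen(genotype: tuple[int, int], dna: float = 5.0, load: float = 1.0,
             shift: float = 0.0, sample_id: str = "spec") -> SampleSpec:
    return SampleSpec(sample_id, Genotype(*genotype), dna, load,
                      probe_region_tm_shift_c=shift)


@pytest.fixture(scope="session")
def control_specs(config):
    return synth._control_specs("CTRL", config)
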