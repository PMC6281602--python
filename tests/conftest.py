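import numpy as np
import pytest

from dielflux.simulate import ClassSpec, GeneratorConfig


@pytest.fixture
def noiseless_tag_config() -> GeneratorConfig:
    """8-day triplicate campaign, storage lipid only, no noise."""
    return GeneratorConfig(
        classes=(ClassSpec("TAG", base_conc=1.0, fold_amplitude=2.3, peak_hour=18.0),),
        noise_cv=0.0,
        seed=42,
    )


@pytest.fixture
def noisy_tag_config(noiseless_tag_config) -> GeneratorConfig:
    return noiseless_tag_config.with_(noise_cv=0.10)


@pytest.fixture
def flat_config() -> GeneratorConfig:
    """Arrhythmic class: fold amplitude 1 with replicate-level noise."""
    return GeneratorConfig(
        classes=(ClassSpec("FLAT", base_conc=1.0, fold_amplitude=1.0),),
        noise_cv=0.10,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
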