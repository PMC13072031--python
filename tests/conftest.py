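import pytest

import needlestoich as ns

#: Published group mean concentrations (mg/g) of the reference field study,
#: restated here as fixed test inputs.
PRINTED_MEANS = {
    "AH": {"c": 447.8, "n": 21.9, "p": 8.3},
    "BH": {"c": 481.8, "n": 12.8, "p": 4.3},
    "AC": {"c": 461.4, "n": 24.7, "p": 7.9},
    "BC": {"c": 472.4, "n": 7.2, "p": 1.6},
}


@pytest.fixture(scope="session")
def zero_noise_config() -> ns.GeneratorConfig:
    """Study-design config with all noise off: samples sit at the group means."""
    return ns.GeneratorConfig(needle_cv=0.0, soil_cv=0.0, seed=11)


@pytest.fixture(scope="session")
def zero_noise_dataset(zero_noise_config) -> ns.StudyDataset:
    return ns.generate_study(zero_noise_config)


@pytest.fixture(scope="session")
def noisy_dataset() -> ns.StudyDataset:
    """Default study conditions (3 trees/condition, CV 0.10 needles / 0.15 soil)."""
    return ns.generate_study(ns.GeneratorConfig(seed=7))
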