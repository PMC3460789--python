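import pytest

from e3miner.synthetic_data import (
    CourseConfig,
    PanelConfig,
    generate_full_panel,
    generate_stage_course,
)


@pytest.fixture(scope="session")
def noiseless_panel():
    """Five noiseless voters (4 arrays + EST) with planted specificity truth."""
    config = PanelConfig(n_genes=400, noise_log_sd=0.0, call_flip_rate=0.0, seed=11)
    datasets, truth = generate_full_panel(config)
    return config, datasets, truth


@pytest.fixture(scope="session")
def noiseless_course():
    """Three noiseless time courses with planted MI/ME/PM/NONE truth."""
    config = CourseConfig(n_genes=400, noise_log_sd=0.0, seed=11)
    datasets, truth = generate_stage_course(config)
    return config, datasets, truth
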