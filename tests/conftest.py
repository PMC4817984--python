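import dataclasses

import pytest

from ynstand import synthetic


@pytest.fixture(scope="session")
def young_noise_free():
    cfg, _ = synthetic.young_and_mature_presets(seed=0)
    cfg = dataclasses.replace(cfg, noise_sd_lnD=0.0)
    return synthetic.generate_series(cfg)


@pytest.fixture(scope="session")
def mature_noise_free():
    _, cfg = synthetic.young_and_mature_presets(seed=0)
    cfg = dataclasses.replace(cfg, noise_sd_lnD=0.0)
    return synthetic.generate_series(cfg)


@pytest.fixture(scope="session")
def default_noisy():
    cfg = synthetic.SyntheticStandConfig(seed=42)
    return synthetic.generate_series(cfg)
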