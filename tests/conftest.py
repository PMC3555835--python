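import pytest

from isomirkit.pipeline import run_simulation
from isomirkit.simulate import SimulationConfig

SMALL_DEPTHS = {k: 1500 for k in ("IB", "WB", "LD", "LW", "PT", "ME", "VT")}


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    defaults = dict(
        seed=seed,
        n_mirnas=12,
        n_novel=3,
        n_decoys=2,
        genome_length=11000,
        library_depths=dict(SMALL_DEPTHS),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def zero_noise_run():
    """One zero-noise simulation pushed through the whole pipeline."""
    cfg = small_config().zero_noise()
    bundle, reference, truth = run_simulation(cfg)
    return cfg, bundle, reference, truth


@pytest.fixture(scope="session")
def noisy_run():
    """A simulation with the default isomiR end-variability model."""
    cfg = small_config(seed=23)
    bundle, reference, truth = run_simulation(cfg)
    return cfg, bundle, reference, truth
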