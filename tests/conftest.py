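import pytest

from traitvar import (
    SimulationConfig,
    TraitConfig,
    default_config,
    generate_dataset,
)


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale dataset under the default (realistic) conditions."""
    return generate_dataset(default_config(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 4-clone dataset for cheap structural tests."""
    cfg = default_config(seed=7)
    cfg.n_clones = 4
    cfg.n_per_clone_treatment = 5
    return generate_dataset(cfg)


@pytest.fixture()
def noise_free_config():
    """All randomness off: every animal sits exactly at its cell mean."""
    tc = TraitConfig(grand_mean=1.0, clone_sd=0.0, residual_sd=0.0, age_slope=0.0)
    # age varies (so the covariate column is not aliased) but has zero slope
    return SimulationConfig(
        n_clones=3,
        n_per_clone_treatment=3,
        traits={"eye_size": tc, "body_size": tc, "reproduction": tc},
        age_sd=2.0,
        seed=0,
    )


def single_trait_config(
    seed=0,
    n_clones=8,
    n_per=15,
    clone_sd=0.5,
    residual_sd=1.0,
    trait="body_size",
    **kwargs,
):
    """Scale-free one-trait config used across simulation studies."""
    tc = TraitConfig(
        grand_mean=10.0, clone_sd=clone_sd, residual_sd=residual_sd, **kwargs
    )
    return SimulationConfig(
        n_clones=n_clones,
        n_per_clone_treatment=n_per,
        traits={trait: tc},
        seed=seed,
    )
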