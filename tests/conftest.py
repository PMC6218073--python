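import dataclasses

import numpy as np
import pytest

from fourc import SubjectRecord, Sex, default_config, generate_cohort
from fourc.cohort import CellConfig, SyntheticConfig


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged 115-subject study cohort at a fixed seed."""
    cfg = default_config(seed=12345)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Same cohort with every noise source silenced: the criterion model
    recovers the latent truth exactly."""
    cfg = default_config(seed=12345).zero_noise()
    return generate_cohort(cfg)


@pytest.fixture
def subject():
    """A physiologically ordinary male subject."""
    return SubjectRecord(
        subject_id="demo",
        sex=Sex.MALE,
        age=30.0,
        height_cm=178.0,
        body_mass_kg=75.0,
        waist_circumference_cm=82.0,
        dxa_fat_mass_kg=14.0,
        dxa_lean_mass_kg=57.5,
        dxa_bmc_kg=3.0,
        adp_body_volume_l=71.0,
        tbw_l=43.0,
    )


def single_cell_config(**overrides) -> SyntheticConfig:
    """A one-cell generator config for targeted cohort tests."""
    cell_kwargs = dict(
        group="OW_BMI_WC", sex="M", n=50,
        height_cm=(179.1, 8.5), bmi=(37.5, 4.8), age=(34.6, 10.2),
        wc_cm=(112.0, 10.8), true_bf=(34.5, 8.5),
    )
    cell_kwargs.update(overrides.pop("cell", {}))
    cfg = SyntheticConfig(cells=(CellConfig(**cell_kwargs),), seed=7)
    return dataclasses.replace(cfg, **overrides)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
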