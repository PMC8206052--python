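import numpy as np
import pytest

from polarscreen.extraction import FactorSettings
from polarscreen.simulate import (
    CampaignConfig,
    DriftModel,
    TrueCompound,
    emulate_reference_campaign,
    generate_campaign,
)

ZERO_DRIFT = DriftModel(rt_shift_sd=0.0, mass_error_sd_ppm=0.0, intensity_cv=0.0)
MILD_DRIFT = DriftModel(rt_shift_sd=0.3, mass_error_sd_ppm=3.0, intensity_cv=0.2)


def small_truth():
    return [
        TrueCompound("guanylurea", 102.0542, 8.0, isotope_pattern=(1.0, 0.1),
                     base_intensity=3e5),
        TrueCompound("melamine", 126.0654, 10.0, isotope_pattern=(1.0, 0.1),
                     base_intensity=2e5),
        TrueCompound("piperidone", 155.1310, 13.5, isotope_pattern=(1.0, 0.15),
                     base_intensity=4e5),
    ]


def small_config(**overrides):
    defaults = dict(
        n_locations=2,
        n_dates=2,
        noise_peak_rate=0.0,
        blank_noise_peak_rate=0.0,
        run_length_min=18.0,
        seed=11,
    )
    defaults.update(overrides)
    return CampaignConfig(**defaults)


@pytest.fixture
def clean_campaign():
    """4 samples + blank, 3 compounds, no drift, no noise."""
    return generate_campaign(small_config(), small_truth(), ZERO_DRIFT)


@pytest.fixture
def drift_campaign():
    """Same layout with realistic RT shift, mass error, and noise ions."""
    return generate_campaign(
        small_config(noise_peak_rate=10.0, seed=13), small_truth(), MILD_DRIFT
    )


@pytest.fixture
def permissive_settings():
    """Setpoint-like factors but low post filters so small test peaks survive."""
    return FactorSettings(
        f6_post_targeted_height_filter=1000.0,
        f7_post_integration_height_filter=1000.0,
    )


@pytest.fixture(scope="session")
def reference_campaign():
    """The full 33-sample + blank preset, generated once per session."""
    return emulate_reference_campaign(seed=1)
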