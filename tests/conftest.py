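"""Shared fixtures: small calibrated worlds reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from sfamap import (
    PixelScenario,
    calibrate_reference,
    derive_threshold,
    simulate_pixel,
)

SPAN = (1986, 2021)
YEARS = np.arange(SPAN[0], SPAN[1] + 1)


@pytest.fixture(scope="session")
def forest_reference():
    """Forest reference statistics from 60 noisy stable-forest samples."""
    series = [
        simulate_pixel(
            PixelScenario("stable_forest", noise_sd=0.015, cloud_fraction=0.3),
            span=SPAN,
            seed=1000 + i,
        )
        for i in range(60)
    ]
    ref, _ = calibrate_reference(series, min_samples=10)
    return ref


@pytest.fixture(scope="session")
def ifz_threshold(forest_reference):
    """Data-driven IFZ threshold from 60 secondary-forest samples."""
    series = [
        simulate_pixel(
            PixelScenario(
                "secondary_forest",
                establishment_year=1990 + (i % 25),
                noise_sd=0.015,
                cloud_fraction=0.3,
            ),
            span=SPAN,
            seed=2000 + i,
        )
        for i in range(60)
    ]
    return derive_threshold(series, forest_reference)
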