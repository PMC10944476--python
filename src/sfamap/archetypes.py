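"""Spectral archetypes and seasonal amplitudes for the synthetic generator.

The constants below define what "forest" and "bare ground" look like in the
six Landsat reflective bands.  They are chosen so that the standard contrasts
the detectors rely on hold by construction:

* bare soil index (BSI) is positive for the bare archetype and negative for
  the forest archetype (MACD detects establishment at the 0-crossing);
* normalized burn ratio (NBR) is high for forest (dark SWIR2, bright NIR)
  and near zero for bare ground;
* the forest archetype is much darker than bare ground in RED/SWIR1/SWIR2,
  the bands entering the integrated forest z-score.

Values are typical Landsat surface-reflectance magnitudes for closed-canopy
broadleaf forest and bright bare soil; they are configuration, not physics,
and can be overridden per scenario.
"""

from __future__ import annotations

import numpy as np

# Band order: blue, green, red, nir, swir1, swir2 (types.BANDS).
FOREST_MEAN = np.array([0.020, 0.045, 0.030, 0.350, 0.120, 0.060])
BARE_MEAN = np.array([0.080, 0.120, 0.180, 0.220, 0.300, 0.250])

# Single annual cosine amplitude per band — the minimum seasonal structure
# the CCDC harmonic model assumes.  Forest phenology is strongest in NIR.
FOREST_SEASONAL_AMP = np.array([0.003, 0.006, 0.006, 0.040, 0.012, 0.008])
BARE_SEASONAL_AMP = np.array([0.002, 0.003, 0.004, 0.008, 0.006, 0.005])

#: Fraction of the year at which the seasonal cosine peaks (mid growing
#: season, ~day 200).
SEASONAL_PEAK = 0.55

#: Reflectance written into cloud-contaminated (masked) observations.
CLOUD_MEAN = np.array([0.70, 0.72, 0.75, 0.78, 0.55, 0.40])

#: Default per-band white-noise standard deviation, reflectance units.
#: Typical Landsat surface-reflectance uncertainty is 1-2%.
DEFAULT_NOISE_SD = 0.015

#: Default logistic regrowth rate (1/yr): establishment transitions from
#: bare to forest spectra over roughly three years.
DEFAULT_REGROWTH_RATE = 2.0
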