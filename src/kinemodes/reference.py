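"""Reference values for squat and lunge joint-reaction-force models.

Published correlation-matrix eigenvalue spectra and peak-force magnitudes for
cohorts of healthy young adults performing maximal-depth squats and forward
lunges.  They serve two purposes: as self-consistency checks of the
compactness/dimensionality machinery, and as the default shapes of the
synthetic cohort generator.

All eigenvalues are on the fully standardized scale where the total variance
equals the number of observations (6 channels x 101 instants = 606).
"""

import numpy as np

from .trials import N_FEATURES

__all__ = [
    "TOTAL_VARIANCE",
    "SQUAT_REFERENCE_EIGENVALUES",
    "LUNGE_REFERENCE_SHARES_PCT",
    "LUNGE_DEFAULT_EIGENVALUES",
    "PEAK_FORCES_BW",
    "PEAK_KNEE_FLEXION_DEG",
    "DEFAULT_VARIANCE_LEVELS",
]

#: Total variance of a fully standardized 606-observation training matrix.
TOTAL_VARIANCE = float(N_FEATURES)

#: Leading 15 eigenvalues of a 50-subject squat model (correlation scale).
SQUAT_REFERENCE_EIGENVALUES = np.array(
    [204.85, 85.11, 71.98, 58.21, 46.81, 31.26, 18.13, 15.18, 13.82, 9.55, 8.38, 6.37, 5.57, 4.65, 3.97]
)

#: Variance shares (percent) of the first three lunge modes.
LUNGE_REFERENCE_SHARES_PCT = np.array([40.87, 15.07, 10.46])

#: Default lunge spectrum for the synthetic generator.  Modes 1-3 carry the
#: reference shares above; the tail (modes 4-17) is synthetic, chosen so the
#: model dimensionality at the 80/90/95/98 % variance levels is 5/9/13/17.
LUNGE_DEFAULT_EIGENVALUES = np.concatenate(
    [
        LUNGE_REFERENCE_SHARES_PCT / 100.0 * TOTAL_VARIANCE,
        [48.0, 37.0, 20.0, 15.0, 12.0, 11.5, 9.0, 8.0, 7.5, 6.5, 5.0, 4.5, 3.8, 3.65],
    ]
)

#: Cohort-mean peak joint-reaction-force magnitudes (BW) at peak flexion.
PEAK_FORCES_BW = {
    "squat": {"hjrf": 3.08, "kjrf": 4.52},
    "lunge": {"hjrf": 4.76, "kjrf": 7.16},
}

#: Cohort-mean peak knee flexion (degrees).
PEAK_KNEE_FLEXION_DEG = {"squat": 112.0, "lunge": 104.0}

#: Variance levels at which models are conventionally validated.
DEFAULT_VARIANCE_LEVELS = (0.80, 0.90, 0.95, 0.98)
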