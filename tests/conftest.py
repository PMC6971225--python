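"""Shared fixtures: calibrated amplitudes and the default haptic trial set.

Both are expensive (bisection calibration; 180 simulated 4-s grasp trials),
so they are session-scoped and computed lazily.
"""

import pytest

from neurotouch.stimulus import (HapticDesign, calibrate_reference_amplitude,
                                 haptic_dataset)

HAPTIC_SEED = 7


@pytest.fixture(scope="session")
def family_amps():
    """Reference-trapezoid amplitudes, one per model family."""
    return {"izh": calibrate_reference_amplitude("izh"),
            "qif": calibrate_reference_amplitude("qif")}


@pytest.fixture(scope="session")
def haptic_trials():
    """The full default haptic experiment: 180 labelled 4-s grasp trials."""
    return haptic_dataset(HapticDesign(), seed=HAPTIC_SEED)
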