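from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from syctqa import EDCalibration, VoxelGrid


@pytest.fixture
def unit_calibration() -> EDCalibration:
    """Two-anchor air/water calibration: ED = (HU + 1000) / 1000, clamped."""
    return EDCalibration(((-1000.0, 0.0), (0.0, 1.0)))


@pytest.fixture
def small_grid() -> VoxelGrid:
    return VoxelGrid(np.zeros((8, 10, 12)), spacing=(2.0, 2.0, 2.5), origin=(-11.0, -9.0, -8.75))


def smooth_dose_pair(seed: int, shape=(14, 16, 16), spacing=(2.5, 2.5, 2.5), scale=10.0,
                     perturbation=0.03):
    """A smooth random reference dose and a smoothly perturbed evaluated dose."""
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.random(shape), 2.0)
    base = base / base.max() * scale
    pert = base * (1 + perturbation * ndimage.gaussian_filter(rng.standard_normal(shape), 2.0))
    ref = VoxelGrid(base, spacing, (0.0, 0.0, 0.0))
    return ref, ref.with_values(pert)
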