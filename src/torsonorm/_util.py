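"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def round_half_up(value: float) -> int:
    """Round to the nearest integer with .5 going up (toward +inf).

    Fractional plane/centroid coordinates are snapped to voxel indices with
    this rule so results do not depend on banker's rounding.
    """
    return int(np.floor(value + 0.5))


def moving_average(profile: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (symmetric in x)."""
    if window <= 1:
        return np.asarray(profile, dtype=np.float64)
    kernel = np.ones(window, dtype=np.float64)
    padded = np.convolve(np.asarray(profile, dtype=np.float64), kernel, mode="same")
    counts = np.convolve(np.ones_like(profile, dtype=np.float64), kernel, mode="same")
    return padded / counts
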