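"""Voxel-wise Z-scores and region (spot) scoring.

A standardized patient SUV P is compared against the normal model's mean M
and SD at the same standard-space voxel:

    Z = (P - M) / SD

A lesion with modest raw SUV can score far above a physiologically hot but
highly variable structure: SUV 2.1 over a quiet bowel background
(M 0.61, SD 0.26) gives Z = 5.73, while SUV 65.4 in the bladder
(M 19.6, SD 24.9) gives only Z = 1.84 — the core inversion this scheme
exists for.

Voxels where the model SD falls below a floor (air, fringes of the body)
would produce explosive Z values; they are marked invalid instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import SuvVolume
from .model import NormalUptakeResults

DEFAULT_SD_FLOOR = 0.05


@dataclass
class ZScoreMap:
    """Voxel-wise Z values with a validity mask."""

    z: np.ndarray
    valid: np.ndarray
    model_ref: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float32)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.z.shape != self.valid.shape:
            raise ValidationError("z and valid grids must share one shape")
        if not np.all(np.isfinite(self.z[self.valid])):
            raise ValidationError("z must be finite wherever valid")


@dataclass
class SpotScore:
    """Per-region readout: SUVmax, Z at the SUVmax voxel, max and mean Z."""

    spot_id: str
    suv_max: float
    z_at_suvmax: float
    z_max: float
    z_mean: float
    voxel_count: int


def zscore_voxel(p: float, m: float, sd: float,
                 sd_floor: float = DEFAULT_SD_FLOOR) -> float:
    """Z-score of a single voxel: (p - m) / sd.

    Raises :class:`ValidationError` when sd falls below the floor — such a
    voxel is invalid, not a number.
    """
    if sd < sd_floor:
        raise ValidationError(f"sd {sd} below floor {sd_floor}: invalid voxel")
    return (p - m) / sd


def zscore_map(volume: SuvVolume, model: NormalUptakeResults,
               sd_floor: float = DEFAULT_SD_FLOOR) -> ZScoreMap:
    """Voxel-wise Z-scores of a standardized volume against the model."""
    if volume.shape != model.shape:
        raise ValidationError(
            f"volume grid {volume.shape} does not match model grid {model.shape}")
    valid = model.valid & (model.sd >= sd_floor)
    z = np.zeros(volume.shape, dtype=np.float64)
    sd = model.sd.astype(np.float64)
    np.divide(volume.data.astype(np.float64) - model.mean, sd,
              out=z, where=valid)
    return ZScoreMap(z=z, valid=valid, model_ref=f"{model.sex}-n{model.n}")


def score_spot(zmap: ZScoreMap, volume: SuvVolume, spot: np.ndarray,
               spot_id: str = "") -> SpotScore:
    """Score one segmented suspicious region.

    ``suv_max`` is the maximum SUV over the spot; ``z_at_suvmax`` reads the
    Z value at that voxel (ties broken toward the highest Z); ``z_max`` and
    ``z_mean`` run over the model-valid spot voxels.
    """
    spot = np.asarray(spot, dtype=bool)
    if spot.shape != zmap.z.shape:
        raise ValidationError("spot mask shape does not match the Z map")
    if not spot.any():
        raise ValidationError("spot mask is empty")
    valid_spot = spot & zmap.valid
    if not valid_spot.any():
        raise ValidationError("spot lies entirely in model-invalid voxels")

    suv = volume.data
    suv_max = float(suv[spot].max())
    at_max = spot & (suv == suv[spot].max())
    z_at = float(zmap.z[at_max & zmap.valid].max()) if (at_max & zmap.valid).any() \
        else float(zmap.z[valid_spot].max())
    zv = zmap.z[valid_spot].astype(np.float64)
    return SpotScore(
        spot_id=spot_id,
        suv_max=suv_max,
        z_at_suvmax=z_at,
        z_max=float(zv.max()),
        z_mean=float(zv.mean()),
        voxel_count=int(spot.sum()),
    )
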