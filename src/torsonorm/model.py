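"""The voxel-wise normal-uptake model.

After anatomical standardization every normal case lives on the same grid,
so normal FDG metabolism can be summarized per voxel: a mean grid M(x,y,z)
and a sample-SD grid SD(x,y,z), stratified by sex. A patient volume deformed
by the same procedure is then scored voxel-by-voxel as

    Z(x,y,z) = (P(x,y,z) - M(x,y,z)) / SD(x,y,z)

The API follows the Model/Results convention: :class:`NormalUptakeModel`
holds the cohort and ``fit()`` returns a :class:`NormalUptakeResults`
carrying the estimated grids, diagnostics, ``summary()``, persistence and
the scoring methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import SuvVolume, load_model, save_model


class NormalUptakeModel:
    """Voxel-wise normal model of SUV over a standardized cohort.

    Parameters
    ----------
    volumes : sequence of SuvVolume
        Standardized normal cases, all on the same grid and of one sex.
    sex : {"male", "female"}
        The stratum being modelled. Mixed-sex cohorts are refused: male and
        female physiques are standardized onto different standard bodies.
    valid_mask : ndarray of bool, optional
        Voxels where the model is meaningful (typically the standard body
        mask). Outside it statistics are still computed but flagged invalid.
    """

    def __init__(self, volumes: Sequence[SuvVolume], sex: str,
                 valid_mask: np.ndarray | None = None):
        volumes = list(volumes)
        if len(volumes) < 2:
            raise ValidationError(f"need >= 2 volumes to estimate SD, got {len(volumes)}")
        if sex not in ("male", "female"):
            raise ValidationError(f"sex must be male or female, got {sex!r}")
        ref = volumes[0]
        for v in volumes:
            if v.shape != ref.shape or v.spacing != ref.spacing:
                raise ValidationError(
                    f"volume {v.id!r} grid {v.shape}/{v.spacing} does not match "
                    f"{ref.id!r} {ref.shape}/{ref.spacing}")
            if v.sex not in (sex, "unknown"):
                raise ValidationError(
                    f"volume {v.id!r} has sex {v.sex!r}, model stratum is {sex!r}")
        if valid_mask is not None and valid_mask.shape != ref.shape:
            raise ValidationError("valid_mask shape does not match volumes")
        self.volumes = volumes
        self.sex = sex
        self.valid_mask = valid_mask

    def fit(self, standard_meta: dict | None = None) -> "NormalUptakeResults":
        """Estimate per-voxel mean and sample SD (n-1 denominator).

        A streaming Welford accumulation in float64 with a fixed reduction
        order: bit-reproducible across runs and, to within float64 rounding,
        independent of input order.
        """
        ref = self.volumes[0]
        mean = np.zeros(ref.shape, dtype=np.float64)
        m2 = np.zeros(ref.shape, dtype=np.float64)
        for k, v in enumerate(self.volumes, start=1):
            x = v.data.astype(np.float64)
            delta = x - mean
            mean += delta / k
            m2 += delta * (x - mean)
        n = len(self.volumes)
        sd = np.sqrt(np.maximum(m2, 0.0) / (n - 1))
        valid = (self.valid_mask.astype(bool) if self.valid_mask is not None
                 else np.ones(ref.shape, dtype=bool))
        return NormalUptakeResults(
            mean=mean.astype(np.float32), sd=sd.astype(np.float32),
            valid=valid, n=n, sex=self.sex, spacing=ref.spacing,
            standard_meta=standard_meta)


@dataclass
class NormalUptakeResults:
    """Fitted per-voxel mean/SD grids plus metadata and scoring methods."""

    mean: np.ndarray
    sd: np.ndarray
    valid: np.ndarray
    n: int
    sex: str
    spacing: tuple[float, float, float]
    standard_meta: dict | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float32)
        self.sd = np.asarray(self.sd, dtype=np.float32)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.mean.shape != self.sd.shape or self.mean.shape != self.valid.shape:
            raise ValidationError("mean, sd and valid grids must share one shape")
        if np.any(self.sd < 0):
            raise ValidationError("sd grid must be non-negative")
        if self.n < 2:
            raise ValidationError(f"a usable model needs n >= 2, got {self.n}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mean.shape  # type: ignore[return-value]

    # -- region summaries ---------------------------------------------------
    def region_summary(self, region: np.ndarray) -> dict:
        """Mean-of-means, pooled SD and mean range within a region mask."""
        region = np.asarray(region, dtype=bool)
        if region.shape != self.shape:
            raise ValidationError("region mask shape does not match model grid")
        if not region.any():
            raise ValidationError("region mask is empty")
        m = self.mean[region].astype(np.float64)
        s = self.sd[region].astype(np.float64)
        return {
            "voxels": int(region.sum()),
            "mean": float(m.mean()),
            "pooled_sd": float(np.sqrt(np.mean(s ** 2))),
            "range": float(m.max() - m.min()),
        }

    def summary(self, regions: dict | None = None) -> str:
        """A text summary table, optionally with named region statistics."""
        rows = [("(all valid voxels)", self.region_summary(self.valid))] if self.valid.any() else []
        for name, mask in (regions or {}).items():
            rows.append((name, self.region_summary(mask)))
        df = pd.DataFrame(
            [{"region": name, **stats} for name, stats in rows]
        )
        header = (f"Normal uptake model: sex={self.sex}, n={self.n}, "
                  f"grid={self.shape}, spacing={self.spacing} mm\n")
        return header + df.to_string(index=False)

    # -- scoring ------------------------------------------------------------
    def zscore_map(self, volume: SuvVolume, sd_floor: float = 0.05):
        from .scoring import zscore_map
        return zscore_map(volume, self, sd_floor=sd_floor)

    def score_spot(self, zmap, volume: SuvVolume, spot: np.ndarray, spot_id: str = ""):
        from .scoring import score_spot
        return score_spot(zmap, volume, spot, spot_id=spot_id)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        save_model(self, path)

    @classmethod
    def load(cls, path) -> "NormalUptakeResults":
        return load_model(path)


# ---------------------------------------------------------------------------
# Functional surface

def build_model(volumes: Sequence[SuvVolume], sex: str,
                valid_mask: np.ndarray | None = None,
                standard_meta: dict | None = None) -> NormalUptakeResults:
    """Fit the voxel-wise normal model over standardized volumes."""
    return NormalUptakeModel(volumes, sex, valid_mask=valid_mask).fit(standard_meta)


def model_summary(model: NormalUptakeResults, region: np.ndarray) -> dict:
    """Region-level summary record: mean, pooled SD, range of the mean grid."""
    return model.region_summary(region)
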