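"""Torso plane detection and the 16-point landmark cuboid.

Eight planes confine and subdivide the torso:

* NS (neck-shoulder): the axial slice of minimum body area in the neck band;
* AC left/right (arms-chest): sagittal slices through the axillae, found as
  the profile minima flanking the central peak of body area vs x;
* TH (thigh-hips): the first axial slice, scanning tail-to-head, where the
  two thigh components unite;
* A / P (anterior/posterior): first and last coronal slices containing body,
  with the head excluded (it may protrude beyond the chest line);
* BL: the axial coordinate of the bladder's average coronal centroid;
* LV: the liver apex — the boundary between liver and lung.

Their intersections give 16 corner points (S1–S4 on NS, T1–T4 on TH, LV1–LV4
and BL1–BL4 on the organ planes) that drive the piecewise affine
registration. Corner numbering: 1 = anterior-left, 2 = anterior-right,
3 = posterior-right, 4 = posterior-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage

from ._util import moving_average, round_half_up
from .errors import DetectionError, ValidationError

_STRUCT_2D = np.ones((3, 3), dtype=bool)

LANDMARK_NAMES = tuple(
    f"{prefix}{i}" for prefix in ("S", "T", "LV", "BL") for i in (1, 2, 3, 4)
)


@dataclass
class TorsoPlanes:
    """Detected plane coordinates (voxel indices, 0-based)."""

    ns_z: int
    th_z: int
    bl_z: int
    lv_z: int
    ac_left_x: int
    ac_right_x: int
    a_y: int
    p_y: int
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if not (self.th_z < self.bl_z < self.lv_z < self.ns_z):
            raise ValidationError(
                "plane ordering violated: need TH < BL < LV < NS, got "
                f"TH={self.th_z}, BL={self.bl_z}, LV={self.lv_z}, NS={self.ns_z}")
        if not self.ac_left_x < self.ac_right_x:
            raise ValidationError(
                f"AC planes must satisfy left < right, got {self.ac_left_x}, {self.ac_right_x}")
        if not self.a_y < self.p_y:
            raise ValidationError(f"A plane must precede P plane, got {self.a_y}, {self.p_y}")
        if self.grid_shape is not None:
            nx, ny, nz = self.grid_shape
            if not (0 <= self.ac_left_x and self.ac_right_x < nx
                    and 0 <= self.a_y and self.p_y < ny
                    and 0 <= self.th_z and self.ns_z < nz):
                raise ValidationError("plane indices outside grid bounds")

    def z_levels(self) -> tuple[int, int, int, int]:
        """Cuboid z knots, inferior to superior: TH, BL, LV, NS."""
        return (self.th_z, self.bl_z, self.lv_z, self.ns_z)


@dataclass
class LandmarkSet:
    """The 16 named cuboid corner points, as (x, y, z) voxel coordinates."""

    points: dict

    def __post_init__(self) -> None:
        if set(self.points) != set(LANDMARK_NAMES):
            raise ValidationError(
                f"landmark set must contain exactly {sorted(LANDMARK_NAMES)}")
        self.points = {k: tuple(int(c) for c in v) for k, v in self.points.items()}
        if len(set(self.points.values())) != 16:
            raise ValidationError("landmark points must be 16 distinct locations")

    def as_array(self, order: Iterable[str] = LANDMARK_NAMES) -> np.ndarray:
        return np.array([self.points[name] for name in order], dtype=float)


def assemble_landmarks(planes: TorsoPlanes) -> LandmarkSet:
    """All 16 corner points from the eight planes by the Cartesian product
    {AC_left, AC_right} x {A, P} x {NS, TH, LV, BL}."""
    corners = {
        1: (planes.ac_left_x, planes.a_y),
        2: (planes.ac_right_x, planes.a_y),
        3: (planes.ac_right_x, planes.p_y),
        4: (planes.ac_left_x, planes.p_y),
    }
    zs = {"S": planes.ns_z, "T": planes.th_z, "LV": planes.lv_z, "BL": planes.bl_z}
    points = {f"{prefix}{i}": (x, y, z)
              for prefix, z in zs.items() for i, (x, y) in corners.items()}
    return LandmarkSet(points=points)


# ---------------------------------------------------------------------------
# Plane detectors (each takes a boolean body grid)

def _body_z_range(mask: np.ndarray) -> tuple[int, int]:
    zs = np.nonzero(mask.any(axis=(0, 1)))[0]
    if zs.size == 0:
        raise DetectionError("body mask is empty")
    return int(zs.min()), int(zs.max())


def detect_ns_plane(mask: np.ndarray, band_fraction: float = 0.35,
                    min_area_fraction: float = 0.1) -> int:
    """Axial slice of minimum body area within the neck search band
    (the superior ``band_fraction`` of the body's z extent).

    Slices whose area falls below ``min_area_fraction`` of the band's median
    are ignored: they are noise specks clinging to the head top, not a neck.
    Ties break toward the superior slice."""
    zmin, zmax = _body_z_range(mask)
    band_lo = int(np.ceil(zmax - band_fraction * (zmax - zmin)))
    areas = mask.sum(axis=(0, 1))
    band = np.arange(band_lo, zmax + 1)
    nz = band[areas[band] > 0]
    if nz.size == 0:
        raise DetectionError("no nonzero body area in the neck search band")
    floor = min_area_fraction * float(np.median(areas[nz]))
    solid = nz[areas[nz] >= floor]
    if solid.size == 0:
        raise DetectionError("no solid body area in the neck search band")
    vals = areas[solid]
    return int(solid[::-1][int(np.argmin(vals[::-1]))])


def detect_ac_planes(mask: np.ndarray, smooth_window: int = 3,
                     max_relative_depth: float = 0.6) -> tuple[int, int]:
    """Axilla positions from the sagittal body-area profile.

    The smoothed profile of body voxels per fixed-x plane has a central
    maximum (torso) flanked, when arms are present, by local minima at the
    air gaps of the axillae. A minimum only counts if it drops below
    ``max_relative_depth`` of the central peak and body exists beyond it
    (otherwise the profile is simply tailing off — no arms). Ties break
    toward the torso.
    """
    profile = mask.sum(axis=(1, 2)).astype(np.float64)
    nzx = np.nonzero(profile > 0)[0]
    if nzx.size == 0:
        raise DetectionError("body mask is empty")
    smoothed = moving_average(profile, smooth_window)
    peak_x = int(np.argmax(smoothed))
    thresh = max_relative_depth * smoothed[peak_x]

    def side_min(candidates: np.ndarray, innermost_last: bool) -> int:
        fail = DetectionError(
            "no axilla found: sagittal profile is unimodal (no arms?)")
        if candidates.size == 0:
            raise fail
        vals = smoothed[candidates]
        if vals.min() >= thresh:
            raise fail
        winners = candidates[vals == vals.min()]
        x_min = int(winners.max() if innermost_last else winners.min())
        # a genuine axilla is a dip: the profile must RISE again outward
        # (toward the arm); a mere tail of the torso ellipse does not
        if innermost_last:
            outer = smoothed[nzx.min(): x_min]
        else:
            outer = smoothed[x_min + 1: nzx.max() + 1]
        if outer.size == 0 or outer.max() < 1.5 * smoothed[x_min] + 1e-9:
            raise fail
        return x_min

    left_candidates = np.arange(nzx.min() + 1, peak_x)
    right_candidates = np.arange(peak_x + 1, nzx.max())
    left = side_min(left_candidates, innermost_last=True)
    right = side_min(right_candidates, innermost_last=False)
    return left, right


def detect_th_plane(mask: np.ndarray, min_component: int = 50) -> int:
    """First axial slice, scanning inferior to superior, where the two thigh
    components (2D components of at least ``min_component`` voxels) unite
    into one."""
    zmin, zmax = _body_z_range(mask)
    seen_two = False
    for z in range(zmin, zmax + 1):
        sl = mask[:, :, z]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl, structure=_STRUCT_2D)
        sizes = np.bincount(labels.ravel())[1:]
        n_large = int((sizes >= min_component).sum())
        if n_large >= 2:
            seen_two = True
        elif seen_two and n_large == 1:
            return z
    raise DetectionError("thigh union not found (legs fused, cropped, or absent)")


def detect_ap_planes(mask: np.ndarray, ns_z: int) -> tuple[int, int]:
    """First and last coronal slices containing body, head excluded
    (only slices at or below the NS plane are counted)."""
    sub = mask[:, :, : ns_z + 1]
    ys = np.nonzero(sub.any(axis=(0, 2)))[0]
    if ys.size == 0:
        raise DetectionError("empty coronal profile below the NS plane")
    return int(ys.min()), int(ys.max())


def compute_bl_plane(bladder: np.ndarray) -> int:
    """BL plane: the z coordinate of the bladder's average coronal centroid.

    For each coronal plane containing bladder voxels the 2D centroid's z is
    taken; the average over planes is rounded half-up to a voxel index.
    """
    if not bladder.any():
        raise ValidationError("bladder mask is empty")
    centroids = []
    for y in range(bladder.shape[1]):
        zs = np.nonzero(bladder[:, y, :])[1]
        if zs.size:
            centroids.append(zs.mean())
    return round_half_up(float(np.mean(centroids)))


def compute_lv_plane(liver: np.ndarray) -> int:
    """LV plane: the liver apex — the maximum z over liver voxels."""
    if not liver.any():
        raise ValidationError("liver mask is empty")
    return int(np.nonzero(liver)[2].max())


def detect_all_planes(volume, body, config=None):
    """Run all eight detectors on a volume; returns (TorsoPlanes, flags).

    ``flags`` records fallback use: when the bladder cannot be segmented
    (e.g. no urinary activity) the BL plane falls back to a configurable
    fraction of the NS–TH span above TH.
    """
    from .config import PipelineConfig
    from .errors import OrganNotFoundError
    from .segmentation import segment_bladder, segment_liver

    cfg = config or PipelineConfig()
    mask = body.data
    ns_z = detect_ns_plane(mask, band_fraction=cfg.ns_band_fraction)
    ac_left, ac_right = detect_ac_planes(
        mask, smooth_window=cfg.ac_smooth_window,
        max_relative_depth=cfg.ac_max_relative_depth)
    th_z = detect_th_plane(mask, min_component=cfg.thigh_min_component)
    a_y, p_y = detect_ap_planes(mask, ns_z)

    flags = {"bl_fallback": False}
    try:
        bladder = segment_bladder(
            volume, body, min_suv=cfg.bladder_min_suv,
            rel_factor=cfg.bladder_rel_factor, z_fraction=cfg.bladder_z_fraction,
            x_fraction=cfg.bladder_x_fraction)
        bl_z = compute_bl_plane(bladder.data)
    except OrganNotFoundError:
        bl_z = th_z + round_half_up(cfg.bl_fallback_fraction * (ns_z - th_z))
        flags["bl_fallback"] = True

    if bl_z >= ns_z - 1:
        raise DetectionError(f"BL plane {bl_z} too close to NS plane {ns_z}")
    planes_partial = TorsoPlanes(
        ns_z=ns_z, th_z=th_z, bl_z=bl_z, lv_z=ns_z - 1,
        ac_left_x=ac_left, ac_right_x=ac_right, a_y=a_y, p_y=p_y)
    liver = segment_liver(
        volume, body, planes_partial, rel_factor=cfg.liver_rel_factor,
        min_region=cfg.liver_min_region, z_fraction=cfg.liver_z_fraction)
    lv_z = compute_lv_plane(liver.data)

    planes = TorsoPlanes(
        ns_z=ns_z, th_z=th_z, bl_z=bl_z, lv_z=lv_z,
        ac_left_x=ac_left, ac_right_x=ac_right, a_y=a_y, p_y=p_y,
        grid_shape=volume.shape)
    return planes, flags
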