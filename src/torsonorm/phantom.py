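"""Synthetic torso SUV phantoms with complete ground truth.

The generator builds a body as a stack of elliptical axial cross-sections —
two thighs that merge at the hips, an abdomen, a chest flanked by arms
separated from it by an air gap, a shoulder taper, a neck whose area dips to
a minimum, and a truncated-ellipsoid head — and places organ-like ellipsoids
(lungs, liver, brain, bladder) with configurable mean SUV inside it. This is
exactly the geometry the rule-based torso detectors presume: a unique
minimum-area neck slice, sagittal-profile gaps at the axillae, thighs that
unite at a known slice, a hot bladder, and a liver whose apex borders the
lung. Every generated volume is accompanied by a :class:`PhantomTruth`
holding the organ masks, the true plane coordinates, the 16 landmark
positions and any planted lesions.

Noise is additive Gaussian in SUV units (clipped at zero), the conventional
approximation for reconstructed PET images; set ``noise_sd=0`` for exact
tests. Geometry scales with the grid so the same anatomy renders at any
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._util import round_half_up
from .errors import ValidationError
from .io import SuvVolume
from .landmarks import LandmarkSet, TorsoPlanes, assemble_landmarks, detect_ac_planes

# Default organ mean SUVs. Chosen so every rule-based detector is well posed
# (e.g. lung above the 0.5 body threshold, bladder far above soft tissue);
# magnitudes follow typical body-weight SUV scales (soft tissue ~1, liver ~2,
# brain ~6, urine-filled bladder tens).
DEFAULT_ORGAN_SUVS = {
    "soft": 1.0,
    "lung": 0.7,
    "liver": 2.0,
    "brain": 6.0,
    "bladder": 20.0,
}

# Per-subject jitter applied by phantom_population: multiplicative uniform
# ranges emulating physique and uptake variation across a screening cohort.
POPULATION_JITTER = {
    "scale": (0.92, 1.08),       # torso width/depth/height multipliers
    "soft": (0.92, 1.08),
    "lung": (0.85, 1.15),
    "liver": (0.90, 1.10),
    "brain": (0.85, 1.15),
    "bladder": (0.60, 1.40),     # urine filling varies hugely -> high variance
}

# Body-height fractions of the anatomical bands (inferior -> superior).
_BANDS = {
    "thigh": (0.00, 0.18),
    "hips": (0.18, 0.32),
    "abdomen": (0.32, 0.54),
    "chest": (0.54, 0.74),
    "arms": (0.54, 0.74),
    "shoulder": (0.74, 0.80),
    "neck": (0.80, 0.88),
    "head": (0.88, 1.001),
}


@dataclass
class Lesion:
    """A planted spherical lesion: voxel-coordinate center, radius in mm, SUV."""

    center: tuple[float, float, float]
    radius_mm: float
    suv: float


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    sex: str = "male"
    torso_height_scale: float = 1.0
    torso_width_scale: float = 1.0
    torso_depth_scale: float = 1.0
    organ_suv_means: dict = field(default_factory=lambda: dict(DEFAULT_ORGAN_SUVS))
    noise_sd: float = 0.0
    lesions: list[Lesion] = field(default_factory=list)
    seed: int = 0
    arms: bool = True

    def __post_init__(self) -> None:
        for organ, suv in self.organ_suv_means.items():
            if suv < 0:
                raise ValidationError(f"organ SUV must be >= 0 ({organ}={suv})")
        missing = set(DEFAULT_ORGAN_SUVS) - set(self.organ_suv_means)
        if missing:
            raise ValidationError(f"organ_suv_means missing {sorted(missing)}")
        for name in ("torso_height_scale", "torso_width_scale", "torso_depth_scale"):
            s = getattr(self, name)
            if not (0.5 < s < 2.0):
                raise ValidationError(f"{name} must be in (0.5, 2.0), got {s}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"phantom sex must be male or female, got {self.sex!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth emitted with each phantom."""

    organ_masks: dict
    plane_truth: TorsoPlanes
    landmark_truth: LandmarkSet
    lesion_records: list[Lesion]


def _ellipse(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float,
             a: float, b: float) -> np.ndarray:
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _sex_factors(sex: str) -> tuple[float, float, float]:
    # Female standard physique: narrower/shallower/shorter, per Table-style
    # population differences in height and weight.
    if sex == "female":
        return 0.90, 0.92, 0.92
    return 1.0, 1.0, 1.0


def generate_phantom(config: PhantomConfig) -> tuple[SuvVolume, PhantomTruth]:
    """Render one torso phantom and its ground truth.

    Deterministic: identical configs (including seed) give identical output.
    """
    nx, ny, nz = config.grid_shape
    fw, fd, fh = _sex_factors(config.sex)
    sx = config.torso_width_scale * fw * (nx / 64.0)
    sy = config.torso_depth_scale * fd * (ny / 64.0)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    z0 = 2
    H = int(round(0.82 * nz * config.torso_height_scale * fh))
    if z0 + H > nz:
        raise ValidationError("torso height exceeds grid; reduce torso_height_scale")

    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    body = np.zeros((nx, ny, nz), dtype=bool)

    chest_a, chest_b = 15.0 * sx, 10.0 * sy
    neck_a, neck_b = 6.0 * sx, 5.5 * sy
    arm_a, arm_b = 2.0 * sx, 2.5 * sy
    arm_gap = 3.0  # absolute voxels of air between chest and arm
    arm_dx = chest_a + arm_gap + arm_a

    shoulder_a = arm_dx + arm_a  # deltoid span bridging arms to the trunk
    th_z = None                  # first slice where the thighs have united

    def _frac(z: int) -> float:
        return (z - z0) / (H - 1)

    # discrete shoulder band: its FIRST slice must span the arms regardless
    # of grid resolution, so the taper is parametrized by slice index
    shoulder_zs = [z for z in range(z0, z0 + H)
                   if _BANDS["shoulder"][0] <= _frac(z) < _BANDS["shoulder"][1]]

    for z in range(z0, z0 + H):
        f = _frac(z)
        sl = np.zeros((nx, ny), dtype=bool)
        if f < _BANDS["thigh"][1]:
            for side in (-1.0, 1.0):
                sl |= _ellipse(xx, yy, cx + side * 8.0 * sx, cy, 5.5 * sx, 6.5 * sy)
        elif f < _BANDS["hips"][1]:
            if th_z is None:
                th_z = z
            sl |= _ellipse(xx, yy, cx, cy, 13.5 * sx, 8.5 * sy)
        elif f < _BANDS["abdomen"][1]:
            sl |= _ellipse(xx, yy, cx, cy, 12.5 * sx, 9.0 * sy)
        elif f < _BANDS["chest"][1]:
            sl |= _ellipse(xx, yy, cx, cy, chest_a, chest_b)
            if config.arms and f < _BANDS["arms"][1]:
                for side in (-1.0, 1.0):
                    sl |= _ellipse(xx, yy, cx + side * arm_dx, cy, arm_a, arm_b)
        elif f < _BANDS["shoulder"][1]:
            # shoulder taper: spans the arms at its base (so arms connect to
            # the trunk) and narrows to the neck
            t = (shoulder_zs.index(z) / max(len(shoulder_zs) - 1, 1)
                 if shoulder_zs else 0.0)
            a0 = shoulder_a if config.arms else chest_a
            a = a0 + t * (neck_a - a0)
            b = chest_b + t * (neck_b - chest_b)
            sl |= _ellipse(xx, yy, cx, cy, a, b)
        elif f < _BANDS["neck"][1]:
            t = (f - _BANDS["neck"][0]) / (_BANDS["neck"][1] - _BANDS["neck"][0])
            dip = 1.0 - 0.15 * (1.0 - (2.0 * t - 1.0) ** 2)
            sl |= _ellipse(xx, yy, cx, cy, neck_a * dip, neck_b * dip)
        else:
            t = (f - _BANDS["head"][0]) / (1.0 - _BANDS["head"][0])
            u = -0.8 + 1.35 * t
            r = np.sqrt(max(1.0 - u * u, 0.0))
            sl |= _ellipse(xx, yy, cx, cy, 9.5 * sx * r, 9.0 * sy * r)
        body[:, :, z] = sl

    # --- organs: ellipsoids clipped to the body, later entries take priority
    X, Y, Z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")

    def ellipsoid(cx_, cy_, fz, a, b, hz_frac):
        cz = z0 + fz * (H - 1)
        c = hz_frac * (H - 1)
        m = (((X - cx_) / a) ** 2 + ((Y - cy_) / b) ** 2 + ((Z - cz) / c) ** 2) <= 1.0
        return m & body

    lung = (ellipsoid(cx - 7.5 * sx, cy, 0.64, 5.0 * sx, 5.5 * sy, 0.10)
            | ellipsoid(cx + 7.5 * sx, cy, 0.64, 5.0 * sx, 5.5 * sy, 0.10))
    liver = ellipsoid(cx + 6.5 * sx, cy, 0.55, 8.5 * sx, 6.5 * sy, 0.105)
    brain = ellipsoid(cx, cy, 0.94, 4.5 * sx, 4.5 * sy, 0.05)
    bladder = ellipsoid(cx, cy, 0.26, 3.5 * sx, 3.0 * sy, 0.055)

    suvs = config.organ_suv_means
    if suvs["bladder"] <= suvs["soft"]:
        # Allowed (used to test detector failure modes) but makes the bladder
        # indistinguishable; the rule-based BL detector will report not-found.
        pass

    suv = np.zeros((nx, ny, nz), dtype=np.float64)
    suv[body] = suvs["soft"]
    lung &= ~liver  # liver apex displaces lung space where they overlap
    suv[lung] = suvs["lung"]
    suv[liver] = suvs["liver"]
    suv[brain] = suvs["brain"]
    suv[bladder] = suvs["bladder"]

    lesion_mask = np.zeros((nx, ny, nz), dtype=bool)
    spx, spy, spz = config.spacing
    for les in config.lesions:
        lc = tuple(float(c) for c in les.center)
        ci = tuple(min(max(int(round(c)), 0), s - 1)
                   for c, s in zip(lc, (nx, ny, nz)))
        if not body[ci]:
            raise ValidationError(f"lesion center {les.center} lies outside the body")
        m = (((X - lc[0]) * spx) ** 2 + ((Y - lc[1]) * spy) ** 2
             + ((Z - lc[2]) * spz) ** 2) <= les.radius_mm ** 2
        m &= body
        suv[m] = les.suv
        lesion_mask |= m

    # --- ground-truth planes from the noiseless geometry
    areas = body.sum(axis=(0, 1))
    zmax = z0 + H - 1
    band_lo = int(np.ceil(zmax - 0.35 * (zmax - z0)))
    band = np.arange(band_lo, zmax + 1)
    band_areas = areas[band]
    nz_band = band[band_areas > 0]
    nz_areas = band_areas[band_areas > 0]
    rev = np.argmin(nz_areas[::-1])           # ties -> most superior slice
    ns_z = int(nz_band[::-1][rev])

    if config.arms:
        # The axilla has no geometric definition apart from the area-profile
        # rule itself, so the truth is that rule applied to the noiseless
        # drawn body (the paper defines the AC planes by these minima).
        ac_left, ac_right = detect_ac_planes(body)
    else:  # armless phantom: record the chest edges (no axilla exists)
        ac_left = round_half_up(cx - chest_a)
        ac_right = round_half_up(cx + chest_a)

    sub = body[:, :, : ns_z + 1]
    ys = np.nonzero(sub.any(axis=(0, 2)))[0]
    a_y, p_y = int(ys.min()), int(ys.max())

    bl_z = round_half_up(float(np.nonzero(bladder)[2].mean())) if bladder.any() else 0
    lv_z = int(np.nonzero(liver)[2].max()) if liver.any() else 0

    planes = TorsoPlanes(ns_z=ns_z, th_z=int(th_z), bl_z=bl_z, lv_z=lv_z,
                         ac_left_x=ac_left, ac_right_x=ac_right, a_y=a_y, p_y=p_y,
                         grid_shape=(nx, ny, nz))
    landmark_truth = assemble_landmarks(planes)

    soft = body & ~(lung | liver | brain | bladder | lesion_mask)
    truth = PhantomTruth(
        organ_masks={"body": body, "soft": soft, "lung": lung, "liver": liver,
                     "brain": brain, "bladder": bladder, "lesion": lesion_mask},
        plane_truth=planes,
        landmark_truth=landmark_truth,
        lesion_records=list(config.lesions),
    )

    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        suv = suv + rng.normal(0.0, config.noise_sd, size=suv.shape)
        np.clip(suv, 0.0, None, out=suv)

    volume = SuvVolume(data=suv, spacing=config.spacing, sex=config.sex,
                       id=f"phantom-{config.sex}-{config.seed}")
    return volume, truth


def anatomical_point(config: PhantomConfig, dx: float = 0.0, dy: float = 0.0,
                     f: float = 0.5) -> tuple[float, float, float]:
    """Voxel coordinates of an anatomically corresponding point.

    ``f`` is the body-height fraction (0 = feet end, 1 = head top); ``dx``
    and ``dy`` are offsets from the body axis in base voxels, scaled by the
    subject's physique. The same (dx, dy, f) addresses the same anatomical
    location in every phantom regardless of its jittered scales — useful for
    planting lesions at corresponding sites across a cohort.
    """
    nx, ny, nz = config.grid_shape
    fw, fd, fh = _sex_factors(config.sex)
    sx = config.torso_width_scale * fw * (nx / 64.0)
    sy = config.torso_depth_scale * fd * (ny / 64.0)
    z0 = 2
    H = int(round(0.82 * nz * config.torso_height_scale * fh))
    return ((nx - 1) / 2.0 + dx * sx, (ny - 1) / 2.0 + dy * sy,
            z0 + f * (H - 1))


def population_configs(base: PhantomConfig, n: int, seed: int) -> list[PhantomConfig]:
    """Jittered per-subject configs for a reproducible phantom cohort."""
    if n < 1:
        raise ValidationError(f"population size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    configs = []
    for i in range(n):
        j = {k: rng.uniform(*v) for k, v in POPULATION_JITTER.items()}
        scales = rng.uniform(*POPULATION_JITTER["scale"], size=3)
        suvs = dict(base.organ_suv_means)
        for organ in ("soft", "lung", "liver", "brain", "bladder"):
            suvs[organ] = base.organ_suv_means[organ] * j[organ]
        configs.append(replace(
            base,
            torso_width_scale=float(np.clip(base.torso_width_scale * scales[0], 0.51, 1.99)),
            torso_depth_scale=float(np.clip(base.torso_depth_scale * scales[1], 0.51, 1.99)),
            torso_height_scale=float(np.clip(base.torso_height_scale * scales[2], 0.51, 1.99)),
            organ_suv_means=suvs,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return configs


def phantom_population(base: PhantomConfig, n: int, seed: int
                       ) -> list[tuple[SuvVolume, PhantomTruth]]:
    """Generate ``n`` phantoms with per-subject physique and uptake jitter."""
    return [generate_phantom(c) for c in population_configs(base, n, seed)]
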