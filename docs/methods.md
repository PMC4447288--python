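# Methods

This note documents the models and procedures torsonorm implements, the
parameters that matter, what the synthetic phantom does and does not
emulate, and the design choices made where the underlying scheme left the
design open.

## SUV volumes and conventions

All computation happens on `SuvVolume`: a 3D float32 grid of body-weight
SUV (dimensionless) with per-axis voxel spacing in mm. The internal axis
convention is fixed: axis 0 = x (patient left → right), axis 1 = y
(anterior → posterior), axis 2 = z (inferior → superior); "axial",
"coronal" and "sagittal" planes are fixed-z, fixed-y and fixed-x slices,
and every detected plane is a 0-based voxel index on its axis. NIfTI files
are reoriented to this convention on read, so volumes from other tools are
usable directly.

`suv_convert` implements body-weight SUV,
`SUV = C[kBq/mL] · mass[g] / dose[kBq]`
(equivalently `activity · body_mass / injected_dose` with MBq and kg).
Body-surface-area normalization is not implemented: the SUV magnitudes this
pipeline is designed around (liver ≈ 2, soft tissue ≈ 1) are body-weight
values. The normalization mode is recorded in volume metadata.

## Rule-based segmentation and plane detection

The torso detectors are deliberately simple threshold/labeling rules; every
free parameter is surfaced in `PipelineConfig`:

* **Body**: largest 26-connected component of {SUV > 0.5}. The threshold
  separates tissue from air robustly on reconstructed PET; the
  largest-component rule removes injection-site artifacts and noise specks.
* **NS plane**: minimum body area over axial slices in the superior 35% of
  the body's z extent (`ns_band_fraction`); a global minimum could fall at
  the thighs, hence the band. Slices with area below 10% of the band median
  are ignored — they are noise specks clinging to the head top, not a neck.
  Ties break superior.
* **AC planes**: the sagittal body-area profile is smoothed (moving average
  over 3 positions) and the minima flanking the central peak are taken as
  the axillae. A minimum counts only if it is below 60% of the central peak
  *and* the profile rises again outward by ≥ 1.5× (otherwise the profile is
  just the torso tailing off and the scan has no resolvable arms — a
  detection error, not a guess).
* **TH plane**: scanning axial slices tail-to-head, slices with two
  8-connected 2D components of ≥ 50 voxels (`thigh_min_component`) are
  thigh slices; the first subsequent slice with one such component is TH.
  The size floor ignores noise specks between the legs.
* **A/P planes**: first and last coronal slices containing body voxels,
  computed over slices at or below NS only, so a head protruding beyond the
  chest line cannot bias the anterior plane.
* **Bladder / BL plane**: urinary FDG excretion makes the bladder the
  hottest structure in the pelvis, so thresholding suffices — but no
  absolute threshold is portable across injected doses, hence
  `max(5.0 SUV, 3 × soft-tissue median)`, restricted to the inferior 40% of
  the body's z extent and the medial 50% of its width, per coronal plane
  with 2D labeling, keeping the largest 3D-connected union. BL is the
  rounded z of the average per-coronal-plane centroid. If no candidate
  exists (tracer-empty bladder), BL falls back to 30% of the NS–TH span
  above TH and the run report flags it.
* **Liver / LV plane**: the liver is the hottest large soft-tissue organ in
  the right upper torso; threshold 1.3 × soft-tissue median, restricted to
  the patient-right half and to z between TH + 0.40 · (NS − TH) and NS.
  The 0.40 fraction (rather than the upper half) keeps the whole liver —
  including its inferior lobe — inside the search band while still
  excluding the bladder. Per coronal plane the largest 2D region of ≥ 20
  voxels is kept. LV is the liver apex (maximum z), the liver–lung
  boundary.

Fractional centroid and plane coordinates round half-up to voxel indices.

## Registration

The deformation is a pull-back composition of two stages, sampled on the
standard grid by nearest-neighbour lookup (so no voxel gaps arise, and no
intensity is ever invented — relevant when the voxels are SUVs).

**Piecewise affine cuboid map.** The 16 landmarks over-determine a single
affine (16 corners × 3 coordinates vs 12 dof), so the torso is split into
three z-slabs — NS–LV, LV–BL, BL–TH — each mapped by an axis-aligned
affine. The x and y maps (from the AC and A/P planes) are shared by all
slabs; z is piecewise linear with knots at TH, BL, LV, NS. This is the
minimal construction that maps all 16 corners exactly and is continuous at
the shared planes (verified to < 1e-9 in the tests). Regions beyond the
cuboid (head, legs) are carried along by linear extrapolation of the end
slabs. A global 12-dof least-squares affine over the 16 points is available
as `slab_mode = "global"` for comparison; it does not interpolate the
corners exactly and is not the default.

**Thin-plate-spline surface registration.** Control points are placed by
casting rays in-plane from each axial slice's body centroid at 15°
intervals (`angular_step`) and keeping the last body voxel per ray, on
axial levels every 5 slices (`level_spacing`, ≈ 20 mm at 4 mm spacing)
spanning the standard's NS–TH range. Correspondence between standard and
subject points is by (level, angle) tag. The number of control points is
therefore a property of the standard body's height, not a constant of the
method. The 3D TPS uses the kernel U(r) = r — the biharmonic fundamental
solution in 3D (the familiar r² log r kernel is the 2D case) — with
smoothing parameter λ = 0 by default (exact interpolation; anchor residual
< 1e-6 voxel). Exact duplicate anchors (adjacent rays hitting the same
boundary voxel on coarse grids) are collapsed to keep the interpolation
system nonsingular; genuinely degenerate configurations raise a solver
error with the condition number. The TPS is fitted in the standard→subject
direction so resampling is a pull-back.

Self-standardization of the standard body is idempotent: identical planes
are detected, the cuboid map is the identity, the TPS degenerates to the
identity, and nearest-neighbour resampling returns the input exactly.

## The normal model and Z-scores

`NormalUptakeModel.fit()` accumulates per-voxel mean and *sample* SD
(n − 1 denominator — the cohort is a sample from the normal population) in
a single streaming Welford pass in float64 with a fixed reduction order:
results are bit-reproducible across runs and independent of input order to
within float64 rounding. Models are sex-stratified; mixed-sex cohorts are
refused, since male and female physiques standardize onto different
standard bodies. Voxels outside the standard body mask are flagged invalid
rather than carrying meaningless air statistics. Models persist as a
versioned ZIP archive (mean/SD/valid NIfTI + JSON metadata) with
deterministic serialization: two saves of one model are byte-identical.

Z-scores are `(P − M)/SD` per voxel. Voxels with SD below 0.05 SUV
(`sd_floor`) are marked invalid instead of producing explosive values —
near-zero SD occurs in air and at body fringes. Spot scores report SUVmax,
the Z at the SUVmax voxel (ties resolved toward the higher Z), and the
max/mean Z over model-valid spot voxels; `z_at_suvmax` is the headline
field, matching the single-voxel readout convention of per-lesion
reporting, with `z_max` alongside since the two can disagree in location.
Spot masks are expected in standard space; masks drawn in native space can
be carried through the recorded deformation with `apply_registration`.

## The synthetic phantom

The phantom emulates exactly the geometric and statistical structure the
pipeline presumes, with complete ground truth:

* a body of stacked elliptical axial cross-sections: two thighs merging at
  a known slice, hips, abdomen, a chest flanked by arms separated from it
  by a ≥ 2-voxel air gap (bridged to the trunk by a deltoid-like shoulder
  taper), a neck with a unique area minimum, and a truncated-ellipsoid
  head;
* organ ellipsoids with configurable mean SUV — defaults: soft tissue 1.0,
  lung 0.7, liver 2.0, brain 6.0, bladder 20.0. These are chosen for
  detector well-posedness at the typical body-weight-SUV scale, not fitted
  to any clinical table; the lung default sits above the 0.5 body threshold
  so the body mask stays exact. The liver apex displaces lung space where
  they overlap, reproducing the liver–lung boundary the LV plane needs;
* additive Gaussian noise in SUV units, clipped at zero (the conventional
  approximation for reconstructed PET), default SD 0.1 for cohorts and 0
  for exactness tests;
* optional spherical lesions (center, radius in mm, SUV), validated to lie
  inside the body;
* cohort jitter (`phantom_population`): per-subject multiplicative uniform
  jitter — physique scales ×U(0.92, 1.08), soft tissue ×U(0.92, 1.08),
  lung ×U(0.85, 1.15), liver ×U(0.90, 1.10), brain ×U(0.85, 1.15), bladder
  ×U(0.60, 1.40). The wide bladder range deliberately makes it the
  high-variance structure, emulating urine filling, which is what lets the
  Z-score discount it. Female phantoms are scaled-down physiques
  (0.90/0.92/0.92 in width/depth/height), mirroring population height and
  weight differences.

Geometry scales with the grid, so the same anatomy renders at any
resolution; the test suite uses 48³ phantoms for unit tests and 64³ (4 mm
voxels) for the end-to-end cohorts — 50 standardized normals and 20 lesion
patients — keeping the whole suite within a few minutes on one CPU.

What the phantom does **not** model: PET physics (attenuation, scatter,
partial volume), brown-fat and muscle-uptake confounders, arm-pose
variation, kidneys/ureters, non-ellipsoidal organ shapes, and any real
inter-subject anatomical topology variation. Passing tests therefore
demonstrate the pipeline's correctness and its discrimination logic under
controlled physique/uptake/noise variation — not clinical performance on
patient scans, which would require a real normal database.

The axilla (AC planes) has no geometric definition independent of the
area-profile rule itself, so the phantom's AC ground truth *is* that rule
evaluated on the noiseless drawn body; the tests verify the detector
against an independent brute-force implementation and under noise.

## Numerical choices and degenerate inputs

* Nearest-neighbour index snapping uses floor(v + 0.5) (half-up),
  everywhere, for determinism across platforms.
* TPS systems are solved dense (a few hundred anchors); condition numbers
  above 1e12 raise a solver error naming the diagnostic.
* Detector tie-breaks: NS ties go superior; AC minima ties go toward the
  torso; SUVmax ties in spot scoring go to the higher Z.
* Degenerate inputs fail loudly with typed errors: empty body, unimodal
  sagittal profile (no arms), legs never uniting (cropped scans), empty
  organ masks, landmark sets violating the TH < BL < LV < NS ordering, sex
  mismatches, and sub-minimal cohorts (n < 2).

## Known limitations

* The piecewise-affine reading of the 16-point registration is this
  package's principal interpretation; a global least-squares affine is
  provided behind a config switch but shares the cuboid's rigidity either
  way — no elastic/diffeomorphic registration is attempted.
* Plane detection assumes arms-down whole-torso acquisitions that include
  the thighs and at least part of the head/neck.
* The bladder fallback (BL at 30% of the NS–TH span) is a coarse prior for
  tracer-empty bladders and is flagged in the run report when used.
* CT-based organ recognition, serial-scan subtraction and automated lesion
  detection are out of scope.
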