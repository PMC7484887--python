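# Methods

This note records the models, conventions, parameter choices and known
limitations behind `stereoct`.

## Geometry and conventions

All volumes share one axis convention: `x` = left–right, `y` =
anterior–posterior increasing posteriorly, `z` = superior–inferior with
slice index 0 superior-most and the world `z` coordinate growing
inferiorly. Coordinates are voxel-centre based, in mm; indices 0-based. HU
values are clamped to the 12-bit scanner range [−1024, 4095]; dense dental
amalgam saturates near the top of that range.

A gantry-tilted acquisition is stored the way scanners deliver it: an
ordinary slice stack whose slice step is the couch-axis increment, with
the signed tilt angle as metadata. **Sign convention:** `tilt_angle_deg >
0` (the "superior" tilt) is defined as the tilt whose untilt transform
displaces posterior content toward inferior slice indices. This is the
orientation the merge step requires — the superior half of the merged
volume comes from the positive-tilt scan, so that scan's posterior
artifacts must untilt into the discarded inferior half. The opposite sign
mirrors the shear.

## Untilt transform

Exact stack geometry for a tilt θ about the LR axis gives, in voxel-index
units with in-plane AP spacing `dy` and slice step `dz`:

* in-slice AP coordinate elongated by 1/cos θ;
* true slice position offset across slices by sin θ·(dy/dz) per AP index.

Untilting is therefore a sagittal-plane shear (factor `sh_zy =
sin θ·dy/dz`) followed by an AP scaling (`cos θ`), which is also the
decomposition behind the published per-angle factor table. Two factor
sources are provided:

* `table` — the published empirical calibration at 5°…30° in 5° steps,
  valid for a 0.55 mm / 2.5 mm grid. Canonical when reproducing the
  published numbers. The geometric formulas reproduce it to ≤ 0.006 at
  every angle (the worst case is the 20° scaling, 0.9397 vs 0.945); the
  small residuals reflect the empirical calibration of the original
  scanner and are not recoverable from theory.
* `geometric` — the closed form above, valid for any angle ≤ 30° and any
  grid. This is the default: it is exactly self-consistent with the
  simulator's forward model, so round-trip errors are pure interpolation
  blur.

Both shear and scale are applied about the grid centre as a **single**
inverse-mapping resample with linear interpolation (out-of-field fill
−1000 HU, air). Composing the two steps into one resample avoids a second
interpolation pass; the two-step path exists behind
`TransformSpec(single_resample=False)` for comparison. The simulator's
forward model is the exact matrix inverse on the same grid, so
`untilt(apply_tilt(V, θ))` differs from `V` only by the symmetric blur of
two linear resamplings — interior ROI means recover to ≪ 1 HU.

The per-voxel RMS round-trip error generally grows with θ but is not
strictly monotone angle-to-angle: it depends on the fractional alignment
of the sheared sampling lattice. Tests assert the 30° blur exceeds the 5°
blur rather than full monotonicity.

## Metal detection and merge

Detection runs on untilted volumes: the first and last slices containing
any voxel above `merge.metal_threshold_hu` (default 2000 HU — above
cortical bone/teeth at 1500 HU, below amalgam at 3500 HU) bound the
metal band; the reference slice is `round((first+last)/2)` with exact
halves rounding toward the inferior (larger) index — a fixed, documented,
arbitrary tie-break. The two scans' references may disagree by a couple of
slices because partial-volume metal at the band edges interpolates just
below threshold; mismatches up to `merge.reference_mismatch_tol` (default
2) are averaged, larger ones are an error naming both references.

The merged volume takes slice `k < r` from the superior-tilt untilted scan
and `k ≥ r` from the inferior one; slice count, grid and (corrected, now
axial) metadata are conserved. A pair without any metal degrades to plain
untilting of the superior scan, with a warning rather than an error.

Geometric consequence of the merge: at tilt θ a posterior point at AP
offset `Δy` from the shear centre has its artifact band displaced by
`tan θ·Δy` mm along SI, so the posterior region clears progressively with
angle; at 5° the displacement (≈ 4 mm at the plugs) is smaller than the
band half-width (10 mm) and residual streaks of a few tens of HU survive
around the reference slice, vanishing by ~15°. Residual artifacts in the
corrected volume concentrate around and anterior of the metal at every
angle — the deliberate trade-off of the method.

## Digital phantom

A 150 × 135 × 80 mm high-impact polystyrene block holds two dental arches
of 16 cylindrical cortical-bone teeth (⌀8 mm, 30 mm long; upper arch
radius 38 mm, lower 32 mm, stacked in SI so the jaws do not intersect) and
five posterior plugs. Material HU (mean, voxel SD): polystyrene (−36, 2),
PBT (693, 2), cork (−758, 10), blue water (87, 0), Techtron HPV (218, 1),
solid water (29, 1), air (−1000, 0), teeth (1500, 10), amalgam (3500, 30).
Teeth and amalgam HU are modelling choices: cortical-bone substitute below
the metal threshold, dental alloy safely above it.

With `amalgam=True` all eight lower-arch teeth carry ⌀5 × 15 mm amalgam
cores near the bite plane, with alternating 0/+5 mm SI offsets so the
union of fillings spans a ~20 mm metal-affected band at 0° — the band
extent reported for the physical phantom. The plug layout (PBT and
Techtron cylinders lateral-posterior, solid/blue water boxes further
posterior, cork central) is schematic: only "posterior to the teeth" is
physically constrained, and the defaults were fixed once so that plugs are
pairwise disjoint, centred on the metal band, and leave room for profile
backgrounds.

Rasterisation composites structures with partial-volume fractions (exact
per-axis overlap for boxes; a one-voxel linear rim ramp for cylinders) and
draws per-voxel material noise from a generator keyed on `(seed,
structure name)`, so adding fillings does not perturb the noise of any
other structure. Sibling structures are validated to be disjoint; the
phantom must lie inside the grid.

**Scan simulation** applies the exact inverse of the untilt (so the study
round trip is closed), then injects streaks into every stack slice whose
plane intersects metal, then optional Gaussian scan noise, then clamps to
the HU range. The streak model is acknowledged phenomenology, not physics:
per metal-component rays `A·cos(n·φ + phase)·exp(−ρ/decay)` with a random
phase per component and slice, plus constant dark bands joining adjacent
component centroids. Defaults (A = 220 HU, n = 12, decay = 35 mm, dark
band 120 HU over 6 mm, scan noise 0 — material noise already models
texture) were calibrated once so the uncorrected 0° metal scan drives the
posterior plug ROI SDs to 12–47 HU, matching the order of magnitude of the
published uncorrected-scan SDs (9–57 HU); they were not revisited
afterwards. What passing tests show about real data is therefore limited:
streak confinement, magnitude at the plugs, and removability are emulated;
beam-hardening physics, scanner-specific texture, patient motion and
couch-sag misregistration between the two scans are not.

## Measurement protocol

Structure widths are FWHMs of HU profiles through each structure centre
along AP/LR/SI, sampled on the native voxel-centre lattice with linear
interpolation. Profiles are strip-averaged ("thick-slab", as
planning-system profile tools do): AP/LR profiles average across slices
well inside the plug and ±2 mm laterally; SI profiles average over the
plug's interior cross-section. Averaging across slices suppresses streak
noise (phases decorrelate slice to slice) without blurring along the
measured axis; without it, anterior streaks produce false half-maximum
crossings on the body's AP profile.

The half level sits midway between the plateau and the per-side local
background (median of the outer 10% of the window). Two plateau
estimators exist: `median` (default) takes the median of the central 50%
of the window, then refines to the central quarter of the measured
structure — robust for the flat-topped plugs and immune to single-sample
streaks; `peak` takes the most extreme central sample — correct for
peaked (triangular/Gaussian) profiles, and verified against the
closed-form Gaussian width 2√(2 ln 2)σ. Crossings are located by linear
interpolation between bracketing samples, giving sub-voxel widths.
Profile windows per structure extend ~5–10 mm past the structure but stay
inside the body (so the background is polystyrene, not air) and clear of
neighbouring plugs; the body's windows reach into air.

ROI statistics use voxel centres inside a fixed interior region (2 mm
margins; population SD, divisor *n* — the convention of the published
tables' parentheses is not disclosed, so one was fixed). The body ROI is
a fixed posterior strip clear of all plugs.

**Trend analysis.** Distortion (corrected − baseline FWHM) and ROI HU are
regressed against gantry angle by OLS. For the "no significant trend"
check the slope/intercept standard errors are floored at the values
implied by the published per-direction FWHM measurement reproducibility
(SD 0.12 / 0.13 / 0.33 mm for AP/LR/SI): the automated measurement
repeats to machine precision, so plain OLS would flag angle patterns
(e.g. the 5–10° partial-clearance residuals, 0.03–0.3 mm decaying with
angle) that are far below what the original measurement process could
resolve. Plain OLS remains the default of `trend_fit` and matches the
textbook closed form to 1e−10.

## Study conditions and problem sizes

The packaged experiment (`run_study`, `stereoct demo`,
`scripts/acceptance.py`) uses a 256 × 256 in-plane grid at 0.7 mm with 80
slices of 2.5 mm — chosen once as the scale at which the whole six-angle
study (12 simulated scans, 12 untilts, 6 merges, 324 profile
measurements) completes in about twenty seconds while keeping every plug
several voxels across. The phantom generator's own default grid remains
512 × 512 at 0.55 mm. Unit tests use a 128 × 128 grid at 1.4 mm with the
same physical phantom. All randomness flows from a single integer seed:
phantom noise streams are keyed per structure name, scan streams per
(seed, angle).

## Known limitations

* Registration between the two tilted scans is assumed perfect (same
  grid); patient motion and couch sag are out of scope.
* The streak model is schematic; conclusions about artifact *appearance*
  on real scanners should not be drawn from it.
* The merge is a hard splice at one slice boundary; no blending across
  the reference slice is attempted.
* Tilts beyond 30° are rejected — outside both the factor table and the
  validated range.
* DICOM support covers plain CT series with rescale tags and the gantry
  tilt attribute; vendor-private tags are ignored.
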