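# stereoct

Stereoscopic CT metal-artifact management for head-and-neck imaging, plus
the digital phantom and QA tooling needed to validate it without a
scanner.

## The problem

Dental amalgam fillings scatter bright/dark streaks across exactly the CT
slices where head-and-neck disease usually sits — posterior to the oral
cavity. The streaks (beam hardening and photon starvation) corrupt both
anatomy visualisation and the Hounsfield units (HU) that radiotherapy dose
calculation depends on. Sinogram-interpolation artifact reduction replaces
corrupted projections with synthetic data and can make dental artifacts
worse.

`stereoct` implements an image-space alternative: acquire **two** scans at
opposite gantry tilts. In each tilted scan the artifact-bearing slice
planes pivot about the metal, so the posterior region is clean on one side
of the fillings. Untilt both stacks, locate the metal, and splice the
clean halves together.

## The algorithm

**Step 1 — untilt.** A stack acquired at gantry tilt θ is, relative to
axial geometry, elongated along AP by 1/cos θ and sheared across slices.
It is restored by the affine map *I = M·I′* with a single active shear
element *sh_zy* followed by an AP scaling *M₂,₂*, resampled once with
linear interpolation:

    shear   sh_zy = sin θ · (dy / dz)      (index units)
    scale   M₂,₂  = cos θ

either computed geometrically from the grid (default) or taken from the
published per-angle calibration table (0.019/0.999 at 5° … 0.108/0.871 at
30°).

**Step 2 — merge.** Each untilted volume is swept from the superior-most
slice for the first voxel above the metal threshold (2000 HU), and from
the inferior end for the last; the reference slice is the centre of that
band. The output takes slices superior of the reference from the
superiorly tilted scan and the rest from the inferiorly tilted scan. Slice
count is conserved, the tilt metadata is corrected to 0, and residual
streaks are confined to the anterior region (nose/chin), which rarely
holds disease or organs at risk.

The package also provides:

* `phantom` — a digital 15 × 13.5 × 8 cm polystyrene jaw phantom with
  cortical-bone teeth, optional 1.5 cm amalgam fillings, and five
  posterior plugs (PBT, cork, blue water, Techtron HPV, solid water) with
  table-derived baseline HU; plus a tilted-scan simulator whose forward
  model is the exact inverse of the untilt, with a seeded streak model.
* `evaluate` — the QA protocol: sub-voxel FWHM structure widths from
  strip-averaged HU profiles (AP/LR/SI), fixed-ROI HU mean/SD, distortion
  tables, and angle-trend regressions.

## Worked example

```python
import stereoct as sc

# digital amalgam phantom on the study grid (256x256 @ 0.7 mm, 80 x 2.5 mm)
spec    = sc.PhantomSpec(amalgam=True, spacing=(0.7, 0.7, 2.5), grid_shape=(80, 256, 256))
phantom = sc.build_phantom(spec, seed=1)
clean   = sc.build_phantom(sc.PhantomSpec(amalgam=False, spacing=spec.spacing,
                                          grid_shape=spec.grid_shape), seed=1)

model = sc.ArtifactModel(seed=1)
sup = sc.simulate_tilted_scan(phantom, +25.0, model)   # superiorly tilted scan
inf = sc.simulate_tilted_scan(phantom, -25.0, model)   # inferiorly tilted scan
corrected, report = sc.reduce_artifacts(sup, inf)
print(report["band_superior"], report["reference"])

for m in sc.measurement_specs(spec):
    base, _ = sc.roi_stats(clean, m.roi)
    corr, _ = sc.roi_stats(corrected, m.roi)
    print(f"{m.name:12s} baseline {base:8.1f} HU   corrected {corr:8.1f} HU")
```

prints

```
[39, 47] 43
pbt          baseline    693.0 HU   corrected    693.0 HU
techtron     baseline    218.0 HU   corrected    218.0 HU
solid_water  baseline     29.0 HU   corrected     29.0 HU
blue_water   baseline     87.0 HU   corrected     87.0 HU
cork         baseline   -757.8 HU   corrected   -757.8 HU
body         baseline    -36.0 HU   corrected    -36.0 HU
```

The metal band spans slices 39–47 (≈ 2 cm for the 1.5 cm
fillings), the merge happens at slice 43, and every posterior ROI of the
corrected volume matches the metal-free baseline to a fraction of an HU —
the same volumes scanned at 0° with metal show errors of tens of HU and
ROI SDs of 12–47 HU.

A one-command version of the whole experiment (six angles, distortion and
HU tables, trend fits) is:

```bash
stereoct demo --out demo_run --seed 1
```

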