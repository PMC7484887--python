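"""Digital head-and-neck jaw phantom and tilted-scan simulator.

The phantom emulates a 15 × 13.5 × 8 cm high-impact polystyrene jaw block:
two dental arches of ~3 cm cortical-bone teeth (the lower arch optionally
carrying 1.5 cm amalgam fillings in all eight teeth), and five posterior
plugs — PBT, cork, blue water, Techtron HPV and solid water — spanning the
HU range seen in head-and-neck patients.  Material HU means/SDs follow the
baseline column of the published plug table; teeth are set to 1500 HU
(cortical-bone substitute, below the 2000 HU metal threshold) and amalgam
to 3500 HU (dense dental alloy, comfortably above it).

The exact AP/LR plug layout and arch geometry are only qualitatively
constrained ("located posterior to the teeth"), so the defaults here are a
fixed schematic arrangement: plugs disjoint, posterior of the arches, and
centred on the metal-affected slice band.  Per-tooth SI offsets of the
fillings (0 or +5 mm) make the 15 mm amalgam span a ~20 mm band of
metal-affected slices in the 0° scan.

Scan simulation is the exact affine inverse of the untilt transform (AP
elongation by 1/cos θ, shear across slices), followed by streak injection
into every stack slice whose plane intersects amalgam, and optional
Gaussian noise.  Streaks are a phenomenological stand-in for beam-hardening
and photon-starvation artifacts: alternating bright/dark rays radiating
from each metal centroid with radial decay, plus dark bands joining
adjacent centroids.  Streak realism is deliberately schematic — what
matters for the pipeline is their confinement to metal-intersecting slice
planes and their magnitude at the posterior plugs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import PhantomError
from .tilt import TransformSpec, apply_tilt
from .volume import HU_MAX, HU_MIN, Volume

# --------------------------------------------------------------------------
# materials
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Material:
    """Mean HU and voxel-to-voxel noise SD of one phantom material."""

    mean_hu: float
    noise_sd_hu: float = 0.0


def default_materials() -> dict[str, Material]:
    """Baseline HU assignments (mean, SD) for every phantom material."""
    return {
        "air": Material(-1000.0, 0.0),
        "polystyrene": Material(-36.0, 2.0),
        "pbt": Material(693.0, 2.0),
        "cork": Material(-758.0, 10.0),
        "blue_water": Material(87.0, 0.0),
        "techtron": Material(218.0, 1.0),
        "solid_water": Material(29.0, 1.0),
        "teeth": Material(1500.0, 10.0),
        "amalgam": Material(3500.0, 30.0),
    }


def validate_materials(materials: dict[str, Material], metal_threshold_hu: float = 2000.0) -> None:
    """Check the metal/non-metal HU separation invariants."""
    for name, mat in materials.items():
        if name == "amalgam":
            if mat.mean_hu <= metal_threshold_hu:
                raise PhantomError(f"amalgam HU {mat.mean_hu} must exceed the metal threshold")
        elif not -1000.0 <= mat.mean_hu <= 1600.0:
            raise PhantomError(f"non-metal material {name!r} HU {mat.mean_hu} outside [-1000, 1600]")


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Structure:
    """One solid of the phantom, positioned relative to the grid centre.

    ``shape`` is ``"box"`` (size = full x/y/z extents, mm) or ``"cylinder"``
    (axis along SI; size = (diameter, diameter, length), mm).  ``children``
    are solids intentionally nested inside this one (fillings in teeth,
    everything in the body); siblings must be pairwise disjoint.
    """

    name: str
    material: str
    shape: str  # "box" | "cylinder"
    center: tuple[float, float, float]  # (x, y, z) mm relative to grid centre
    size: tuple[float, float, float]  # full extents (x, y, z) mm
    children: tuple["Structure", ...] = ()


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the digital jaw phantom and its acquisition grid.

    Defaults reproduce the physical phantom's dimensions on a 0.55 mm
    in-plane / 2.5 mm slice grid; tests and the packaged experiment use a
    coarser 0.7 mm in-plane grid so the whole study runs quickly.
    """

    body_size: tuple[float, float, float] = (150.0, 135.0, 80.0)
    tooth_length_mm: float = 30.0
    tooth_diameter_mm: float = 8.0
    amalgam_length_mm: float = 15.0
    amalgam_diameter_mm: float = 5.0
    amalgam: bool = False
    spacing: tuple[float, float, float] = (0.55, 0.55, 2.5)  # (dx, dy, dz)
    grid_shape: tuple[int, int, int] = (80, 512, 512)  # (nz, ny, nx)
    arch_center_y: float = -22.0
    upper_arch_radius: float = 38.0
    lower_arch_radius: float = 32.0
    tooth_angles_deg: tuple[float, ...] = (-80.0, -55.0, -30.0, -10.0, 10.0, 30.0, 55.0, 80.0)

    def __post_init__(self):
        if self.amalgam_length_mm > self.tooth_length_mm:
            raise PhantomError("amalgam insert longer than the tooth")

    # -- derived layout ----------------------------------------------------

    def _arch(self, radius: float, z_center: float, length: float, diameter: float,
              prefix: str, material: str, fillings: bool) -> list[Structure]:
        teeth = []
        for i, ang in enumerate(self.tooth_angles_deg):
            a = math.radians(ang)
            x = radius * math.sin(a)
            y = self.arch_center_y - radius * math.cos(a)
            children: tuple[Structure, ...] = ()
            if fillings:
                # fillings sit in the crown near the bite plane, alternating
                # per-tooth SI offsets so the metal band spans ~20 mm
                dz_off = 5.0 * (i % 2)
                fill_zc = z_center - length / 2 + self.amalgam_length_mm / 2 + dz_off
                children = (
                    Structure(
                        name=f"{prefix}_tooth_{i}_amalgam",
                        material="amalgam",
                        shape="cylinder",
                        center=(x, y, fill_zc),
                        size=(self.amalgam_diameter_mm, self.amalgam_diameter_mm, self.amalgam_length_mm),
                    ),
                )
            teeth.append(
                Structure(
                    name=f"{prefix}_tooth_{i}",
                    material=material,
                    shape="cylinder",
                    center=(x, y, z_center),
                    size=(diameter, diameter, length),
                    children=children,
                )
            )
        return teeth

    def plugs(self) -> list[Structure]:
        """The five posterior plugs, centred in the metal band (z = +10 mm)."""
        return [
            Structure("pbt", "pbt", "cylinder", (-35.0, 22.0, 10.0), (25.0, 25.0, 10.0)),
            Structure("techtron", "techtron", "cylinder", (35.0, 22.0, 10.0), (20.0, 20.0, 10.0)),
            Structure("solid_water", "solid_water", "box", (-30.0, 46.0, 10.0), (20.0, 10.0, 20.0)),
            Structure("blue_water", "blue_water", "box", (30.0, 46.0, 10.0), (20.0, 10.0, 10.0)),
            Structure("cork", "cork", "box", (0.0, 38.0, 10.0), (20.0, 20.0, 40.0)),
        ]

    def teeth(self) -> list[Structure]:
        tl, td = self.tooth_length_mm, self.tooth_diameter_mm
        upper = self._arch(self.upper_arch_radius, -2.5 - tl / 2, tl, td, "upper", "teeth", False)
        lower = self._arch(self.lower_arch_radius, -2.5 + tl / 2, tl, td, "lower", "teeth", self.amalgam)
        return upper + lower

    def body(self) -> Structure:
        return Structure(
            "body", "polystyrene", "box", (0.0, 0.0, 0.0), self.body_size,
            children=tuple(self.teeth() + self.plugs()),
        )


# --------------------------------------------------------------------------
# rasterisation
# --------------------------------------------------------------------------


def _structure_seed(seed: int, name: str) -> np.random.SeedSequence:
    # keyed by structure name so adding/removing siblings (e.g. amalgam)
    # does not shift the noise of unrelated structures
    return np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])


def _grid_axes(spec: PhantomSpec):
    nz, ny, nx = spec.grid_shape
    dx, dy, dz = spec.spacing
    xs = (np.arange(nx) - (nx - 1) / 2) * dx
    ys = (np.arange(ny) - (ny - 1) / 2) * dy
    zs = (np.arange(nz) - (nz - 1) / 2) * dz
    return zs, ys, xs


def _axis_overlap(coords: np.ndarray, step: float, lo: float, hi: float) -> np.ndarray:
    """Fraction of each voxel cell [c-step/2, c+step/2] inside [lo, hi]."""
    left = np.maximum(coords - step / 2, lo)
    right = np.minimum(coords + step / 2, hi)
    return np.clip((right - left) / step, 0.0, 1.0)


def _occupancy(struct: Structure, spec: PhantomSpec):
    """Fractional occupancy of ``struct`` on the grid, restricted to a bbox.

    Returns ``(slices, frac)`` where ``slices`` are (z, y, x) index slices of
    the bounding box and ``frac`` the occupancy fraction array.  Box overlap
    fractions are exact per axis; cylinder radial fractions use a one-voxel
    linear ramp at the rim (adequate partial-volume model at these voxel
    sizes).
    """
    zs, ys, xs = _grid_axes(spec)
    dx, dy, dz = spec.spacing
    cx, cy, cz = struct.center
    sx, sy, sz = struct.size
    bounds = [
        (cz - sz / 2 - dz, cz + sz / 2 + dz, zs, 0),
        (cy - sy / 2 - dy, cy + sy / 2 + dy, ys, 1),
        (cx - sx / 2 - dx, cx + sx / 2 + dx, xs, 2),
    ]
    idx = []
    for lo, hi, coords, _ in bounds:
        sel = np.flatnonzero((coords >= lo) & (coords <= hi))
        if sel.size == 0:
            return None, None
        idx.append(slice(int(sel[0]), int(sel[-1]) + 1))
    zi, yi, xi = idx
    zloc, yloc, xloc = zs[zi], ys[yi], xs[xi]
    fz = _axis_overlap(zloc, dz, cz - sz / 2, cz + sz / 2)
    if struct.shape == "box":
        fy = _axis_overlap(yloc, dy, cy - sy / 2, cy + sy / 2)
        fx = _axis_overlap(xloc, dx, cx - sx / 2, cx + sx / 2)
        frac = fz[:, None, None] * fy[None, :, None] * fx[None, None, :]
    elif struct.shape == "cylinder":
        radius = sx / 2
        r = np.hypot(yloc[:, None] - cy, xloc[None, :] - cx)
        fr = np.clip((radius - r) / max(dx, dy) + 0.5, 0.0, 1.0)
        frac = fz[:, None, None] * fr[None, :, :]
    else:
        raise PhantomError(f"unknown shape {struct.shape!r} for {struct.name!r}")
    return (zi, yi, xi), frac


def _check_inside_grid(struct: Structure, spec: PhantomSpec) -> None:
    nz, ny, nx = spec.grid_shape
    dx, dy, dz = spec.spacing
    half = ((nx - 1) / 2 * dx, (ny - 1) / 2 * dy, (nz - 1) / 2 * dz)
    for c, s, h, axis in zip(struct.center, struct.size, half, "xyz"):
        if c - s / 2 < -h or c + s / 2 > h:
            raise PhantomError(f"structure {struct.name!r} exceeds the grid along {axis}")


def _paint(vox: np.ndarray, struct: Structure, spec: PhantomSpec,
           materials: dict[str, Material], seed: int,
           sibling_fracs: list) -> None:
    mat = materials.get(struct.material)
    if mat is None:
        raise PhantomError(f"structure {struct.name!r} uses unknown material {struct.material!r}")
    slices, frac = _occupancy(struct, spec)
    if slices is None:
        raise PhantomError(f"structure {struct.name!r} lies outside the grid")
    value = np.full(frac.shape, mat.mean_hu)
    if mat.noise_sd_hu > 0:
        rng = np.random.default_rng(_structure_seed(seed, struct.name))
        value += rng.normal(0.0, mat.noise_sd_hu, size=frac.shape)
    region = vox[slices]
    vox[slices] = (1.0 - frac) * region + frac * value
    sibling_fracs.append((struct.name, slices, frac))
    child_fracs: list = []
    for child in struct.children:
        _paint(vox, child, spec, materials, seed, child_fracs)


def _check_disjoint(sibling_fracs: list) -> None:
    for i in range(len(sibling_fracs)):
        for j in range(i + 1, len(sibling_fracs)):
            name_a, sl_a, fa = sibling_fracs[i]
            name_b, sl_b, fb = sibling_fracs[j]
            inter = []
            for a, b in zip(sl_a, sl_b):
                lo, hi = max(a.start, b.start), min(a.stop, b.stop)
                if lo >= hi:
                    inter = None
                    break
                inter.append((lo, hi))
            if inter is None:
                continue
            sub_a = tuple(slice(lo - a.start, hi - a.start) for (lo, hi), a in zip(inter, sl_a))
            sub_b = tuple(slice(lo - b.start, hi - b.start) for (lo, hi), b in zip(inter, sl_b))
            overlap = fa[sub_a] * fb[sub_b]
            if float(overlap.max(initial=0.0)) > 0.25:
                raise PhantomError(f"structures {name_a!r} and {name_b!r} overlap")


def build_phantom(
    spec: PhantomSpec = PhantomSpec(),
    materials: dict[str, Material] | None = None,
    seed: int = 0,
) -> Volume:
    """Rasterise the phantom into an axial (tilt 0) HU volume.

    Interior voxels of each structure are drawn from its material's
    (mean, SD); boundary voxels are partial-volume blends.  Sibling
    structures are validated to be pairwise disjoint and the body must lie
    inside the grid.
    """
    materials = default_materials() if materials is None else materials
    validate_materials(materials)
    body = spec.body()
    _check_inside_grid(body, spec)
    for tooth in spec.teeth() + spec.plugs():
        _check_inside_grid(tooth, spec)

    nz, ny, nx = spec.grid_shape
    air = materials["air"]
    vox = np.full((nz, ny, nx), air.mean_hu, dtype=float)
    if air.noise_sd_hu > 0:
        rng = np.random.default_rng(_structure_seed(seed, "air"))
        vox += rng.normal(0.0, air.noise_sd_hu, size=vox.shape)

    top_level: list = []
    _paint(vox, body, spec, materials, seed, top_level)
    # disjointness among the body's children (teeth + plugs); parent-child
    # nesting (fillings in teeth, everything in the body) is intentional
    child_fracs: list = []
    for child in body.children:
        slices, frac = _occupancy(child, spec)
        child_fracs.append((child.name, slices, frac))
    _check_disjoint(child_fracs)

    np.clip(vox, HU_MIN, HU_MAX, out=vox)
    dx, dy, dz = spec.spacing
    origin = (-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, -(nz - 1) / 2 * dz)
    return Volume(vox, spacing=spec.spacing, origin=origin, tilt_angle_deg=0.0)


# --------------------------------------------------------------------------
# artifact model and scan simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactModel:
    """Phenomenological streak model injected into metal-intersecting slices.

    ``streak_amplitude_hu`` scales the alternating bright/dark rays
    (``n_streaks`` angular periods, exponential radial decay over
    ``decay_mm``); ``dark_band_hu`` is subtracted in bands of width
    ``dark_band_width_mm`` joining adjacent metal centroids;
    ``noise_sd_hu`` adds Gaussian scan noise everywhere.  Defaults were
    calibrated once so that the uncorrected 0° metal scan drives the
    posterior solid-water ROI SD to the order of the published uncorrected
    values (tens of HU).  A model with zero streak amplitude and zero dark
    band injects nothing.
    """

    streak_amplitude_hu: float = 220.0
    n_streaks: int = 12
    decay_mm: float = 35.0
    dark_band_hu: float = 120.0
    dark_band_width_mm: float = 6.0
    noise_sd_hu: float = 0.0
    metal_threshold_hu: float = 2000.0
    seed: int = 0

    @property
    def is_null(self) -> bool:
        return self.streak_amplitude_hu == 0.0 and self.dark_band_hu == 0.0


def inject_streaks(
    slice_hu: np.ndarray,
    metal_mask: np.ndarray,
    model: ArtifactModel,
    rng: np.random.Generator,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Return a copy of one (y, x) slice with streak artifacts added.

    Rays radiate from the centroid of each connected metal component with a
    random angular phase; dark bands join adjacent centroids (ordered by
    LR position).  An empty mask returns the slice unchanged.  Output is
    clamped to the HU storage range.
    """
    if not np.any(metal_mask) or model.is_null:
        return slice_hu.copy()
    from scipy import ndimage as ndi

    dx, dy = spacing
    labels, n = ndi.label(metal_mask)
    centroids = ndi.center_of_mass(metal_mask, labels, range(1, n + 1))  # (y, x) index
    ny, nx = slice_hu.shape
    yy = np.arange(ny)[:, None] * dy
    xx = np.arange(nx)[None, :] * dx
    art = np.zeros_like(slice_hu, dtype=float)
    pts = []
    for cy, cx in centroids:
        cy_mm, cx_mm = cy * dy, cx * dx
        pts.append((cx_mm, cy_mm))
        if model.streak_amplitude_hu != 0.0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            dyy = yy - cy_mm
            dxx = xx - cx_mm
            rho = np.hypot(dyy, dxx)
            phi = np.arctan2(dyy, dxx)
            art += (
                model.streak_amplitude_hu
                * np.cos(model.n_streaks * phi + phase)
                * np.exp(-rho / model.decay_mm)
            )
    if model.dark_band_hu != 0.0 and len(pts) >= 2:
        pts.sort()
        half_w = model.dark_band_width_mm / 2.0
        for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
            vx, vy = x2 - x1, y2 - y1
            seg2 = vx * vx + vy * vy
            if seg2 == 0:
                continue
            t = np.clip(((xx - x1) * vx + (yy - y1) * vy) / seg2, 0.0, 1.0)
            dist = np.hypot(xx - (x1 + t * vx), yy - (y1 + t * vy))
            art -= model.dark_band_hu * (dist < half_w)
    out = slice_hu + art
    np.clip(out, HU_MIN, HU_MAX, out=out)
    return out


def simulate_tilted_scan(
    phantom: Volume,
    angle_deg: float,
    artifact_model: ArtifactModel | None = None,
    transform_spec: TransformSpec = TransformSpec(),
) -> Volume:
    """Simulate a CT acquisition of an axial phantom at a gantry tilt.

    Forward model: the exact affine inverse of the untilt transform on the
    same grid (identity at 0°), then streak injection into every stack
    slice whose plane intersects metal, then additive Gaussian noise.  With
    no artifact model (or a null one) and angle 0 the output is
    voxel-identical to the phantom.  Seeded generation is reproducible; the
    per-scan stream is keyed on (model seed, angle).
    """
    if abs(angle_deg) > 30.0 + 1e-9:
        raise PhantomError(f"|angle| must be <= 30°, got {angle_deg}")
    tilted = apply_tilt(phantom, angle_deg, transform_spec)
    if artifact_model is None:
        return tilted
    model = artifact_model
    rng = np.random.default_rng(
        np.random.SeedSequence([int(model.seed), 50_000 + int(round(angle_deg * 100))])
    )
    vox = tilted.voxels
    if not model.is_null:
        dx, dy, _ = tilted.spacing
        metal = vox > model.metal_threshold_hu
        for k in np.flatnonzero(np.any(metal, axis=(1, 2))):
            vox[k] = inject_streaks(vox[k], metal[k], model, rng, spacing=(dx, dy))
    if model.noise_sd_hu > 0:
        vox = vox + rng.normal(0.0, model.noise_sd_hu, size=vox.shape)
    np.clip(vox, HU_MIN, HU_MAX, out=vox)
    return tilted.with_voxels(vox)
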