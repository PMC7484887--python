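"""Metal-band detection and stereoscopic merge (step 2 of the algorithm).

Each untilted scan is swept axially from the superior-most slice until the
first voxel above the metal threshold (2000 HU by default) is found, and
again from the inferior-most slice, giving the first and last
metal-affected slices.  The reference slice is the centre of that band
(half-integers round toward the inferior, i.e. larger, index).  The final
artifact-reduced volume takes slices superior of the reference from the
superiorly tilted scan and the reference slice onward from the inferiorly
tilted scan; because the tilted slice planes through the metal run away
from the posterior region in opposite directions, both kept halves are free
of posterior streaks.
"""

from __future__ import annotations

import logging
import math
import time
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, MetalNotFoundError, ReferenceMismatchError, StereoCTError
from .tilt import TransformSpec, untilt
from .volume import Volume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeConfig:
    """Detection and merge parameters.

    ``metal_threshold_hu`` must sit above the soft-tissue/bone range so
    cortical bone (and teeth) never trigger detection; only metal does.
    ``reference_mismatch_tol`` is the largest tolerated difference (slices)
    between the reference slices derived from the two scans — small
    mismatches arise from interpolation at the band edges.
    """

    metal_threshold_hu: float = 2000.0
    reference_mismatch_tol: int = 2

    def __post_init__(self):
        if self.metal_threshold_hu <= 1600.0:
            raise StereoCTError(
                f"metal threshold must exceed the bone range (> 1600 HU), got {self.metal_threshold_hu}"
            )


@dataclass(frozen=True)
class SliceRange:
    """First/last metal-affected slice indices and the derived reference."""

    first: int
    last: int
    reference: int

    @classmethod
    def from_band(cls, first: int, last: int) -> "SliceRange":
        if not 0 <= first <= last:
            raise StereoCTError(f"invalid metal band [{first}, {last}]")
        return cls(first, last, _round_half_inferior((first + last) / 2.0))


def _round_half_inferior(x: float) -> int:
    """Round, with exact halves going to the larger (more inferior) index."""
    return int(math.floor(x + 0.5))


def find_metal_slice_range(volume: Volume, config: MergeConfig = MergeConfig()) -> SliceRange:
    """Locate the metal-affected slice band of an untilted volume.

    Raises :class:`MetalNotFoundError` when no voxel exceeds the threshold.
    """
    if volume.tilt_angle_deg != 0.0:
        raise StereoCTError("metal detection runs on untilted volumes (tilt 0)")
    slice_has_metal = np.any(volume.voxels > config.metal_threshold_hu, axis=(1, 2))
    hits = np.flatnonzero(slice_has_metal)
    if hits.size == 0:
        raise MetalNotFoundError(
            f"no voxel above {config.metal_threshold_hu} HU in any slice"
        )
    return SliceRange.from_band(int(hits[0]), int(hits[-1]))


def common_reference(
    range_superior: SliceRange,
    range_inferior: SliceRange,
    config: MergeConfig = MergeConfig(),
) -> int:
    """Combine the two per-scan reference slices into the merge boundary.

    The two references may differ by interpolation effects at the band
    edges; up to ``reference_mismatch_tol`` slices of disagreement are
    averaged (half rounding inferior), anything larger is an error.
    """
    r_sup, r_inf = range_superior.reference, range_inferior.reference
    if abs(r_sup - r_inf) > config.reference_mismatch_tol:
        raise ReferenceMismatchError(r_sup, r_inf, config.reference_mismatch_tol)
    return _round_half_inferior((r_sup + r_inf) / 2.0)


def merge_volumes(
    superior_untilted: Volume,
    inferior_untilted: Volume,
    config: MergeConfig = MergeConfig(),
    reference: int | None = None,
) -> tuple[Volume, dict]:
    """Merge two untilted scans at the common reference slice.

    Output slice ``k`` is the superior scan's slice for ``k < reference``
    and the inferior scan's slice for ``k >= reference``; the slice count is
    conserved.  Returns the merged volume and a report dict with the
    detected bands and reference slices.
    """
    if not superior_untilted.same_grid(inferior_untilted):
        raise GridMismatchError(
            f"scan grids differ: {superior_untilted.shape}/{superior_untilted.spacing} vs "
            f"{inferior_untilted.shape}/{inferior_untilted.spacing}"
        )
    if superior_untilted.tilt_angle_deg != 0.0 or inferior_untilted.tilt_angle_deg != 0.0:
        raise StereoCTError("merge inputs must be untilted (tilt 0)")
    report: dict = {}
    if reference is None:
        range_sup = find_metal_slice_range(superior_untilted, config)
        range_inf = find_metal_slice_range(inferior_untilted, config)
        reference = common_reference(range_sup, range_inf, config)
        report["band_superior"] = [range_sup.first, range_sup.last]
        report["band_inferior"] = [range_inf.first, range_inf.last]
        report["reference_superior"] = range_sup.reference
        report["reference_inferior"] = range_inf.reference
    reference = int(reference)
    if not 0 <= reference <= superior_untilted.n_slices:
        raise StereoCTError(f"reference slice {reference} outside volume")
    report["reference"] = reference
    merged = np.concatenate(
        [superior_untilted.voxels[:reference], inferior_untilted.voxels[reference:]], axis=0
    )
    return superior_untilted.with_voxels(merged).with_tilt(0.0), report


def reduce_artifacts(
    superior_scan: Volume,
    inferior_scan: Volume,
    config: MergeConfig = MergeConfig(),
    transform_spec: TransformSpec = TransformSpec(),
) -> tuple[Volume, dict]:
    """Full pipeline: untilt both scans, detect the metal band, merge.

    ``superior_scan`` must carry a positive tilt angle and ``inferior_scan``
    a negative one.  When neither scan contains metal the untilted superior
    scan is returned unchanged with a warning (the tool degrades to plain
    untilting).  Returns the corrected volume (tilt metadata 0) and a run
    report.
    """
    t0 = time.perf_counter()
    if superior_scan.tilt_angle_deg <= 0:
        raise StereoCTError(
            f"superior scan must have positive tilt, got {superior_scan.tilt_angle_deg}°"
        )
    if inferior_scan.tilt_angle_deg >= 0:
        raise StereoCTError(
            f"inferior scan must have negative tilt, got {inferior_scan.tilt_angle_deg}°"
        )
    sup = untilt(superior_scan, transform_spec)
    inf = untilt(inferior_scan, transform_spec)
    report: dict = {
        "tilt_superior_deg": superior_scan.tilt_angle_deg,
        "tilt_inferior_deg": inferior_scan.tilt_angle_deg,
    }
    range_sup = range_inf = None
    try:
        range_sup = find_metal_slice_range(sup, config)
    except MetalNotFoundError:
        pass
    try:
        range_inf = find_metal_slice_range(inf, config)
    except MetalNotFoundError:
        pass
    if range_sup is None and range_inf is None:
        warnings.warn(
            "no metal found in either scan; returning the untilted superior scan",
            stacklevel=2,
        )
        report["reference"] = None
        merged = sup
    else:
        if range_sup is not None and range_inf is not None:
            reference = common_reference(range_sup, range_inf, config)
        else:
            only = range_sup if range_sup is not None else range_inf
            warnings.warn(
                "metal found in only one scan; merging at its reference slice",
                stacklevel=2,
            )
            reference = only.reference
        for name, rng in (("superior", range_sup), ("inferior", range_inf)):
            if rng is not None:
                report[f"band_{name}"] = [rng.first, rng.last]
                report[f"reference_{name}"] = rng.reference
        merged, merge_report = merge_volumes(sup, inf, config, reference=reference)
        report.update(merge_report)
    report["runtime_s"] = time.perf_counter() - t0
    log.info("artifact reduction done in %.2f s (reference=%s)", report["runtime_s"], report["reference"])
    return merged, report
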