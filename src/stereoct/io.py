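"""Reading and writing CT volumes: DICOM series and NIfTI (+ tilt sidecar).

DICOM slices are sorted by patient z position (superior first) regardless
of file naming; pixel values are converted to HU through the series'
rescale slope/intercept; the gantry tilt is taken from GantryDetectorTilt
(0018,1120), defaulting to 0 when absent.  Tilted stacks are stored as
ordinary arrays whose slice step is the couch-axis increment, with the
angle kept as metadata.

NIfTI files carry voxels, spacing and origin; the tilt angle lives in a
JSON sidecar next to the image (``<name>.json``).  A missing sidecar reads
as tilt 0 with a warning.

Internal ↔ DICOM axis mapping: internal x = DICOM +x (patient left),
internal y = DICOM +y (posterior), internal z grows inferiorly while DICOM
patient z grows superiorly, so slice files are written at descending
ImagePositionPatient z.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import (
    DicomReadError,
    DicomWriteError,
    MissingRescaleError,
    MixedSeriesError,
    NonUniformSliceStepError,
)
from .volume import HU_MAX, HU_MIN, ScanMetadata, Volume

log = logging.getLogger(__name__)

GANTRY_TILT_TAG = "GantryDetectorTilt"  # (0018,1120)
SLICE_STEP_TOL_MM = 1e-3


def read_dicom_series(directory) -> tuple[Volume, ScanMetadata]:
    """Load one CT series from a directory of slice files.

    Slices are ordered superior → inferior by ImagePositionPatient, pixel
    values are rescaled to HU, and the tilt angle is read from the gantry
    tilt attribute.  Mixed series, missing rescale attributes and
    non-uniform slice steps raise distinct errors.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix != ".json")
    datasets = []
    for path in files:
        try:
            datasets.append(pydicom.dcmread(str(path)))
        except pydicom.errors.InvalidDicomError:
            continue
    if not datasets:
        raise DicomReadError(f"no DICOM files found in {directory}")
    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series_uids) != 1:
        raise MixedSeriesError(f"directory {directory} holds {len(series_uids)} series")
    for ds in datasets:
        if not hasattr(ds, "RescaleSlope") or not hasattr(ds, "RescaleIntercept"):
            raise MissingRescaleError("slice lacks RescaleSlope/RescaleIntercept")
    # superior-most first: descending DICOM patient z
    datasets.sort(key=lambda ds: -float(ds.ImagePositionPatient[2]))
    zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(datasets) > 1:
        steps = -np.diff(zpos)
        if np.any(steps <= 0):
            raise DicomReadError("duplicate or non-monotone slice positions")
        if steps.max() - steps.min() > SLICE_STEP_TOL_MM:
            raise NonUniformSliceStepError(
                f"slice step varies from {steps.min():.4f} to {steps.max():.4f} mm"
            )
        dz = float(steps.mean())
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)
    first = datasets[0]
    py, px = (float(v) for v in first.PixelSpacing)  # (row=y, col=x) spacing
    shapes = {ds.pixel_array.shape for ds in datasets}
    if len(shapes) != 1:
        raise DicomReadError("in-plane shapes differ between slices")
    hu = np.stack(
        [
            ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
            for ds in datasets
        ]
    )
    np.clip(hu, HU_MIN, HU_MAX, out=hu)
    tilt = float(getattr(first, GANTRY_TILT_TAG, 0.0) or 0.0)
    ipp = first.ImagePositionPatient
    origin = (float(ipp[0]), float(ipp[1]), -float(ipp[2]))  # internal z grows inferiorly
    volume = Volume(hu, spacing=(px, py, dz), origin=origin, tilt_angle_deg=tilt)
    meta = ScanMetadata(
        kvp=float(first.KVP) if getattr(first, "KVP", None) is not None else None,
        mas=float(getattr(first, "Exposure", 0) or 0) or None,
        slice_thickness_mm=float(getattr(first, "SliceThickness", 0) or 0) or None,
        recon_kernel=str(getattr(first, "ConvolutionKernel", "")) or None,
        tube_rotation_s=None,
        tilt_tag_value=tilt,
    )
    return volume, meta


def write_dicom_series(
    volume: Volume,
    directory,
    metadata: ScanMetadata | None = None,
    rescale_intercept: float = -1024.0,
) -> list[Path]:
    """Write one file per slice as a CT series with HU stored losslessly.

    Stored values use slope 1 / intercept ``rescale_intercept``; HU that
    are not integer-representable under that rescale raise
    :class:`DicomWriteError` (round the volume first if it has been
    interpolated).  The gantry tilt attribute of every slice equals the
    volume's ``tilt_angle_deg`` — in particular, a corrected volume writes
    tilt 0 so downstream software displays it as a plain axial stack.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stored = volume.voxels - rescale_intercept
    rounded = np.round(stored)
    if not np.allclose(stored, rounded, atol=1e-6):
        raise DicomWriteError(
            "HU values are not integer-representable under the chosen rescale; "
            "round the volume before writing DICOM"
        )
    if rounded.min() < 0 or rounded.max() > 65535:
        raise DicomWriteError("stored values exceed the unsigned 16-bit range")
    stored_int = rounded.astype(np.uint16)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    dx, dy, dz = volume.spacing
    x0, y0, z0 = volume.origin
    paths = []
    for k in range(volume.n_slices):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        # internal z grows inferiorly; DICOM patient z grows superiorly
        ds.ImagePositionPatient = [x0, y0, -(z0 + k * dz)]
        ds.SliceThickness = dz
        ds.PixelSpacing = [dy, dx]  # (row, col)
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = rescale_intercept
        setattr(ds, GANTRY_TILT_TAG, volume.tilt_angle_deg)
        if metadata is not None:
            if metadata.kvp is not None:
                ds.KVP = metadata.kvp
            if metadata.recon_kernel is not None:
                ds.ConvolutionKernel = metadata.recon_kernel
        ds.PixelData = stored_int[k].tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


# --------------------------------------------------------------------------
# NIfTI + sidecar
# --------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: Volume, path) -> Path:
    """Write a volume to NIfTI with the tilt angle in a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(np.transpose(volume.voxels, (2, 1, 0)))  # (x, y, z)
    affine = np.diag([*volume.spacing, 1.0]).astype(float)
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"tilt_angle_deg": volume.tilt_angle_deg}, indent=1))
    return path


def read_volume(path) -> Volume:
    """Read a NIfTI volume written by :func:`write_volume`.

    A missing sidecar is tolerated: the tilt is assumed 0 and a warning is
    logged.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    affine = img.affine
    spacing = tuple(float(abs(affine[i, i])) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        tilt = float(json.loads(sidecar.read_text()).get("tilt_angle_deg", 0.0))
    else:
        warnings.warn(f"no tilt sidecar next to {path.name}; assuming tilt 0", stacklevel=2)
        log.warning("no tilt sidecar next to %s; assuming tilt 0", path)
        tilt = 0.0
    vox = np.transpose(data, (2, 1, 0)).astype(float)  # back to (z, y, x)
    return Volume(vox, spacing=spacing, origin=origin, tilt_angle_deg=tilt)


def load_any(path) -> Volume:
    """Load a volume from a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)[0]
    return read_volume(path)
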