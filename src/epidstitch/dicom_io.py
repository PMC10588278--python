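"""DICOM RT Image reading and writing for portal-dose fluence maps.

Reading uses only the geometry facts the stitching procedure needs: pixel
data, the pixel spacing at the image plane (3002,0011), the source-to-image
distance (3002,0026), and the rescale slope/intercept that map stored
integers to calibration units.  Writing stores composites as 32-bit unsigned
integers with a decimal-exact rescale slope so the read-back error is at
most half a quantization step — negligible against a 3 % dose tolerance.
"""
from __future__ import annotations

import hashlib
import logging
import warnings

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .fluence import FluenceMap, ROWS_SUP_INF
from .stitching import CompositeFluence

log = logging.getLogger(__name__)

RT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.1"
_U32_MAX = 2 ** 32 - 1

# deterministic UID root (derived from content hashes, not wall clock)
_UID_PREFIX = "2.25."


class DicomTagError(ValueError):
    """A required DICOM tag is missing or unusable."""


def read_portal_dose(
    path,
    isocenter_index: int = 0,
    source_kind: str = "measured",
    field_label: str | None = None,
) -> FluenceMap:
    """Read one portal-dose fluence map from a DICOM RT Image file.

    Stored values are rescaled to calibration units via
    ``pixels = stored * RescaleSlope + RescaleIntercept`` (slope/intercept
    default 1/0 when absent).  Negative rescaled pixels are clipped to zero;
    the clip count is kept on the returned map and raised as a warning.
    """
    ds = pydicom.dcmread(path)
    modality = getattr(ds, "Modality", None)
    if modality != "RTIMAGE":
        raise DicomTagError(
            f"{path}: expected Modality RTIMAGE, got {modality!r}"
        )
    if "PixelData" not in ds:
        raise DicomTagError(f"{path}: missing PixelData (7FE0,0010)")
    if "ImagePlanePixelSpacing" not in ds:
        raise DicomTagError(
            f"{path}: missing ImagePlanePixelSpacing (3002,0011)"
        )
    if "RTImageSID" not in ds:
        raise DicomTagError(f"{path}: missing RTImageSID (3002,0026)")

    spacing = [float(v) for v in ds.ImagePlanePixelSpacing]
    sid = float(ds.RTImageSID)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = ds.pixel_array.astype(np.float64) * slope + intercept
    if not np.all(np.isfinite(arr)):
        raise DicomTagError(f"{path}: non-finite pixel values after rescale")

    neg = int(np.sum(arr < 0))
    if neg:
        warnings.warn(
            f"{path}: clipped {neg} negative pixels to 0 CU", stacklevel=2
        )
        arr = np.clip(arr, 0.0, None)

    # rows run superior->inferior unless orientation metadata says otherwise;
    # no orientation tag in portal-dose exports we target, so default applies
    axis_convention = ROWS_SUP_INF

    label = field_label
    if label is None:
        label = str(getattr(ds, "RTImageLabel", "")) or str(path)

    return FluenceMap(
        pixels=arr,
        row_spacing_mm=spacing[0],
        col_spacing_mm=spacing[1],
        plane_distance_mm=sid,
        source_kind=source_kind,
        field_label=label,
        isocenter_index=isocenter_index,
        axis_convention=axis_convention,
        clipped_negative_count=neg,
    )


def _decimal_slope(max_cu: float) -> tuple[float, str]:
    """Rescale slope as a 10-significant-digit decimal (fits DICOM DS).

    Returned as both the float and the exact string written to the file, so
    read-back multiplies by the identical value.
    """
    exact = max_cu / _U32_MAX if max_cu > 0 else 1.0
    s = f"{exact:.9e}"
    slope = float(s)
    if max_cu > 0 and max_cu / slope > _U32_MAX:
        s = f"{exact * (1 + 1e-8):.9e}"
        slope = float(s)
    return slope, s


def _write_fluence(
    pixels: np.ndarray,
    row_spacing_mm: float,
    col_spacing_mm: float,
    plane_distance_mm: float,
    path,
    label: str = "",
) -> str:
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.size == 0:
        raise ValueError("cannot write an empty fluence grid")
    slope, slope_str = _decimal_slope(float(pixels.max()))
    stored = np.clip(np.rint(pixels / slope), 0, _U32_MAX).astype(np.uint32)

    content = hashlib.sha256(
        stored.tobytes()
        + np.array([row_spacing_mm, col_spacing_mm, plane_distance_mm]).tobytes()
        + label.encode()
    ).hexdigest()
    sop_uid = generate_uid(prefix=_UID_PREFIX, entropy_srcs=[content, "sop"])

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RT_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RT_IMAGE_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTIMAGE"
    ds.PatientName = "QA^PHANTOM"
    ds.PatientID = "EPIDSTITCH"
    ds.StudyInstanceUID = generate_uid(prefix=_UID_PREFIX,
                                       entropy_srcs=[content, "study"])
    ds.SeriesInstanceUID = generate_uid(prefix=_UID_PREFIX,
                                        entropy_srcs=[content, "series"])
    ds.RTImageLabel = (label[:16] if label else "COMPOSITE")  # SH VR: 16 max
    ds.Rows, ds.Columns = stored.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.ImagePlanePixelSpacing = [f"{row_spacing_mm:.10g}",
                                 f"{col_spacing_mm:.10g}"]
    ds.RTImageSID = f"{plane_distance_mm:.10g}"
    ds.RadiationMachineSAD = "1000"
    ds.RescaleSlope = slope_str
    ds.RescaleIntercept = "0"
    ds.PixelData = stored.tobytes()

    try:
        ds.save_as(path, enforce_file_format=True)
    except OSError as exc:
        raise OSError(f"cannot write DICOM to {path}: {exc}") from exc
    log.info("wrote %s (%dx%d, slope %s)", path, ds.Rows, ds.Columns, slope_str)
    return str(path)


def write_composite(composite: CompositeFluence, path) -> str:
    """Export a stitched composite as a single DICOM RT Image file."""
    return _write_fluence(
        composite.pixels,
        composite.row_spacing_mm,
        composite.col_spacing_mm,
        composite.plane_distance_mm,
        path,
        label=f"COMPOSITE_{composite.source_kind.upper()}",
    )


def write_field(fmap: FluenceMap, path) -> str:
    """Write a single per-field fluence map (used by the simulator)."""
    return _write_fluence(
        fmap.pixels,
        fmap.row_spacing_mm,
        fmap.col_spacing_mm,
        fmap.plane_distance_mm,
        path,
        label=fmap.field_label,
    )


def write_gamma_map(gamma: np.ndarray, row_spacing_mm: float,
                    col_spacing_mm: float, plane_distance_mm: float,
                    path) -> str:
    """Store a gamma map in the same RT Image dialect (gamma x 1000).

    NaN (below-threshold) pixels are stored as 0.
    """
    g = np.nan_to_num(np.asarray(gamma, dtype=np.float64), nan=0.0)
    return _write_fluence(g * 1000.0, row_spacing_mm, col_spacing_mm,
                          plane_distance_mm, path, label="GAMMA_X1000")
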