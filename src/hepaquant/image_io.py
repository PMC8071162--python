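"""Reading MR slices and masks; writing contours, maps and score tables.

DICOM handling covers the single-frame little-endian files the
quantification workflow consumes: the rescale transform
``slope * stored + intercept`` is applied on read and intensities are
kept as floating point afterwards (no windowing — the CV-based scores
are scale-invariant but windowing could clip). When the pixel-spacing
attribute is missing, the acquisition default of 0.74 mm isotropic
in-plane spacing is assumed with a logged warning.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .contour import Contour
from .errors import FormatError
from .image import BinaryMask, Image2D

logger = logging.getLogger(__name__)

DEFAULT_SPACING_MM = (0.74, 0.74)


def read_dicom(path: str | Path) -> Image2D:
    """Read a single-frame DICOM slice into an :class:`Image2D`.

    Raises
    ------
    FormatError
        Missing pixel data, or multi-frame input (unsupported).
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several types
        raise FormatError(f"cannot read DICOM file {path}: {exc}") from exc
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise FormatError(f"{path}: multi-frame DICOM is unsupported")
    if "PixelData" not in ds:
        raise FormatError(f"{path}: DICOM file has no pixel data")
    pixels = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = slope * pixels + intercept
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        logger.warning(
            "%s: no PixelSpacing attribute; assuming %.2f mm isotropic in-plane spacing",
            path,
            DEFAULT_SPACING_MM[0],
        )
        spacing_mm = DEFAULT_SPACING_MM
    else:
        spacing_mm = (float(spacing[0]), float(spacing[1]))
    meta = {
        "path": str(path),
        "patient_id": str(getattr(ds, "PatientID", "")),
        "description": str(getattr(ds, "SeriesDescription", "")),
    }
    return Image2D(pixels=pixels, spacing_mm=spacing_mm, meta=meta)


def write_dicom(image: Image2D, path: str | Path) -> None:
    """Write an image as a single-frame secondary-capture DICOM.

    Pixels are stored as unsigned 16-bit with identity rescale, so the
    round trip is bit-exact for integer-valued images in [0, 65535];
    fractional intensities are rounded (a warning is logged).
    """
    path = Path(path)
    pixels = image.pixels
    if np.any(np.abs(pixels - np.round(pixels)) > 1e-9):
        logger.warning("%s: non-integer intensities rounded for uint16 DICOM storage", path)
    stored = np.round(pixels)
    if stored.max() > 65535:
        raise FormatError("intensities exceed uint16 range; rescale before writing DICOM")
    stored = stored.astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.PatientID = str(image.meta.get("patient_id", "PHANTOM"))
    ds.SeriesDescription = str(image.meta.get("description", "hepaquant"))
    ds.Rows, ds.Columns = stored.shape
    ds.PixelSpacing = [f"{image.spacing_mm[0]:.6g}", f"{image.spacing_mm[1]:.6g}"]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "0"
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_grayscale(
    path: str | Path, spacing_mm: tuple[float, float] = DEFAULT_SPACING_MM
) -> Image2D:
    """Read a PNG or CSV grayscale image (no intensity transform applied)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        try:
            pixels = np.loadtxt(path, delimiter=",", dtype=np.float64)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed (non-rectangular?) CSV image: {exc}") from exc
        if pixels.ndim != 2:
            raise FormatError(f"{path}: CSV image must be 2-D, got shape {pixels.shape}")
    else:
        import imageio.v3 as iio

        try:
            pixels = np.asarray(iio.imread(path), dtype=np.float64)
        except Exception as exc:
            raise FormatError(f"cannot read image {path}: {exc}") from exc
        if pixels.ndim == 3:  # collapse identical RGB channels
            pixels = pixels.mean(axis=2)
    return Image2D(pixels=pixels, spacing_mm=spacing_mm, meta={"path": str(path)})


def write_png16(image_or_array, path: str | Path) -> None:
    """Write an array (or Image2D) as 16-bit PNG, rounding intensities."""
    import imageio.v3 as iio

    arr = image_or_array.pixels if isinstance(image_or_array, Image2D) else image_or_array
    arr = np.round(np.asarray(arr)).clip(0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), arr)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask from PNG or CSV (nonzero = inside)."""
    img = read_grayscale(path)
    return BinaryMask(img.pixels > 0)


def write_contour_csv(contour: Contour, path: str | Path) -> None:
    """Write contour vertices as ``index,row,col`` (0-based pixel coords)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "row", "col"])
        for i, (r, c) in enumerate(contour.points):
            writer.writerow([i, f"{r:.9g}", f"{c:.9g}"])


def read_contour_csv(
    path: str | Path,
    spacing_mm: tuple[float, float] = DEFAULT_SPACING_MM,
    closed: bool = True,
) -> Contour:
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed contour CSV: {exc}") from exc
    if data.shape[1] != 3:
        raise FormatError(f"{path}: contour CSV must have 3 columns, got {data.shape[1]}")
    return Contour(points=data[:, 1:3], closed=closed, spacing_mm=spacing_mm)


def write_scores_json(scores, path: str | Path) -> None:
    """Serialise a SubjectScores (or any dataclass-like) to JSON."""
    from dataclasses import asdict, is_dataclass

    path = Path(path)
    obj = asdict(scores) if is_dataclass(scores) else dict(scores)
    with path.open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_scores_json(path: str | Path):
    from .scoring import SubjectScores

    path = Path(path)
    try:
        with path.open() as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed scores JSON: {exc}") from exc
    return SubjectScores(**obj)
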