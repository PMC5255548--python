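"""Reading parametric maps and writing fused color images.

Supported inputs: NIfTI volumes, DICOM files or series directories
(position-sorted, rescale slope/intercept applied via SimpleITK's GDCM
reader) and single-slice grayscale PNGs (unit spacing assumed). Fused
images can be written as 8-bit PNG (with provenance in a text chunk and a
JSON sidecar), DICOM secondary capture (RGB) or NIfTI RGB vector volumes.
"""

from __future__ import annotations

import datetime
import json
import warnings
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
from PIL import Image
from PIL.PngImagePlugin import PngInfo
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .fusion import FusedImage
from .preprocess import ParametricMap

__all__ = ["read_image", "write_fused", "write_parametric_map"]


class ImageIOError(IOError):
    pass


_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if any(name.endswith(s) for s in _NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(".png"):
        return "png"
    if path.is_dir() or name.endswith(".dcm"):
        return "dicom"
    raise ImageIOError(f"cannot infer image format of {path}")


def _read_dicom(path: Path, channel_name: str) -> ParametricMap:
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        series_ids = reader.GetGDCMSeriesIDs(str(path))
        if not series_ids:
            raise ImageIOError(f"no DICOM series found under {path}")
        if len(series_ids) > 1:
            raise ImageIOError(f"ambiguous: {len(series_ids)} DICOM series under {path}")
        # GDCM sorts files by image position along the normal and applies
        # RescaleSlope/Intercept
        reader.SetFileNames(reader.GetGDCMSeriesFileNames(str(path), series_ids[0]))
        img = reader.Execute()
        if img.GetSize()[-1] == 1:
            img = img[:, :, 0]
    else:
        img = sitk.ReadImage(str(path))
        if img.GetDimension() == 3 and img.GetSize()[-1] == 1:
            img = img[:, :, 0]
    return ParametricMap.from_sitk(img, channel_name=channel_name)


def read_image(path, fmt: str | None = None, channel_name: str = "") -> ParametricMap:
    """Read one parametric map from NIfTI, DICOM (file or series dir) or PNG."""
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file or directory: {path}")
    fmt = fmt or _infer_format(path)
    if fmt == "nifti":
        img = sitk.ReadImage(str(path))
        if img.GetNumberOfComponentsPerPixel() > 1:
            warnings.warn(f"{path.name} is multi-component; averaging to one channel")
            arr = sitk.GetArrayFromImage(img).astype(float).mean(axis=-1)
            scalar = sitk.GetImageFromArray(arr)
            scalar.CopyInformation(sitk.VectorIndexSelectionCast(img, 0, sitk.sitkFloat64))
            img = scalar
        return ParametricMap.from_sitk(img, channel_name=channel_name)
    if fmt == "dicom":
        return _read_dicom(path, channel_name)
    if fmt == "png":
        arr = np.asarray(Image.open(path).convert("F"), dtype=float)
        warnings.warn(f"PNG {path.name} carries no geometry; assuming unit spacing")
        return ParametricMap(arr, channel_name=channel_name)
    raise ImageIOError(f"unknown format {fmt!r}")


def write_parametric_map(m: ParametricMap, path) -> None:
    """Write a single channel as NIfTI."""
    sitk.WriteImage(m.to_sitk(), str(Path(path)))


def _provenance_json(f: FusedImage) -> str:
    return json.dumps(f.provenance, sort_keys=True)


def _write_png(f: FusedImage, path: Path) -> None:
    if f.rgb.ndim != 3:
        raise ImageIOError("PNG export requires a single 2-D slice")
    img = Image.fromarray(f.rgb8(), mode="RGB")
    meta = PngInfo()
    meta.add_text("provenance", _provenance_json(f))
    img.save(path, pnginfo=meta)
    Path(str(path) + ".json").write_text(_provenance_json(f) + "\n")


def _write_dicom_sc(f: FusedImage, path: Path) -> None:
    rgb8 = f.rgb8()
    if rgb8.ndim != 3:
        raise ImageIOError("DICOM secondary capture export requires a single 2-D slice")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.Modality = "OT"
    ds.ConversionType = "WSD"
    now = datetime.datetime.now()
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    ds.Rows, ds.Columns = rgb8.shape[:2]
    ds.SamplesPerPixel = 3
    ds.PhotometricInterpretation = "RGB"
    ds.PlanarConfiguration = 0
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [f.spacing[1], f.spacing[0]]
    ds.ImageComments = _provenance_json(f)[:1024]
    ds.PixelData = rgb8.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def _write_nifti_rgb(f: FusedImage, path: Path) -> None:
    img = sitk.GetImageFromArray(f.rgb8(), isVector=True)
    nd = f.rgb8().ndim - 1
    img.SetSpacing(f.spacing[:nd] if len(f.spacing) >= nd else (1.0,) * nd)
    img.SetOrigin(f.origin[:nd] if len(f.origin) >= nd else (0.0,) * nd)
    sitk.WriteImage(img, str(path))
    Path(str(path) + ".json").write_text(_provenance_json(f) + "\n")


_WRITERS = {
    "png": _write_png,
    "dicom_secondary_capture": _write_dicom_sc,
    "nifti_rgb": _write_nifti_rgb,
}


def write_fused(f: FusedImage, path, fmt: str = "png") -> None:
    """Write a fused color image as 8-bit RGB with embedded provenance."""
    if fmt not in _WRITERS:
        raise ImageIOError(f"unknown output format {fmt!r}; known: {tuple(_WRITERS)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        _WRITERS[fmt](f, path)
    except OSError as exc:
        raise ImageIOError(f"cannot write {path}: {exc}") from exc
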