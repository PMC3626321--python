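"""Reading CT series and writing masks, overlays and tables.

Two on-disk series layouts are supported: a directory of plain array
files (``.npy`` or whitespace-delimited ``.txt``, one file per slice,
lexicographic order = slice order) and a DICOM series (one file per
slice; HU recovered via rescale slope/intercept).  DICOM support needs
the optional ``pydicom`` dependency.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from .segmentation import VesselTrack
from .types import CTSlice

__all__ = [
    "read_series",
    "write_series",
    "write_mask_png",
    "write_overlay_png",
    "write_objects_csv",
]

log = logging.getLogger(__name__)

try:  # pydicom is optional; plain-array series need nothing extra
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    HAVE_PYDICOM = True
except ImportError:  # pragma: no cover - depends on environment
    HAVE_PYDICOM = False

#: Display window (HU) used when rendering slices to 8-bit PNGs.
DEFAULT_WINDOW = (-160.0, 640.0)


def read_series(path) -> list[CTSlice]:
    """Load a slice series from a directory of array or DICOM files."""
    path = Path(path)
    if not path.is_dir():
        raise IOError(f"not a readable series directory: {path}")
    dcm = sorted(path.glob("*.dcm"))
    if dcm:
        return _read_dicom_series(dcm)
    files = sorted(list(path.glob("*.npy")) + list(path.glob("*.txt")))
    if not files:
        raise IOError(f"no .npy/.txt/.dcm slice files found in {path}")
    slices = []
    for idx, f in enumerate(files):
        try:
            arr = np.load(f) if f.suffix == ".npy" else np.loadtxt(f)
        except Exception as exc:
            raise IOError(f"unreadable slice file {f}: {exc}") from exc
        slices.append(CTSlice(np.asarray(arr, dtype=np.int32), idx))
    return slices


def _read_dicom_series(files: Sequence[Path]) -> list[CTSlice]:
    if not HAVE_PYDICOM:
        raise ImportError("reading DICOM series requires the optional 'pydicom' package")
    loaded = []
    for f in files:
        ds = pydicom.dcmread(f)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(float) * slope + intercept
        spacing = getattr(ds, "PixelSpacing", None)
        spacing = (float(spacing[0]), float(spacing[1])) if spacing is not None else None
        loaded.append((int(getattr(ds, "InstanceNumber", len(loaded) + 1)), hu, spacing))
    loaded.sort(key=lambda t: t[0])
    return [
        CTSlice(np.rint(hu).astype(np.int32), idx, spacing)
        for idx, (_, hu, spacing) in enumerate(loaded)
    ]


def write_series(slices: Sequence[CTSlice], out_dir, fmt: str = "npy") -> list[Path]:
    """Write a series as one file per slice; formats: npy, txt, dicom."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ct in slices:
        if fmt == "npy":
            p = out_dir / f"slice_{ct.slice_index:04d}.npy"
            np.save(p, ct.pixels)
        elif fmt == "txt":
            p = out_dir / f"slice_{ct.slice_index:04d}.txt"
            np.savetxt(p, ct.pixels, fmt="%d")
        elif fmt == "dicom":
            p = out_dir / f"slice_{ct.slice_index:04d}.dcm"
            _write_dicom(ct, p)
        else:
            raise ValueError(f"unknown series format {fmt!r}")
        paths.append(p)
    return paths


def _write_dicom(ct: CTSlice, path: Path) -> None:
    if not HAVE_PYDICOM:
        raise ImportError("writing DICOM requires the optional 'pydicom' package")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = ct.shape
    ds.InstanceNumber = ct.slice_index + 1
    spacing = ct.pixel_spacing_mm or (1.0, 1.0)
    ds.PixelSpacing = [str(spacing[0]), str(spacing[1])]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "0"
    ds.PixelData = ct.pixels.astype(np.int16).tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground = 255)."""
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)


def write_overlay_png(
    ct: CTSlice,
    highlight: np.ndarray,
    path,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> None:
    """Render the slice windowed to 8-bit grey with highlighted pixels in red."""
    lo, hi = window
    grey = np.clip((ct.pixels.astype(float) - lo) / (hi - lo), 0.0, 1.0)
    grey8 = (grey * 255).astype(np.uint8)
    rgb = np.stack([grey8, grey8, grey8], axis=-1)
    rgb[highlight] = (255, 0, 0)
    Image.fromarray(rgb, mode="RGB").save(path)


def write_objects_csv(tracks: Sequence[VesselTrack], path) -> None:
    """Object table: slice_index, label, n_pixels, centroid_row, centroid_col."""
    import pandas as pd

    rows = []
    for track in tracks:
        for idx in sorted(track.objects):
            obj = track.objects[idx]
            rows.append({
                "slice_index": idx,
                "label": obj.anatomy_label,
                "n_pixels": obj.n_pixels,
                "centroid_row": obj.centroid[0],
                "centroid_col": obj.centroid[1],
            })
        for idx in track.gaps:
            rows.append({
                "slice_index": idx,
                "label": f"{track.anatomy_label}_gap",
                "n_pixels": 0,
                "centroid_row": float("nan"),
                "centroid_col": float("nan"),
            })
    pd.DataFrame(rows).sort_values(["slice_index", "label"]).to_csv(path, index=False)
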