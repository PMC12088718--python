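"""Core slice container and on-disk interchange.

A CMR slice is a 2-D grid of CT attenuation values in Hounsfield units (HU,
water = 0, air ≈ −1000).  On disk slices travel either as DICOM (rescale
slope/intercept applied on read) or as lossless 16-bit PNG with a JSON
sidecar recording the affine HU mapping ``hu = slope * stored + offset``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

HU_MIN, HU_MAX = -1024.0, 3000.0

#: default sidecar mapping: stored uint16 0 corresponds to −1024 HU
DEFAULT_HU_OFFSET = -1024.0
DEFAULT_HU_SLOPE = 1.0


@dataclass
class HUSlice:
    """One CMR slice as a 2-D attenuation grid in Hounsfield units."""

    patient_id: str
    slice_index: int
    pixels: np.ndarray  # float32, shape (H, W), HU

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError(f"slice pixels must be 2-D, got shape {self.pixels.shape}")

    @property
    def slice_id(self) -> str:
        return f"{self.patient_id}:{self.slice_index:04d}"


def write_png16(hu_slice: HUSlice, path: str | Path) -> Path:
    """Write a slice as 16-bit PNG plus a ``<name>.json`` HU sidecar."""
    path = Path(path)
    stored = np.clip((hu_slice.pixels - DEFAULT_HU_OFFSET) / DEFAULT_HU_SLOPE, 0, 65535)
    Image.fromarray(np.round(stored).astype(np.uint16)).save(path)
    sidecar = {
        "hu_offset": DEFAULT_HU_OFFSET,
        "hu_slope": DEFAULT_HU_SLOPE,
        "patient_id": hu_slice.patient_id,
        "slice_index": hu_slice.slice_index,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def read_png16(path: str | Path) -> HUSlice:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    stored = np.asarray(Image.open(path), dtype=np.float32)
    hu = stored * float(sidecar.get("hu_slope", DEFAULT_HU_SLOPE)) + float(
        sidecar.get("hu_offset", DEFAULT_HU_OFFSET)
    )
    return HUSlice(
        patient_id=str(sidecar.get("patient_id", path.stem.split("_")[0])),
        slice_index=int(sidecar.get("slice_index", 0)),
        pixels=hu,
    )


def read_dicom(path: str | Path, patient_id: str | None = None, slice_index: int = 0) -> HUSlice:
    """Read a DICOM slice, applying RescaleSlope/RescaleIntercept to HU."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = ds.pixel_array.astype(np.float32) * slope + intercept
    pid = patient_id if patient_id is not None else str(getattr(ds, "PatientID", Path(path).stem))
    idx = int(getattr(ds, "InstanceNumber", slice_index))
    return HUSlice(patient_id=pid, slice_index=idx, pixels=hu)


def read_slice(path: str | Path) -> HUSlice:
    """Dispatch on file suffix: ``.png`` (with sidecar) or ``.dcm``."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        return read_png16(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return read_dicom(path)
    raise ValueError(f"unsupported slice format: {path.suffix}")
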