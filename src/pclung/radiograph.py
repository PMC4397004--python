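"""Radiograph container and image/annotation I/O.

A :class:`Radiograph` is a 2-D nonnegative intensity matrix with a nominal
bit depth and optional annotations: a class label (``NL``, ``LC`` or
``PNEU``), named vertebral landmark positions and a rectangular region of
interest.  Images are read from DICOM (as produced by film digitisers) or
from PNG/TIFF; synthetic and processed images are written as TIFF with a
JSON sidecar carrying the annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CLASS_LABELS = ("NL", "LC", "PNEU")

#: landmark names used throughout: seventh cervical and first four thoracic
#: vertebrae, top to bottom along the spine.
LANDMARK_NAMES = ("C7", "T1", "T2", "T3", "T4")


@dataclass
class Radiograph:
    """A grayscale chest radiograph with optional annotations.

    Parameters
    ----------
    pixels
        2-D array of nonnegative intensities (stored as float64).
    bit_depth
        Nominal bit depth of the acquisition (12 for digitised film).
    label
        Diagnostic class, one of ``NL``/``LC``/``PNEU``, or None.
    landmarks
        Mapping from landmark name to ``(row, col)`` pixel position.
    roi_box
        Region of interest as ``(row0, col0, height, width)``.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    label: str | None = None
    landmarks: dict[str, tuple[int, int]] | None = None
    roi_box: tuple[int, int, int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("radiograph pixels must be a 2-D matrix")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("radiograph contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("radiograph intensities must be nonnegative")
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        """Largest representable intensity at the nominal bit depth."""
        return 2**self.bit_depth - 1

    def annotations(self) -> dict:
        """JSON-serialisable annotation record (label, landmarks, ROI)."""
        return {
            "label": self.label,
            "bit_depth": self.bit_depth,
            "landmarks": {k: list(map(int, v)) for k, v in (self.landmarks or {}).items()},
            "roi_box": list(map(int, self.roi_box)) if self.roi_box else None,
        }


def read_image(path: str | Path) -> Radiograph:
    """Read a radiograph from DICOM, TIFF or PNG.

    A JSON sidecar ``<stem>.json`` next to the image, if present, supplies
    label/landmark/ROI annotations.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        pixels = ds.pixel_array.astype(float)
        bit_depth = int(getattr(ds, "BitsStored", 12))
    elif suffix in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path).astype(float)
        bit_depth = 16 if pixels.max() > 4095 else 12
    elif suffix == ".png":
        from PIL import Image

        pixels = np.asarray(Image.open(path)).astype(float)
        bit_depth = 16 if pixels.max() > 4095 else 12
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")

    rad = Radiograph(pixels, bit_depth=bit_depth)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        ann = json.loads(sidecar.read_text())
        rad.label = ann.get("label")
        rad.bit_depth = int(ann.get("bit_depth", rad.bit_depth))
        rad.landmarks = {k: tuple(v) for k, v in (ann.get("landmarks") or {}).items()} or None
        rad.roi_box = tuple(ann.get("roi_box")) if ann.get("roi_box") else None
    return rad


def write_image(path: str | Path, rad: Radiograph, dtype: str = "uint16") -> Path:
    """Write a radiograph as TIFF (uint16 or float32) plus JSON sidecar."""
    import tifffile

    path = Path(path)
    if dtype == "uint16":
        data = np.clip(np.round(rad.pixels), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = rad.pixels.astype(np.float32)
    else:
        raise ValueError("dtype must be 'uint16' or 'float32'")
    tifffile.imwrite(path, data)
    path.with_suffix(".json").write_text(json.dumps(rad.annotations(), indent=1))
    return path


def write_map(path: str | Path, values: np.ndarray, params: dict | None = None) -> Path:
    """Write a real-valued response map as 32-bit TIFF with a JSON sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    if params is not None:
        path.with_suffix(".json").write_text(json.dumps(params, indent=1, default=float))
    return path
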