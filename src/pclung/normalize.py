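"""Histogram equalization and landmark-based intensity normalization.

Radiographs digitised from film differ in overall exposure, which would
confound any intensity-based texture comparison.  Spine landmarks (centres
of the first four thoracic vertebrae, T1-T4) are practically unaffected by
pulmonary infiltrates, so their intensities index each image's exposure.
Each image is divided by its *signature* -- the mean, over the four
landmarks, of the ratio between the image's landmark intensity and the
cohort mean at that landmark -- which removes the per-image multiplicative
exposure factor.  The cohort mean of the per-image signatures (the central
signature, CS) equals 1 by construction and is retained as a diagnostic.

C7 is also measured, as it is commonly annotated, but only T1-T4 enter the
signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import exposure


@dataclass(frozen=True)
class LandmarkIntensities:
    """Mean intensity over a small disk at each vertebral landmark."""

    c7: float
    t1: float
    t2: float
    t3: float
    t4: float

    def __post_init__(self):
        if min(self.c7, self.t1, self.t2, self.t3, self.t4) <= 0:
            raise ValueError("landmark intensities must be positive")

    @property
    def thoracic(self) -> np.ndarray:
        """T1-T4 as an array (the values entering the signature)."""
        return np.array([self.t1, self.t2, self.t3, self.t4])


@dataclass(frozen=True)
class CentralSignature:
    """Cohort landmark means and per-image signatures.

    ``t_bar`` holds the cohort means of T1-T4.  ``signatures[i]`` is image
    i's signature s_i = mean_j(T_ji / t_bar_j); ``cs`` is the cohort mean
    of the s_i (1 by construction, kept as a sanity value).
    """

    t_bar: np.ndarray
    signatures: np.ndarray
    cs: float

    def __post_init__(self):
        if not self.cs > 0:
            raise ValueError("central signature must be positive")


def equalize_histogram(image: np.ndarray, bit_depth: int = 12) -> np.ndarray:
    """Global histogram equalization onto the [0, 2**bit_depth - 1] range.

    The mapping is the cumulative histogram (monotone in intensity), with
    2**bit_depth bins.  A constant image has no defined mapping and is
    returned unchanged.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.max() == image.min():
        return image.copy()
    eq = exposure.equalize_hist(image, nbins=2**bit_depth)
    return eq * (2**bit_depth - 1)


def disk_mean(image: np.ndarray, center: tuple[int, int], radius: int) -> float:
    """Mean intensity over the disk of given radius centred at ``center``.

    ``radius`` 0 returns the exact pixel value.  The disk must fit inside
    the image.
    """
    image = np.asarray(image, dtype=float)
    r, c = center
    h, w = image.shape
    if not (radius <= r < h - radius and radius <= c < w - radius):
        raise ValueError(f"disk of radius {radius} at {center} exceeds image bounds")
    if radius == 0:
        return float(image[r, c])
    rr, cc = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    mask = rr**2 + cc**2 <= radius**2
    patch = image[r - radius : r + radius + 1, c - radius : c + radius + 1]
    return float(patch[mask].mean())


def extract_landmark_intensities(
    image: np.ndarray,
    landmarks: dict[str, tuple[int, int]],
    radius: int = 3,
) -> LandmarkIntensities:
    """Measure C7 and T1-T4 intensities as disk means of given radius."""
    vals = {}
    for name in ("C7", "T1", "T2", "T3", "T4"):
        if name not in landmarks:
            raise ValueError(f"missing landmark {name}")
        vals[name.lower()] = disk_mean(image, landmarks[name], radius)
    return LandmarkIntensities(**vals)


def compute_central_signature(cohort: Sequence[LandmarkIntensities]) -> CentralSignature:
    """Cohort landmark means, per-image signatures and their mean (CS)."""
    if len(cohort) < 2:
        raise ValueError("a cohort of at least two images is required")
    t = np.array([li.thoracic for li in cohort])  # (n_images, 4)
    if np.any(t <= 0):
        raise ValueError("landmark intensities must be positive")
    t_bar = t.mean(axis=0)
    signatures = (t / t_bar).mean(axis=1)
    return CentralSignature(t_bar=t_bar, signatures=signatures, cs=float(signatures.mean()))


def image_signature(li: LandmarkIntensities, t_bar: np.ndarray) -> float:
    """Per-image signature s = mean_j(T_j / t_bar_j) against cohort means."""
    t_bar = np.asarray(t_bar, dtype=float)
    if np.any(t_bar <= 0):
        raise ValueError("cohort landmark means must be positive")
    return float((li.thoracic / t_bar).mean())


def normalize_image(image: np.ndarray, signature: float) -> np.ndarray:
    """Divide image intensities by the (positive) signature."""
    if not signature > 0:
        raise ValueError("signature must be positive")
    return np.asarray(image, dtype=float) / signature


def crop_roi(image: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    """Copy the ``(row0, col0, height, width)`` sub-matrix out of the image."""
    image = np.asarray(image)
    r0, c0, bh, bw = box
    h, w = image.shape
    if r0 < 0 or c0 < 0 or bh <= 0 or bw <= 0 or r0 + bh > h or c0 + bw > w:
        raise ValueError(f"ROI box {box} does not fit inside image of shape {image.shape}")
    return image[r0 : r0 + bh, c0 : c0 + bw].copy()
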