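"""Synthetic phantom radiographs and feature-level simulations.

No public image archive accompanies the discrimination problem this package
addresses, so the pipeline is exercised on parametric-geometric phantoms:
dark elliptical lung fields on a brighter soft-tissue background, periodic
rib ridges, and a bright vertebral strip carrying five landmark blobs (C7
and T1-T4).  Disease classes differ by the opacity added inside a lung
field -- a compact, sharp-margined nodule for lung cancer (LC) versus a
diffuse wedge confined to one lower lung zone for lobar pneumonia (PNEU).
The phantom reproduces the *signal structure* the pipeline assumes (edges,
stable spine landmarks with a small multiplicative per-image intensity
factor, focal versus diffuse opacity); it makes no claim to anatomical
realism or projection physics.

A second, feature-level simulator draws per-class texture-measure values
from univariate normal distributions, providing ground truth for the
discriminant and ROC machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .radiograph import CLASS_LABELS, LANDMARK_NAMES, Radiograph


class PlacementError(ValueError):
    """Raised when a lesion cannot be placed inside a lung field."""


def default_landmarks(height: int, width: int) -> dict[str, tuple[int, int]]:
    """Landmark positions along the spine: C7 on top, T1-T4 below."""
    col = width // 2
    fracs = (0.14, 0.24, 0.34, 0.44, 0.54)
    return {name: (int(f * height), col) for name, f in zip(LANDMARK_NAMES, fracs)}


@dataclass
class PhantomSpec:
    """Parameters of one phantom radiograph.

    ``noise_sd`` is the standard deviation of additive Gaussian noise in
    (12-bit) intensity units.  ``lesion_radius_frac`` sets the LC nodule
    radius as a fraction of the smaller image dimension.
    """

    class_label: str
    width: int = 512
    height: int = 512
    noise_sd: float = 15.0
    seed: int = 0
    landmark_positions: dict[str, tuple[int, int]] | None = None
    roi_size: int = 256
    lesion_radius_frac: float = 0.07

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.roi_size > min(self.height, self.width):
            raise ValueError("roi_size exceeds image dimensions")
        if self.landmark_positions is None:
            self.landmark_positions = default_landmarks(self.height, self.width)
        for name, (r, c) in self.landmark_positions.items():
            if not (0 <= r < self.height and 0 <= c < self.width):
                raise ValueError(f"landmark {name} lies outside the image")


# intensity levels on the 12-bit scale of digitised film
_BASE = 1600.0       # mediastinum / soft tissue
_LUNG = 680.0        # aerated lung field
_RIB_AMP = 130.0     # sinusoidal rib ridge amplitude
_STRIP = 2900.0      # vertebral strip
_BLOB = 480.0        # landmark blob peak on top of the strip
_LC_AMP = 650.0      # nodule peak opacity
_PNEU_AMP = 420.0    # wedge opacity
_LANDMARK_LOG_SD = 0.05  # per-image lognormal factor on spine intensity


def _lung_geometry(h: int, w: int):
    """Centers and semi-axes (rows, cols) of the two lung ellipses."""
    left = (0.50 * h, 0.27 * w)
    right = (0.50 * h, 0.73 * w)
    axes = (0.32 * h, 0.17 * w)
    return left, right, axes


def _ellipse_mask(h, w, center, axes):
    rr, cc = np.mgrid[0:h, 0:w]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> Radiograph:
    """Render one phantom radiograph with ground-truth annotations.

    Deterministic for a fixed ``spec.seed``; the seed drives three
    independent streams (landmark intensity factor, lesion variation,
    pixel noise) so that phantoms of different classes built from the same
    seed share the identical noise field.
    """
    h, w = spec.height, spec.width
    ss = np.random.SeedSequence(spec.seed)
    rng_land, rng_lesion, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    left_c, right_c, axes = _lung_geometry(h, w)
    left = _ellipse_mask(h, w, left_c, axes)
    right = _ellipse_mask(h, w, right_c, axes)
    lungs = left | right

    img = np.full((h, w), _BASE)
    img[lungs] = _LUNG

    # rib ridges: gently tilted sinusoidal bands inside the lung fields
    rr, cc = np.mgrid[0:h, 0:w]
    period = h / 9.0
    ribs = _RIB_AMP * (1.0 + np.cos(2 * np.pi * (rr + 0.15 * cc) / period))
    img[lungs] += ribs[lungs]

    # vertebral strip with landmark blobs, scaled by a per-image factor
    m = float(np.exp(rng_land.normal(0.0, _LANDMARK_LOG_SD)))
    half = max(2, int(0.045 * w))
    col0 = w // 2
    strip = np.abs(cc - col0) <= half
    img[strip] = _STRIP * m
    sigma_b = max(2.0, 0.01 * min(h, w))
    for name, (lr, lc_) in spec.landmark_positions.items():
        d2 = (rr - lr) ** 2.0 + (cc - lc_) ** 2.0
        img += _BLOB * m * np.exp(-d2 / (2 * sigma_b**2))

    roi_center = right_c  # NL: fixed box over the right lung field
    if spec.class_label == "LC":
        center = (0.42 * h, 0.71 * w)
        radius = spec.lesion_radius_frac * min(h, w)
        # the nodule disk must fit inside the lung ellipse
        d = np.hypot((center[0] - right_c[0]) / axes[0], (center[1] - right_c[1]) / axes[1])
        if d + radius / min(axes) > 1.0:
            raise PlacementError("nodule does not fit inside the lung field")
        amp = _LC_AMP * float(np.exp(rng_lesion.normal(0.0, 0.08)))
        dist = np.hypot(rr - center[0], cc - center[1])
        img += amp * np.exp(-((dist / radius) ** 8))  # compact, sharp margin
        roi_center = center
    elif spec.class_label == "PNEU":
        # diffuse wedge confined to the left lower zone
        wedge = left & (rr > 0.52 * h) & (np.abs(cc - left_c[1]) < 0.9 * (rr - 0.50 * h))
        if not wedge.any():
            raise PlacementError("wedge does not intersect the lung field")
        amp = _PNEU_AMP * float(np.exp(rng_lesion.normal(0.0, 0.08)))
        soft = ndimage.gaussian_filter(wedge.astype(float), 0.02 * min(h, w))
        img += amp * soft
        roi_center = tuple(np.mean(np.nonzero(wedge), axis=1))

    if spec.noise_sd > 0:
        img = img + rng_noise.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 4095.0)

    s = spec.roi_size
    r0 = int(np.clip(round(roi_center[0] - s / 2), 0, h - s))
    c0 = int(np.clip(round(roi_center[1] - s / 2), 0, w - s))
    return Radiograph(
        img,
        bit_depth=12,
        label=spec.class_label,
        landmarks=dict(spec.landmark_positions),
        roi_box=(r0, c0, s, s),
        meta={"seed": spec.seed},
    )


def generate_cohort(
    n_nl: int,
    n_lc: int,
    n_pneu: int,
    seed: int,
    *,
    width: int = 512,
    height: int = 512,
    noise_sd: float = 15.0,
    roi_size: int | None = None,
) -> list[Radiograph]:
    """Generate an annotated phantom cohort (NL first, then LC, then PNEU).

    Per-image seeds are derived reproducibly from the master seed, and the
    per-image lognormal factor on the vertebral strip gives the landmark
    intensities a small (~5%) coefficient of variation across the cohort.
    """
    if min(n_nl, n_lc, n_pneu) < 0:
        raise ValueError("cohort counts must be nonnegative")
    if roi_size is None:
        roi_size = min(256, min(width, height) // 2)
    total = n_nl + n_lc + n_pneu
    seeds = np.random.default_rng(seed).integers(0, 2**31, size=max(total, 1))
    labels = ["NL"] * n_nl + ["LC"] * n_lc + ["PNEU"] * n_pneu
    return [
        generate_phantom(
            PhantomSpec(
                class_label=lab,
                width=width,
                height=height,
                noise_sd=noise_sd,
                seed=int(s),
                roi_size=roi_size,
            )
        )
        for lab, s in zip(labels, seeds)
    ]


def write_cohort(images: list[Radiograph], outdir) -> "pd.DataFrame":
    """Write a cohort as uint16 TIFFs + JSON sidecars and a CSV manifest."""
    from pathlib import Path

    from .radiograph import write_image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rad in enumerate(images):
        path = outdir / f"img_{i:04d}_{rad.label}.tif"
        write_image(path, rad)
        rows.append({"path": str(path), "class": rad.label, "seed": rad.meta.get("seed")})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# feature-level simulation


#: Default per-class (mean, SD) of the eight texture measures, at the
#: magnitudes these measures take on 256x256 response maps of clinical
#: chest radiographs.  Near-degenerate spreads are given a nominal 2e-5.
DEFAULT_FEATURE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "NL": {
        "energy": (34516.27, 180.4126),
        "mean_energy": (0.1317, 0.0012),
        "entropy": (7.1395, 0.5147),
        "contrast": (4.770335660e9, 1.6368541e7),
        "homogeneity": (1795.1242, 108.4563),
        "stdv": (0.0011, 2e-5),
        "stde": (0.0012, 2e-5),
        "corr": (0.9999, 2e-5),
    },
    "LC": {
        "energy": (20827.91, 176.8569),
        "mean_energy": (0.0176, 0.0023),
        "entropy": (7.0051, 0.3724),
        "contrast": (3.656382764e9, 2.3589643e7),
        "homogeneity": (1137.0325, 89.7962),
        "stdv": (0.0011, 2e-5),
        "stde": (0.0012, 2e-5),
        "corr": (0.9999, 2e-5),
    },
    "PNEU": {
        "energy": (21634.0, 158.1402),
        "mean_energy": (0.0130, 0.0019),
        "entropy": (6.9958, 0.4145),
        "contrast": (3.086836786e9, 1.8975301e7),
        "homogeneity": (1009.1185, 93.5230),
        "stdv": (0.0010, 2e-5),
        "stde": (0.0010, 2e-5),
        "corr": (0.9999, 2e-5),
    },
}


@dataclass
class FeatureSimSpec:
    """Per-class normal parameters for simulated texture measures."""

    class_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_FEATURE_PARAMS
    )
    n_per_class: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("need at least two samples per class")
        for label, params in self.class_params.items():
            for measure, (mu, sd) in params.items():
                if not sd > 0:
                    raise ValueError(f"SD for {label}/{measure} must be positive")


def sample_features(spec: FeatureSimSpec) -> pd.DataFrame:
    """Draw a labelled feature table from the per-class normal model."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for label, params in spec.class_params.items():
        cols = {"class": [label] * spec.n_per_class}
        for measure, (mu, sd) in params.items():
            cols[measure] = rng.normal(mu, sd, size=spec.n_per_class)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)
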