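"""Texture measures of a response map.

Eight scalar measures summarise a real-valued response map (a phase
congruency map or a rectified Gabor response).  Five are classical
co-occurrence (Haralick-style) statistics of the normalised gray-level
co-occurrence matrix P built from the min-max quantised map:

    energy       sum P^2                       (angular second moment)
    entropy      -sum P log2 P                 (0 log 0 := 0)
    contrast     sum (i - j)^2 P
    homogeneity  sum P / (1 + |i - j|)
    correlation  sum (i - mu_i)(j - mu_j) P / (sigma_i sigma_j)

Three are computed from the raw map values: the mean energy (mean of the
squared values), the standard deviation of the values (STDV), and the
standard deviation of per-channel energies (STDE) when the 30-channel
stack behind the map is available (otherwise the SD of the squared
values).  The total map energy sum(map^2) is exposed alongside.

Because quantisation is min-max relative, all co-occurrence measures are
invariant to affine rescaling of the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: canonical measure order used in feature tables
MEASURES = (
    "energy",
    "mean_energy",
    "entropy",
    "contrast",
    "homogeneity",
    "stdv",
    "stde",
    "corr",
)


def quantize(values: np.ndarray, levels: int = 256) -> np.ndarray:
    """Linear min-max binning of a finite map into ``levels`` integer bins.

    A constant map quantises to all zeros.
    """
    values = np.asarray(values, dtype=float)
    if levels < 2:
        raise ValueError("need at least two quantisation levels")
    if not np.all(np.isfinite(values)):
        raise ValueError("map contains non-finite values")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.intp)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


@dataclass
class CooccurrenceMatrix:
    """Normalised joint distribution of level pairs at a fixed offset."""

    p: np.ndarray  # (levels, levels), sums to 1
    offset: tuple[int, int]
    levels: int
    symmetric: bool


def cooccurrence(
    qmap: np.ndarray,
    offset: tuple[int, int] = (0, 1),
    *,
    levels: int | None = None,
    symmetric: bool = True,
) -> CooccurrenceMatrix:
    """Gray-level co-occurrence matrix of an integer map at one offset.

    Counts pairs (qmap[r, c], qmap[r+dr, c+dc]); with ``symmetric`` the
    transposed counts are added.  The matrix is normalised to sum 1.
    """
    qmap = np.asarray(qmap)
    if not np.issubdtype(qmap.dtype, np.integer):
        raise ValueError("cooccurrence expects an integer (quantised) map")
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise ValueError("offset must be nonzero")
    h, w = qmap.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset {offset} does not fit in a {h}x{w} map")
    if levels is None:
        levels = int(qmap.max()) + 1

    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    a = qmap[r0, c0].ravel()
    b = qmap[r1, c1].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels).astype(float)
    counts = counts.reshape(levels, levels)
    if symmetric:
        counts = counts + counts.T
    return CooccurrenceMatrix(
        p=counts / counts.sum(), offset=(dr, dc), levels=levels, symmetric=symmetric
    )


def glcm_measures(p: np.ndarray) -> dict[str, float]:
    """The five co-occurrence measures of a normalised matrix P.

    Correlation of a single-cell (constant-map) matrix is undefined and
    reported as NaN.
    """
    p = np.asarray(p, dtype=float)
    levels = p.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i > 0 and var_j > 0:
        corr = float((((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j))
    else:
        corr = float("nan")
    return {
        "energy": float((p**2).sum()),
        "entropy": entropy,
        "contrast": float(((i - j) ** 2 * p).sum()),
        "homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "corr": corr,
    }


@dataclass(frozen=True)
class TextureVector:
    """The eight texture measures of one response map."""

    energy: float
    mean_energy: float
    entropy: float
    contrast: float
    homogeneity: float
    stdv: float
    stde: float
    corr: float
    map_energy: float = float("nan")  # raw sum of squared map values

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURES}


def texture_vector(
    values: np.ndarray,
    *,
    levels: int = 256,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = True,
    channel_stack: np.ndarray | None = None,
) -> TextureVector:
    """Compute the eight texture measures of a response map.

    ``channel_stack`` (any array whose trailing two axes are the map) lets
    STDE be the SD over per-channel mean energies; without it STDE falls
    back to the SD of the squared map values.
    """
    values = np.asarray(values, dtype=float)
    q = quantize(values, levels)
    glcm = cooccurrence(q, offset, levels=levels, symmetric=symmetric)
    meas = glcm_measures(glcm.p)

    if channel_stack is not None:
        energies = (np.asarray(channel_stack, dtype=float) ** 2).mean(axis=(-2, -1)).ravel()
        stde = float(energies.std(ddof=1)) if energies.size > 1 else 0.0
    else:
        stde = float((values**2).std(ddof=1))

    return TextureVector(
        energy=meas["energy"],
        mean_energy=float((values**2).mean()),
        entropy=meas["entropy"],
        contrast=meas["contrast"],
        homogeneity=meas["homogeneity"],
        stdv=float(values.std(ddof=1)),
        stde=stde,
        corr=meas["corr"],
        map_energy=float((values**2).sum()),
    )
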