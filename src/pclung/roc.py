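"""ROC analysis of a fitted discriminant over the cost-prior ratio C.

Sweeping the decision threshold ln C over all positive C traces out the
receiver operating characteristic: at each C the true positive fraction
is TPF = 1 - delta and the false positive fraction is FPF = beta.  The
area under the sorted (FPF, TPF) curve (trapezoidal rule, with (0,0) and
(1,1) appended) summarises a measure's discriminating power free of any
threshold choice; curves can also be compared at a fixed low FPF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import DiscriminantModel, score


def default_log_c_grid(n_points: int = 201, span: float = 10.0) -> np.ndarray:
    """Uniform grid of ln C values on [-span, span]."""
    if n_points < 2:
        raise ValueError("need at least two grid points")
    return np.linspace(-span, span, n_points)


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (FPF, TPF) pairs with their generating ln C values."""

    fpf: np.ndarray
    tpf: np.ndarray
    log_c: np.ndarray  # NaN for the appended (0,0)/(1,1) endpoints
    auc: float

    def __post_init__(self):
        if np.any(self.fpf < 0) or np.any(self.fpf > 1):
            raise ValueError("FPF out of [0, 1]")
        if np.any(self.tpf < 0) or np.any(self.tpf > 1):
            raise ValueError("TPF out of [0, 1]")

    def tpf_at_fpf(self, fpf: float) -> float:
        """Interpolated TPF at a fixed FPF (dominance comparison point)."""
        return float(np.interp(fpf, self.fpf, self.tpf))


def auc(fpf: np.ndarray, tpf: np.ndarray) -> float:
    """Trapezoidal area under a sorted ROC polyline with endpoints."""
    fpf = np.asarray(fpf, dtype=float)
    tpf = np.asarray(tpf, dtype=float)
    if fpf.size < 2 or np.any(np.diff(fpf) < 0):
        raise ValueError("curve must be sorted by FPF with >= 2 points")
    if not (fpf[0] == 0 and tpf[0] == 0 and fpf[-1] == 1 and tpf[-1] == 1):
        raise ValueError("curve must include the (0,0) and (1,1) endpoints")
    return float(np.trapezoid(tpf, fpf))


def roc_curve(
    model: DiscriminantModel,
    x1,
    x2,
    log_c_grid: np.ndarray | None = None,
) -> ROCCurve:
    """ROC curve of a fitted discriminant on a labelled test set.

    ``x1``/``x2`` are the class-1 (positive) and class-2 feature values.
    At each grid value, TPF is the class-1 fraction with score >= ln C and
    FPF the class-2 fraction; points are sorted by (FPF, TPF), duplicates
    merged, and the endpoints appended.
    """
    if log_c_grid is None:
        log_c_grid = default_log_c_grid()
    log_c_grid = np.asarray(log_c_grid, dtype=float)
    if log_c_grid.size == 0:
        raise ValueError("empty threshold grid")
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both classes must be present")

    s1 = np.sort(np.atleast_1d(score(model, x1)))
    s2 = np.sort(np.atleast_1d(score(model, x2)))
    # fraction of scores >= threshold, via a right-bisect on sorted scores
    tpf = 1.0 - np.searchsorted(s1, log_c_grid, side="left") / s1.size
    fpf = 1.0 - np.searchsorted(s2, log_c_grid, side="left") / s2.size

    fpf = np.concatenate([[0.0], fpf, [1.0]])
    tpf = np.concatenate([[0.0], tpf, [1.0]])
    log_c = np.concatenate([[np.nan], log_c_grid, [np.nan]])
    order = np.lexsort((tpf, fpf))
    fpf, tpf, log_c = fpf[order], tpf[order], log_c[order]
    keep = np.concatenate([[True], (np.diff(fpf) > 0) | (np.diff(tpf) > 0)])
    fpf, tpf, log_c = fpf[keep], tpf[keep], log_c[keep]
    return ROCCurve(fpf=fpf, tpf=tpf, log_c=log_c, auc=auc(fpf, tpf))
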