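"""PSNR-guided coordinate search over the phase-congruency parameters.

The PC model has nine coupled parameters; they are selected by maximising
the peak signal-to-noise ratio between each (normal-lung) image and its
PC map, sweeping one parameter at a time in a fixed order while holding
the others at their current best -- a deterministic coordinate descent.
Before comparison the image is min-max rescaled to [0, 1], the scale on
which the PC map already lives, so MAX = 1 and

    PSNR = 10 log10(1 / MSE).

The search starts from a generic natural-image parameter set and, because
the current value of every parameter is always among its candidates, the
final PSNR can never fall below the starting one.  Ties are broken toward
the smaller parameter value (cheaper filters, deterministic outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Callable, Sequence

import numpy as np

from .pc import GENERIC_START, PCParams, phase_congruency_map

#: the order in which parameters are swept; alpha and sigma jointly
DEFAULT_ORDER: tuple = ("n", "o", "lambda_min", ("alpha", "sigma"), "d", "gamma", "c", "k")

#: default candidate lists per parameter
DEFAULT_GRID: dict[str, list] = {
    "n": [2, 3, 4, 5, 6],
    "o": [2, 4, 6, 8],
    "lambda_min": [3.0, 4.0, 6.0, 8.0, 10.0],
    "alpha": [1.5, 2.0, 2.5, 3.0],
    "sigma": [0.45, 0.55, 0.65, 0.75],
    "d": [0.5, 1.0, 1.5, 1.7, 2.0],
    "gamma": [10.0, 20.0, 50.0],
    "c": [0.1, 0.2, 0.3, 0.4, 0.5],
    "k": [1.0, 2.0, 3.0],
}


def psnr(original: np.ndarray, transformed: np.ndarray) -> float:
    """PSNR in dB between an image and a response map on a common scale.

    The original is min-max rescaled to [0, 1] (a constant original is
    used as-is); the transformed map is assumed already dimensionless on
    [0, 1].  Identical inputs (MSE = 0) raise, as PSNR is unbounded.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(transformed, dtype=float)
    if a.shape != b.shape:
        raise ValueError("original and transformed shapes differ")
    lo, hi = a.min(), a.max()
    if hi > lo:
        a = (a - lo) / (hi - lo)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        raise ValueError("images are identical; PSNR is unbounded")
    return float(10.0 * np.log10(1.0 / mse))


@dataclass
class TuneResult:
    """Outcome of a coordinate search."""

    best_params: PCParams
    best_psnr: float
    start_psnr: float
    trace: list[dict]  # one record per swept parameter (group)


def _param_names(entry) -> tuple[str, ...]:
    return (entry,) if isinstance(entry, str) else tuple(entry)


def coordinate_descent(
    objective: Callable[[dict], float],
    grid: dict[str, Sequence],
    order: Sequence,
    start: dict,
) -> tuple[dict, float, list[dict]]:
    """Maximise ``objective`` by sweeping one parameter (group) at a time.

    ``order`` entries are parameter names or tuples of names swept
    jointly (Cartesian product of their candidate lists).  The current
    value is always evaluated alongside the candidates, so the objective
    is nondecreasing along the trace.  Ties go to the candidate that
    sorts first (smallest values).
    """
    import itertools

    current = dict(start)
    best_score = objective(current)
    trace: list[dict] = []
    for entry in order:
        names = _param_names(entry)
        for name in names:
            if name not in grid or len(grid[name]) == 0:
                raise ValueError(f"empty candidate list for parameter {name!r}")
        cand_lists = [sorted(set(list(grid[n]) + [current[n]])) for n in names]
        combos = list(itertools.product(*cand_lists))
        scores = []
        for combo in combos:
            trial = dict(current, **dict(zip(names, combo)))
            scores.append(objective(trial))
        best_idx = int(np.argmax(scores))  # first (smallest combo) wins ties
        current.update(dict(zip(names, combos[best_idx])))
        best_score = scores[best_idx]
        trace.append(
            {
                "parameters": names,
                "candidates": combos,
                "scores": scores,
                "chosen": combos[best_idx],
                "score": best_score,
            }
        )
    return current, best_score, trace


def sequential_search(
    images: Sequence[np.ndarray],
    grid: dict[str, Sequence] | None = None,
    order: Sequence | None = None,
    start: PCParams | None = None,
) -> TuneResult:
    """Coordinate search of the PC parameters maximising mean PSNR.

    The objective is the mean, over the supplied images, of the PSNR
    between the image and its PC map.
    """
    if not images:
        raise ValueError("need at least one image")
    if grid is None:
        grid = DEFAULT_GRID
    if order is None:
        order = DEFAULT_ORDER
    if start is None:
        start = GENERIC_START

    def objective(param_dict: dict) -> float:
        params = replace(PCParams(), **param_dict)
        vals = [psnr(img, phase_congruency_map(img, params).pc) for img in images]
        return float(np.mean(vals))

    start_dict = {
        f.name: getattr(start, f.name) for f in fields(PCParams) if f.name != "epsilon"
    }
    start_psnr = objective(start_dict)
    best, best_score, trace = coordinate_descent(objective, grid, order, start_dict)
    return TuneResult(
        best_params=replace(PCParams(), **best),
        best_psnr=best_score,
        start_psnr=start_psnr,
        trace=trace,
    )
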