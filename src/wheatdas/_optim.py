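"""Bounded derivative-free simplex search shared by calibration and assimilation.

All parameter fits in the package go through one subspace-scaled
Nelder-Mead wrapper: parameters are rescaled to the unit box spanned by
their bounds (so a single simplex step is meaningful for quantities whose
magnitudes differ by orders of magnitude, e.g. SLA vs. TDWI), the search
is strictly bound-constrained, and results are deterministic for a given
start point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["OptResult", "nelder_mead"]


@dataclass
class OptResult:
    x: np.ndarray
    fun: float
    nfev: int
    success: bool


def nelder_mead(
    func,
    x0: np.ndarray,
    bounds: list[tuple[float, float]],
    maxfev: int = 2000,
    xtol: float = 1e-4,
    ftol: float = 1e-8,
) -> OptResult:
    """Minimize ``func`` from ``x0`` within ``bounds``.

    ``xtol`` is interpreted on the unit-box scale, i.e. relative to each
    parameter's bound width.
    """
    x0 = np.asarray(x0, float)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy lower < upper")
    width = hi - lo
    z0 = np.clip((x0 - lo) / width, 0.0, 1.0)

    def wrapped(z):
        return func(lo + np.clip(z, 0.0, 1.0) * width)

    # explicit initial simplex: a fixed fraction of each bound width, so the
    # first moves are meaningful even when a coordinate starts at zero
    step = 0.15
    simplex = np.tile(z0, (z0.size + 1, 1))
    for i in range(z0.size):
        simplex[i + 1, i] = z0[i] + step if z0[i] + step <= 1.0 else z0[i] - step

    res = minimize(
        wrapped,
        z0,
        method="Nelder-Mead",
        bounds=[(0.0, 1.0)] * z0.size,
        options={
            "maxfev": maxfev,
            "xatol": xtol,
            "fatol": ftol,
            "adaptive": z0.size > 2,
            "initial_simplex": simplex,
        },
    )
    x = lo + np.clip(res.x, 0.0, 1.0) * width
    return OptResult(x=x, fun=float(res.fun), nfev=int(res.nfev), success=bool(res.success))
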