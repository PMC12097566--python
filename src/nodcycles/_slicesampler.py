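"""Univariate slice sampling, vectorized over independent coordinates.

The Gibbs sweep in :mod:`nodcycles.inference` updates each scalar parameter
from its full conditional with the classic step-out/shrinkage slice sampler
(Neal 2003).  Random intercepts are conditionally independent given the
globals, so all of them are updated in one vectorized pass: ``logf`` maps a
vector of coordinate values to the vector of their (separable) conditional
log densities.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["slice_sample_many", "slice_sample_scalar"]


def slice_sample_many(
    x0: np.ndarray,
    logf: Callable[[np.ndarray], np.ndarray],
    rng: np.random.Generator,
    width: float | np.ndarray = 1.0,
    lower: float = -np.inf,
    upper: float = np.inf,
    max_stepout: int = 30,
    max_shrink: int = 100,
) -> np.ndarray:
    """One slice-sampling transition for each coordinate of ``x0``.

    ``logf`` must be separable: component i of the output may depend only on
    component i of the input.  Support bounds are handled by clamping the
    bracket; ``logf`` must return -inf outside its support only if the
    bracket can still reach there (we clamp first, so it normally cannot).
    """
    x0 = np.asarray(x0, dtype=float)
    m = x0.shape
    f0 = logf(x0)
    logy = f0 - rng.exponential(size=m)

    u = rng.uniform(size=m)
    L = x0 - width * u
    R = L + width
    L = np.clip(L, lower, None)
    R = np.clip(R, None, upper)

    for _ in range(max_stepout):
        open_l = (L > lower) & (logf(L) > logy)
        if not open_l.any():
            break
        L = np.where(open_l, np.clip(L - width, lower, None), L)
    for _ in range(max_stepout):
        open_r = (R < upper) & (logf(R) > logy)
        if not open_r.any():
            break
        R = np.where(open_r, np.clip(R + width, None, upper), R)

    x1 = x0.copy()
    done = np.zeros(m, dtype=bool)
    for _ in range(max_shrink):
        prop = L + rng.uniform(size=m) * (R - L)
        fp = logf(np.where(done, x0, prop))
        accept = (fp >= logy) & ~done
        x1 = np.where(accept, prop, x1)
        done |= accept
        if done.all():
            break
        below = ~done & (prop < x0)
        L = np.where(below, prop, L)
        R = np.where(~done & ~below, prop, R)
    return x1


def slice_sample_scalar(
    x0: float,
    logf: Callable[[float], float],
    rng: np.random.Generator,
    width: float = 1.0,
    lower: float = -np.inf,
    upper: float = np.inf,
) -> float:
    """Scalar convenience wrapper around :func:`slice_sample_many`."""

    def vec_logf(x: np.ndarray) -> np.ndarray:
        return np.array([logf(float(x[0]))])

    out = slice_sample_many(np.array([x0]), vec_logf, rng,
                            width=width, lower=lower, upper=upper)
    return float(out[0])
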