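"""Central-difference derivatives with Richardson extrapolation.

Used for the score vectors, cluster score contributions and observed Hessians
of the frailty log-likelihood, which has no convenient closed-form
derivatives once the frailty is integrated out.  Steps are scaled per
coordinate (cube-root machine epsilon times the coordinate magnitude for
first derivatives) and one Richardson step removes the leading O(h^2) error,
giving O(h^4) accuracy on smooth objectives.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

_EPS = np.finfo(float).eps


def _steps(x: np.ndarray, power: float) -> np.ndarray:
    return _EPS ** power * np.maximum(1.0, np.abs(x))


def gradient(f: Callable[[np.ndarray], np.ndarray], x,
             richardson: bool = True) -> np.ndarray:
    """Gradient (or Jacobian, for vector-valued f) by central differences.

    For f mapping R^p -> R^m the result has shape (m, p); scalar-valued f
    gives shape (p,).  With ``richardson`` the two-step estimate
    (4 D(h/2) - D(h)) / 3 is returned.
    """
    x = np.asarray(x, dtype=float)
    h = _steps(x, 1.0 / 3.0)
    cols = []
    for k in range(x.size):
        e = np.zeros_like(x)
        e[k] = h[k]
        d1 = (np.asarray(f(x + e)) - np.asarray(f(x - e))) / (2 * h[k])
        if richardson:
            d2 = (np.asarray(f(x + e / 2)) - np.asarray(f(x - e / 2))) / h[k]
            d1 = (4 * d2 - d1) / 3
        cols.append(d1)
    return np.stack(cols, axis=-1)


def hessian(f: Callable[[np.ndarray], float], x,
            richardson: bool = True) -> np.ndarray:
    """Symmetric Hessian of a scalar function by central second differences."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = _steps(x, 0.25)

    def second(hs: np.ndarray) -> np.ndarray:
        out = np.empty((p, p))
        f0 = f(x)
        for k in range(p):
            ek = np.zeros(p); ek[k] = hs[k]
            out[k, k] = (f(x + ek) - 2 * f0 + f(x - ek)) / hs[k] ** 2
        for k in range(p):
            for l in range(k + 1, p):
                ek = np.zeros(p); ek[k] = hs[k]
                el = np.zeros(p); el[l] = hs[l]
                out[k, l] = out[l, k] = (
                    f(x + ek + el) - f(x + ek - el)
                    - f(x - ek + el) + f(x - ek - el)
                ) / (4 * hs[k] * hs[l])
        return out

    h1 = second(h)
    if not richardson:
        return 0.5 * (h1 + h1.T)
    h2 = second(h / 2)
    out = (4 * h2 - h1) / 3
    return 0.5 * (out + out.T)
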