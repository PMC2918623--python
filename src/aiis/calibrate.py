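"""Calibration helpers for the controller's trend coefficients.

The trend parameter A = a0*G0 + a5*G5 + a10*G10 approximates, from three
5-min-spaced readings, the 4-minute aggregate glycemia change that the
original per-minute artificial-pancreas algorithm used.  The shipped default
(a0, a5, a10) = (0.4, 0, -0.4) is the symmetric first difference over the
10-min window scaled to that aggregate.  `fit_trend_coefficients` re-derives
the coefficients by least squares against any user-supplied reference
glycemia profile, under the zero-sum constraint that makes A vanish for
constant glycemia.
"""

from __future__ import annotations

import numpy as np


def reference_trend(t: np.ndarray, G: np.ndarray, horizon: float = 4.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Target A values: glycemia change over the trailing `horizon` minutes.

    t must be sampled at 1-min resolution (or finer, uniformly).
    Returns (times, A_ref) where A_ref(t) = G(t) - G(t - horizon).
    """
    t = np.asarray(t, dtype=float)
    G = np.asarray(G, dtype=float)
    dt = float(np.median(np.diff(t)))
    lag = round(horizon / dt)
    if lag < 1 or lag >= len(G):
        raise ValueError("profile too short for the trend horizon")
    return t[lag:], G[lag:] - G[:-lag]


def fit_trend_coefficients(t: np.ndarray, G: np.ndarray, horizon: float = 4.0,
                           spacing: float = 5.0) -> tuple[float, float, float]:
    """Least-squares (a0, a5, a10) against a reference glycemia profile.

    Minimizes sum_t (a0*G(t) + a5*G(t-spacing) + a10*G(t-2*spacing)
    - A_ref(t))^2 subject to a0 + a5 + a10 = 0, parameterized as
    a0 = u, a5 = v - u, a10 = -v so the constraint holds identically.
    """
    t = np.asarray(t, dtype=float)
    G = np.asarray(G, dtype=float)
    dt = float(np.median(np.diff(t)))
    k = round(spacing / dt)
    if k < 1 or 2 * k >= len(G):
        raise ValueError("profile too short for the reading spacing")
    g0 = G[2 * k:]
    g5 = G[k:-k]
    g10 = G[:-2 * k]
    _, a_ref = reference_trend(t, G, horizon)
    a_ref = a_ref[len(a_ref) - len(g0):]
    # basis of the zero-sum subspace: (1,-1,0) and (0,1,-1)
    X = np.column_stack([g0 - g5, g5 - g10])
    coef, *_ = np.linalg.lstsq(X, a_ref, rcond=None)
    u, v = coef
    return float(u), float(v - u), float(-v)


__all__ = ["fit_trend_coefficients", "reference_trend"]
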