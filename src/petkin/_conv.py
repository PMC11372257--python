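"""Exact convolution primitives for piecewise-linear curves.

Tissue responses of linear compartment models are sums of exponential
convolutions of the blood input.  With the input represented as a
piecewise-linear curve (frame-midpoint knots), every convolution integral
has a closed form per segment, so the forward model carries no
grid-resolution error.  These primitives are shared by the analytic model
and by the frame-averaging step.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "exp_conv",
    "cum_integral",
    "double_integral",
]


def _phi1(z: np.ndarray) -> np.ndarray:
    """(1 - exp(-z))/z, stable near 0."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-10
    zs = np.where(small, 1.0, z)
    out = -np.expm1(-zs) / zs
    return np.where(small, 1.0 - z / 2.0, out)


def _phi2(z: np.ndarray) -> np.ndarray:
    """(z - 1 + exp(-z))/z**2, stable near 0."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < 1e-6
    zs = np.where(small, 1.0, z)
    out = (zs + np.expm1(-zs)) / zs**2
    return np.where(small, 0.5 - z / 6.0, out)


def _check_knots(tk: np.ndarray, vk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tk = np.asarray(tk, dtype=float)
    vk = np.asarray(vk, dtype=float)
    if tk.ndim != 1 or tk.shape != vk.shape or tk.size < 2:
        raise ValueError("knots must be two equal-length 1-d arrays (>= 2 points)")
    if np.any(np.diff(tk) <= 0):
        raise ValueError("knot times must be strictly increasing")
    return tk, vk


def exp_conv(tk, vk, alpha: float, t_eval) -> np.ndarray:
    """Convolve a piecewise-linear curve with exp(-alpha*t), exactly.

    Computes I(t) = \\int_0^t exp(-alpha*(t-s)) u(s) ds where u is linear
    between knots ``(tk, vk)`` and zero before ``tk[0]``.  ``t_eval`` must lie
    within ``[tk[0], tk[-1]]``.
    """
    tk, vk = _check_knots(tk, vk)
    T = np.atleast_1d(np.asarray(t_eval, dtype=float))
    if T.size and (T.min() < tk[0] - 1e-9 or T.max() > tk[-1] + 1e-9):
        raise ValueError(
            f"evaluation time outside knot support [{tk[0]}, {tk[-1]}]"
        )
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0.0:
        return cum_integral(tk, vk, t_eval)

    t0 = tk[:-1]
    t1 = tk[1:]
    v0 = vk[:-1]
    dt = t1 - t0
    m = np.diff(vk) / dt
    z = alpha * dt
    # contribution of a whole segment, valued at the segment end
    c_seg = v0 * dt * _phi1(z) + m * dt**2 * _phi2(z)

    # full segments: end time <= T, propagated by exp(-alpha*(T - t1))
    # (n_eval x n_seg); exponent <= 0 on the mask so no overflow after clip
    lag = T[:, None] - t1[None, :]
    full = lag >= -1e-12
    decay = np.exp(-alpha * np.clip(lag, 0.0, None))
    out = np.sum(np.where(full, c_seg[None, :] * decay, 0.0), axis=1)

    # partial segment containing T (knot-coincident T is fully counted above)
    idx = np.clip(np.searchsorted(tk, T, side="right") - 1, 0, tk.size - 2)
    s = T - tk[idx]
    inside = (s > 1e-12) & (T < tk[idx + 1] - 1e-12)
    if np.any(inside):
        i = idx[inside]
        ds = s[inside]
        zz = alpha * ds
        out[inside] += vk[i] * ds * _phi1(zz) + m[i] * ds**2 * _phi2(zz)
    return out if np.ndim(t_eval) else out[0]


def cum_integral(tk, vk, t_eval) -> np.ndarray:
    """\\int_0^t u(s) ds for piecewise-linear u (exact trapezoid)."""
    tk, vk = _check_knots(tk, vk)
    T = np.atleast_1d(np.asarray(t_eval, dtype=float))
    dt = np.diff(tk)
    seg = 0.5 * (vk[:-1] + vk[1:]) * dt
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    idx = np.clip(np.searchsorted(tk, T, side="right") - 1, 0, tk.size - 2)
    s = T - tk[idx]
    m = np.diff(vk) / dt
    out = cum[idx] + vk[idx] * s + 0.5 * m[idx] * s**2
    return out if np.ndim(t_eval) else out[0]


def double_integral(tk, vk, t_eval) -> np.ndarray:
    """\\int_0^t \\int_0^s u(r) dr ds for piecewise-linear u (exact)."""
    tk, vk = _check_knots(tk, vk)
    T = np.atleast_1d(np.asarray(t_eval, dtype=float))
    dt = np.diff(tk)
    m = np.diff(vk) / dt
    seg = 0.5 * (vk[:-1] + vk[1:]) * dt
    A = np.concatenate([[0.0], np.cumsum(seg)])  # cumulative integral at knots
    # integral of the cumulative over one segment:
    #   A_k*dt + v_k*dt^2/2 + m*dt^3/6
    segB = A[:-1] * dt + 0.5 * vk[:-1] * dt**2 + m * dt**3 / 6.0
    B = np.concatenate([[0.0], np.cumsum(segB)])
    idx = np.clip(np.searchsorted(tk, T, side="right") - 1, 0, tk.size - 2)
    s = T - tk[idx]
    out = B[idx] + A[idx] * s + 0.5 * vk[idx] * s**2 + m[idx] * s**3 / 6.0
    return out if np.ndim(t_eval) else out[0]
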