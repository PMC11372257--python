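"""Blood-pool input functions: continuous evaluation, delay, tail extrapolation.

The image-derived whole-blood curve is only sampled at frame midpoints; the
kinetic model needs it as a continuous function, shifted by a per-region
arrival delay, and — for equilibrium (SUVR) analysis — extrapolated far past
the scan end.  The late washout is fitted with a biexponential
A1*exp(-lam1*t) + A2*exp(-lam2*t) over a 14-90 min window and that tail is
used beyond the measured support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .tac_io import TimeActivityCurve

__all__ = [
    "BiexpTail",
    "InputFunction",
    "fit_biexp_tail",
    "extrapolate",
    "shift",
    "half_life",
]


class ExtrapolationError(ValueError):
    pass


class TailFitError(RuntimeError):
    pass


def half_life(lam: float) -> float:
    """Biologic half-life ln(2)/lam, minutes."""
    if lam <= 0:
        raise ValueError("rate must be positive")
    return math.log(2.0) / lam


@dataclass(frozen=True)
class BiexpTail:
    """Ordered biexponential washout (lam1 > lam2 > 0), amplitudes >= 0."""

    A1: float
    lam1: float
    A2: float
    lam2: float
    window: tuple[float, float]
    rss: float = 0.0

    def __post_init__(self):
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("amplitudes must be nonnegative")
        if not (self.lam1 > self.lam2 > 0):
            raise ValueError("rates must satisfy lam1 > lam2 > 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A1 * np.exp(-self.lam1 * t) + self.A2 * np.exp(-self.lam2 * t)

    @property
    def half_lives(self) -> tuple[float, float]:
        return (half_life(self.lam1), half_life(self.lam2))


@dataclass(frozen=True)
class InputFunction:
    """Whole-blood input: measured TAC + optional fitted tail + delay (min).

    Evaluation is linear interpolation between frame midpoints, ramping from
    zero at t=0 to the first midpoint, and follows the biexponential tail
    beyond the last midpoint once fitted.
    """

    tac: TimeActivityCurve
    tail: Optional[BiexpTail] = None
    delay: float = 0.0

    @property
    def _mid(self) -> np.ndarray:
        return self.tac.schedule.midpoints

    @property
    def support_end(self) -> float:
        return float(self._mid[-1])

    def base_knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Measured knots, anchored at (0, 0), before delay shifting."""
        tm = self._mid
        vm = self.tac.values
        if tm[0] > 0:
            tm = np.concatenate([[0.0], tm])
            vm = np.concatenate([[0.0], vm])
        return tm, vm

    def knots(self, t_max: float, tail_step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear knots covering [0, t_max], delay applied.

        Beyond the measured support the fitted tail is sampled every
        ``tail_step`` minutes (the tail is smooth and slow, so linear
        interpolation at this spacing is far below fitting noise).
        """
        tk, vk = self.base_knots()
        if t_max > self.support_end + self.delay + 1e-9:
            if self.tail is None:
                raise ExtrapolationError(
                    f"t={t_max:g} min is beyond the measured input support "
                    f"({self.support_end:g} min) and no biexponential tail is fitted"
                )
            t_ext = np.arange(self.support_end + tail_step, t_max - self.delay + tail_step, tail_step)
            if t_ext.size:
                tk = np.concatenate([tk, t_ext])
                vk = np.concatenate([vk, self.tail(t_ext)])
        return _shift_knots(tk, vk, self.delay, t_end=max(t_max, tk[-1] + self.delay))

    def __call__(self, t) -> np.ndarray:
        return self.evaluate(t)

    def evaluate(self, t) -> np.ndarray:
        """Concentration at time ``t`` (minutes, scalar or array)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        ts = t - self.delay
        tk, vk = self.base_knots()
        out = np.interp(np.clip(ts, 0.0, None), tk, vk, left=0.0)
        beyond = ts > self.support_end + 1e-12
        if np.any(beyond):
            if self.tail is None:
                raise ExtrapolationError(
                    "evaluation beyond the measured window requires a fitted tail"
                )
            out = np.where(beyond, self.tail(np.where(beyond, ts, 1.0)), out)
        out = np.where(ts < 0, 0.0, out)
        return out if t.ndim else float(out)

    def frame_values(self, schedule) -> np.ndarray:
        """Frame-averaged input concentrations on an arbitrary schedule."""
        from ._conv import cum_integral

        tk, vk = self.knots(float(schedule.ends[-1]) + 1e-9)
        ends = np.concatenate([schedule.starts, schedule.ends])
        cum = cum_integral(tk, vk, ends)
        n = schedule.n_frames
        return (cum[n:] - cum[:n]) / schedule.durations


def _shift_knots(tk: np.ndarray, vk: np.ndarray, t_d: float, t_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Shift knots so that u_shifted(t) = u(t - t_d), clamped to 0 before 0."""
    if t_d == 0.0:
        return tk, vk
    ts = tk + t_d
    if t_d > 0:
        ts = np.concatenate([[0.0], ts])
        vs = np.concatenate([[0.0], vk])
    else:
        keep = ts > 0
        v0 = np.interp(0.0, ts, vk)
        ts = np.concatenate([[0.0], ts[keep]])
        vs = np.concatenate([[v0], vk[keep]])
    return ts, vs


def fit_biexp_tail(
    inp: InputFunction,
    window: tuple[float, float] = (14.0, 90.0),
    n_starts: int = 6,
    seed: int = 0,
) -> BiexpTail:
    """Fit the biexponential washout on frame midpoints inside ``window``.

    Nonlinear least squares with nonnegativity bounds and multi-start over
    log-spaced rate initializations (the biexponential objective is
    multimodal).  Returns the rate-ordered tail.
    """
    t = inp._mid
    y = inp.tac.values
    sel = (t >= window[0]) & (t <= window[1])
    if sel.sum() < 4:
        raise TailFitError(f"need >= 4 frames inside window {window}, got {sel.sum()}")
    t, y = t[sel], y[sel]
    scale = max(float(np.max(np.abs(y))), 1e-12)

    def resid(p):
        a1, l1, a2, l2 = p
        return a1 * np.exp(-l1 * t) + a2 * np.exp(-l2 * t) - y

    lb = [0.0, 1e-6, 0.0, 1e-6]
    ub = [np.inf, 10.0, np.inf, 10.0]
    rng = np.random.default_rng(seed)
    fast_rates = np.geomspace(0.02, 1.0, n_starts)
    best = None
    for i, l1 in enumerate(fast_rates):
        l2 = l1 / 20.0
        jitter = 1.0 if i == 0 else float(rng.uniform(0.5, 2.0))
        x0 = [scale * jitter, l1, 0.5 * scale * jitter, l2]
        try:
            res = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise TailFitError("biexponential tail fit failed for every start")
    a1, l1, a2, l2 = best.x
    if l1 < l2:
        a1, l1, a2, l2 = a2, l2, a1, l1
    if abs(l1 - l2) < 1e-12:
        l1 = l2 * (1 + 1e-9) + 1e-12
    rss = float(2 * best.cost)
    return BiexpTail(float(a1), float(l1), float(a2), float(l2), window, rss)


def extrapolate(inp: InputFunction, horizon: float) -> InputFunction:
    """Attach the fitted tail for evaluation out to ``horizon`` minutes.

    Measured values are untouched on the measured support.  A horizon inside
    the scan is a no-op (warned).
    """
    if inp.tail is None:
        raise ExtrapolationError("fit_biexp_tail must be called before extrapolate")
    if horizon < inp.support_end:
        import logging

        logging.getLogger("petkin").warning(
            "extrapolation horizon %.1f min is inside the measured window; no-op",
            horizon,
        )
    return inp


def shift(inp: InputFunction, t_d: float, bound: float = 1.0) -> InputFunction:
    """Return the input delayed by ``t_d`` minutes (|t_d| <= bound)."""
    if abs(t_d) > bound + 1e-12:
        raise ValueError(f"|t_d| = {abs(t_d):g} exceeds the configured bound {bound:g} min")
    return replace(inp, delay=inp.delay + t_d)
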