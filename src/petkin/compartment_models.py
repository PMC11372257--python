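"""Forward simulation of 1- and 2-tissue compartment models.

The measured regional signal is modeled as

    C_m(t) = v_b * C_wb(t - t_d) + (1 - v_b) * C_t(t)

with the tissue concentration C_t driven by the delayed whole-blood input:

    1T:  dC_t/dt = K_1 u - k_2 C_t
    2T:  dC_1/dt = K_1 u - (k_2 + k_3) C_1 + k_4 C_2
         dC_2/dt = k_3 C_1 - k_4 C_2,      C_t = C_1 + C_2

Because the system is linear, C_t is the convolution of u with a sum of (at
most two) exponentials whose rates are the system eigenvalues.  With the
input represented piecewise-linearly, that convolution — and the per-frame
time average the scanner records — are evaluated in closed form
(:mod:`petkin._conv`), so the analytic model and the adaptive ODE oracle
are genuinely independent computations.

Model kinds follow the fitted-parameter-count naming: 1T4P (v_b, K_1, k_2,
t_d), 2T5P (+k_3, irreversible), 2T6P (+k_4, reversible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from ._conv import cum_integral, double_integral, exp_conv
from .input_function import InputFunction, _shift_knots
from .tac_io import FrameSchedule, TimeActivityCurve

MODEL_KINDS = ("1T4P", "2T5P", "2T6P")

#: number of fitted parameters per model kind (t_d included)
N_PARAMS = {"1T4P": 4, "2T5P": 5, "2T6P": 6}


@dataclass(frozen=True)
class KineticParams:
    """Microparameters of one region: fractional blood volume v_b, rate
    constants (1/min; K_1 in mL/min/mL), and arrival delay t_d (min)."""

    model: str
    v_b: float
    K_1: float
    k_2: float
    k_3: float = 0.0
    k_4: float = 0.0
    t_d: float = 0.0

    def __post_init__(self):
        if self.model not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model!r}")
        if not (0.0 <= self.v_b <= 1.0):
            raise ValueError("v_b must be in [0, 1]")
        for name in ("K_1", "k_2", "k_3", "k_4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.model == "1T4P" and (self.k_3 != 0 or self.k_4 != 0):
            raise ValueError("1T4P requires k_3 = k_4 = 0")
        if self.model == "2T5P" and self.k_4 != 0:
            raise ValueError("2T5P requires k_4 = 0")

    @property
    def vector(self) -> np.ndarray:
        full = [self.v_b, self.K_1, self.k_2, self.k_3, self.k_4, self.t_d]
        if self.model == "1T4P":
            return np.array(full[:3] + [full[5]])
        if self.model == "2T5P":
            return np.array(full[:4] + [full[5]])
        return np.array(full)

    @classmethod
    def from_vector(cls, model: str, x, fixed_delay: float | None = None) -> "KineticParams":
        x = list(map(float, x))
        if fixed_delay is None:
            *rates, td = x
        else:
            rates, td = x, fixed_delay
        if model == "1T4P":
            vb, k1, k2 = rates
            return cls(model, vb, k1, k2, 0.0, 0.0, td)
        if model == "2T5P":
            vb, k1, k2, k3 = rates
            return cls(model, vb, k1, k2, k3, 0.0, td)
        vb, k1, k2, k3, k4 = rates
        return cls(model, vb, k1, k2, k3, k4, td)


def impulse_response_terms(p: KineticParams) -> list[tuple[float, float]]:
    """(amplitude, rate) pairs of the tissue impulse response K_1 h(t).

    For the 2T system the rates are the eigenvalues
    a_{1,2} = (s ± sqrt(s^2 - 4 k_2 k_4))/2, s = k_2+k_3+k_4.  With
    nonnegative rates the eigenvalues coincide only when k_3 = 0 and
    k_2 = k_4, where the response degenerates to a single exponential
    (the analytic limit — the second compartment never fills).
    """
    if p.model == "1T4P" or (p.k_3 == 0.0 and p.k_4 == 0.0):
        return [(p.K_1, p.k_2)]
    s = p.k_2 + p.k_3 + p.k_4
    disc = math.sqrt(max(s * s - 4.0 * p.k_2 * p.k_4, 0.0))
    if disc <= 1e-10 * max(s, 1e-30):
        return [(p.K_1, 0.5 * s)]
    a_fast = 0.5 * (s + disc)
    a_slow = 0.5 * (s - disc)
    q = p.k_3 + p.k_4
    amp_fast = p.K_1 * (a_fast - q) / disc
    amp_slow = p.K_1 * (q - a_slow) / disc
    return [(amp_fast, a_fast), (amp_slow, a_slow)]


def _frame_avg_from_knots(
    tk: np.ndarray,
    vk: np.ndarray,
    p: KineticParams,
    schedule: FrameSchedule,
    extra_delay: float = 0.0,
) -> np.ndarray:
    """Frame-averaged C_m given input knots (delay already excluded)."""
    t_d = p.t_d + extra_delay
    t_end = float(schedule.ends[-1])
    if tk[-1] + t_d < t_end - 1e-9:
        raise ValueError(
            f"input knots (to {tk[-1]:g} min, delay {t_d:g}) do not cover the "
            f"schedule end {t_end:g} min"
        )
    ts, vs = _shift_knots(tk, vk, t_d, t_end)
    times = np.concatenate([schedule.starts, schedule.ends])
    n = schedule.n_frames
    dur = schedule.durations

    I0 = cum_integral(ts, vs, times)
    blood_avg = (I0[n:] - I0[:n]) / dur

    tissue_avg = np.zeros(n)
    if p.K_1 > 0:
        for amp, rate in impulse_response_terms(p):
            if amp == 0.0:
                continue
            if rate < 1e-8:
                G = double_integral(ts, vs, times)
            else:
                G = (I0 - exp_conv(ts, vs, rate, times)) / rate
            tissue_avg += amp * (G[n:] - G[:n]) / dur
    return p.v_b * blood_avg + (1.0 - p.v_b) * tissue_avg


def model_tac(p: KineticParams, inp: InputFunction, schedule: FrameSchedule) -> TimeActivityCurve:
    """Frame-averaged model TAC (analytic exponential convolution)."""
    t_need = float(schedule.ends[-1]) + max(0.0, -p.t_d) + 1e-6
    tk, vk = inp.knots(t_need)
    vals = _frame_avg_from_knots(tk, vk, p, schedule)
    return TimeActivityCurve(f"model[{p.model}]", schedule, vals, unit=inp.tac.unit)


def ode_oracle(p: KineticParams, inp: InputFunction, schedule: FrameSchedule) -> TimeActivityCurve:
    """Same contract as :func:`model_tac`, via adaptive numeric integration.

    Used only as a verification oracle in tests: integrates the compartment
    ODEs plus a running integral of C_m, from which exact frame averages are
    differenced.
    """
    t_need = float(schedule.ends[-1]) + max(0.0, -p.t_d) + 1e-6
    tk, vk = inp.knots(t_need)
    ts, vs = _shift_knots(tk, vk, p.t_d, float(schedule.ends[-1]))

    def u(t):
        return np.interp(t, ts, vs)

    vb, k1, k2, k3, k4 = p.v_b, p.K_1, p.k_2, p.k_3, p.k_4

    def rhs(t, y):
        c1, c2, _ = y
        ut = u(t)
        dc1 = k1 * ut - (k2 + k3) * c1 + k4 * c2
        dc2 = k3 * c1 - k4 * c2
        cm = vb * ut + (1.0 - vb) * (c1 + c2)
        return [dc1, dc2, cm]

    t0 = float(schedule.starts[0])
    t_end = float(schedule.ends[-1])
    times = np.unique(np.concatenate([schedule.starts, schedule.ends]))
    sol = solve_ivp(
        rhs,
        (min(t0, 0.0), t_end),
        [0.0, 0.0, 0.0],
        method="LSODA",
        t_eval=times,
        rtol=1e-10,
        atol=1e-13,
        max_step=1.0,
    )
    if not sol.success:
        raise RuntimeError(f"ODE oracle failed: {sol.message}")
    S = dict(zip(sol.t, sol.y[2]))
    vals = np.array(
        [(S[e] - S[s]) / (e - s) for s, e in zip(schedule.starts, schedule.ends)]
    )
    return TimeActivityCurve(f"oracle[{p.model}]", schedule, vals, unit=inp.tac.unit)


def with_model(p: KineticParams, model: str) -> KineticParams:
    """Project parameters onto another model kind (zeroing absent rates)."""
    k3 = p.k_3 if model != "1T4P" else 0.0
    k4 = p.k_4 if model == "2T6P" else 0.0
    return replace(p, model=model, k_3=k3, k_4=k4)
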