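"""Macroparameters and graphical analysis.

Quantities derived from fitted microparameters or directly from curves:

- net influx rate      K_i   = K_1*k_3/(k_2+k_3)        (2-tissue models)
- volume of distribution V_T = K_1/k_2                   (1T)
                             = (K_1/k_2)*(1+k_3/k_4)     (reversible 2T)
- blood-volume-corrected V_T(v_b) = v_b + (1-v_b)*V_T,
  the exact equilibrium limit of the measured tissue-to-blood ratio under
  C_m = v_b*C_wb + (1-v_b)*C_t
- SUVR: per-frame tissue-to-whole-blood ratio, and duration-weighted window
  averages
- Logan plot: slope of int_0^t C_T / C_T(t) against int_0^t C_P / C_T(t)
  for frame midpoints after t* (default 30 min)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .compartment_models import KineticParams
from .input_function import InputFunction
from .tac_io import TimeActivityCurve

logger = logging.getLogger("petkin")

__all__ = [
    "MacroParams",
    "compute_ki",
    "compute_vt",
    "compute_vt_vb",
    "suvr_curve",
    "suvr_window",
    "logan",
]


@dataclass(frozen=True)
class MacroParams:
    region_label: str
    K_i: float | None
    V_T: float | None
    V_T_vb: float | None
    SUVR: float
    suvr_window: tuple[float, float]
    K_Logan: float
    logan_intercept: float
    t_star: float


def compute_ki(p: KineticParams) -> float:
    """Net influx rate K_1*k_3/(k_2+k_3) (2-tissue models only)."""
    if p.model == "1T4P":
        raise ValueError("K_i is undefined for the 1-tissue model")
    if p.k_2 + p.k_3 <= 0:
        raise ValueError("K_i requires k_2 + k_3 > 0")
    return p.K_1 * p.k_3 / (p.k_2 + p.k_3)


def compute_vt(p: KineticParams) -> float:
    """Total volume of distribution (reversible models only)."""
    if p.k_2 <= 0:
        raise ValueError("V_T requires k_2 > 0")
    if p.model == "1T4P":
        return p.K_1 / p.k_2
    if p.model == "2T5P" or p.k_4 <= 0:
        raise ValueError("V_T is undefined for the irreversible 2T5P model (k_4 = 0)")
    return (p.K_1 / p.k_2) * (1.0 + p.k_3 / p.k_4)


def compute_vt_vb(p: KineticParams) -> float:
    """Blood-volume-corrected V_T: v_b + (1-v_b)*V_T."""
    vt = compute_vt(p)
    return p.v_b + (1.0 - p.v_b) * vt


def _blood_frame_values(inp: InputFunction, schedule) -> np.ndarray:
    # on its own schedule the measured frame averages are exact
    if schedule == inp.tac.schedule and inp.delay == 0.0:
        return inp.tac.values
    return inp.frame_values(schedule)


def suvr_curve(tac: TimeActivityCurve, inp: InputFunction) -> np.ndarray:
    """Per-frame tissue-to-blood ratio; frames with zero blood are NaN."""
    cb = _blood_frame_values(inp, tac.schedule)
    out = np.full(tac.values.shape, np.nan)
    ok = cb != 0
    if not np.all(ok):
        logger.warning("SUVR: %d frame(s) with zero blood value excluded", (~ok).sum())
    out[ok] = tac.values[ok] / cb[ok]
    return out


def suvr_window(tac: TimeActivityCurve, inp: InputFunction, window: tuple[float, float]) -> float:
    """Window SUVR: ratio of duration-weighted mean tissue to mean blood
    activity over frames whose midpoints lie in ``window`` (minutes)."""
    sched = tac.schedule
    mid = sched.midpoints
    sel = (mid >= window[0]) & (mid <= window[1])
    if not np.any(sel):
        raise ValueError(f"no frame midpoints inside SUVR window {window}")
    cb = _blood_frame_values(inp, sched)
    dur = sched.durations[sel]
    num = np.sum(tac.values[sel] * dur) / np.sum(dur)
    den = np.sum(cb[sel] * dur) / np.sum(dur)
    if den == 0:
        raise ValueError("blood activity averages to zero inside the SUVR window")
    return float(num / den)


def logan(tac: TimeActivityCurve, inp: InputFunction, t_star: float) -> tuple[float, float]:
    """Logan graphical analysis: returns (K_Logan, intercept).

    Cumulative integrals use a zero-anchored trapezoid on frame midpoints
    (activity is zero at injection); the regression uses ordinary least
    squares over points with midpoint >= t*.
    """
    sched = tac.schedule
    mid = sched.midpoints
    ct = tac.values
    cp = _blood_frame_values(inp, sched)
    t = np.concatenate([[0.0], mid])
    int_ct = np.concatenate([[0.0], np.cumsum(np.diff(t) * 0.5 * (np.concatenate([[0.0], ct])[:-1] + np.concatenate([[0.0], ct])[1:]))])[1:]
    int_cp = np.concatenate([[0.0], np.cumsum(np.diff(t) * 0.5 * (np.concatenate([[0.0], cp])[:-1] + np.concatenate([[0.0], cp])[1:]))])[1:]
    sel = (mid >= t_star) & (ct > 0)
    if sel.sum() < 3:
        raise ValueError(
            f"Logan fit needs >= 3 usable frames with midpoint >= t*={t_star} min, "
            f"got {int(sel.sum())}"
        )
    x = int_cp[sel] / ct[sel]
    yv = int_ct[sel] / ct[sel]
    slope, intercept = np.polyfit(x, yv, 1)
    return float(slope), float(intercept)
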