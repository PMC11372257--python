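"""Nonlinear least-squares fitting of compartment models with AICc selection.

Each region's TAC is fitted by bound-constrained, multi-start weighted least
squares; the arrival delay t_d is estimated jointly (continuously, via the
interpolated input) unless fixed.  Model choice among 1T4P/2T5P/2T6P uses
the small-sample-corrected Akaike criterion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .compartment_models import (
    N_PARAMS,
    KineticParams,
    _frame_avg_from_knots,
)
from .input_function import InputFunction
from .tac_io import FrameSchedule, TimeActivityCurve

logger = logging.getLogger("petkin")

__all__ = ["FitOptions", "KineticFit", "fit_model", "fit_all_models", "aicc", "select_model"]


@dataclass
class FitOptions:
    """Fitting controls.

    weights: ``None`` (uniform, default) or ``"framevar"`` for
        w_i = dt_i / max(C_i, eps) — the inverse of the count-statistics
        frame-variance model.
    fixed_delay: fix t_d to this value (min) instead of fitting it.
    extra_starts: additional start vectors (in the free-parameter layout),
        e.g. the ground truth during identifiability refits.
    """

    weights: Optional[str] = None
    seed: int = 0
    n_starts: int = 10
    max_nfev: int = 400
    delay_bound: float = 1.0
    k1_max: float = 5.0
    rate_max: float = 5.0
    fixed_delay: Optional[float] = None
    extra_starts: Sequence[Sequence[float]] = field(default_factory=tuple)
    rss_early_stop: Optional[float] = None  # stop multi-start below this RSS
    delay_grid: Optional[int] = None  # fallback: fit t_d on a fixed grid instead


@dataclass
class KineticFit:
    params: KineticParams
    rss: float
    n_frames: int
    k_params: int
    aicc: float
    converged: bool
    n_restarts: int
    fixed_delay: bool
    at_bounds: tuple[str, ...] = ()


def aicc(rss: float, n: int, k: int) -> float:
    """Akaike information criterion with small-sample correction:
    n*ln(rss/n) + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    if rss <= 0:
        raise ValueError("rss must be > 0")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _bounds(model: str, opts: FitOptions) -> tuple[np.ndarray, np.ndarray]:
    lo = [0.0, 0.0, 0.0]
    hi = [1.0, opts.k1_max, opts.rate_max]
    if model in ("2T5P", "2T6P"):
        lo.append(0.0)
        hi.append(opts.rate_max)
    if model == "2T6P":
        lo.append(0.0)
        hi.append(opts.rate_max)
    if opts.fixed_delay is None:
        lo.append(-opts.delay_bound)
        hi.append(opts.delay_bound)
    return np.array(lo), np.array(hi)


def _default_start(model: str, opts: FitOptions) -> np.ndarray:
    x = [0.05, 0.3, 0.3]
    if model in ("2T5P", "2T6P"):
        x.append(0.05)
    if model == "2T6P":
        x.append(0.02)
    if opts.fixed_delay is None:
        x.append(0.0)
    return np.array(x)


def fit_model(
    tac: TimeActivityCurve,
    inp: InputFunction,
    model_kind: str,
    options: Optional[FitOptions] = None,
) -> KineticFit:
    """Fit one model kind to one TAC; deterministic given the seed.

    With ``options.delay_grid`` set, t_d is not fitted continuously;
    instead that many equispaced delays across the delay bound are each
    fitted with t_d fixed and the lowest-RSS fit wins (a robust fallback
    when the continuous delay estimate is unstable).  AICc still counts
    t_d as estimated.
    """
    opts = options or FitOptions()
    if opts.delay_grid is not None and opts.fixed_delay is None:
        import dataclasses

        best = None
        for td in np.linspace(-opts.delay_bound, opts.delay_bound, opts.delay_grid):
            sub = dataclasses.replace(opts, delay_grid=None, fixed_delay=float(td))
            fit = fit_model(tac, inp, model_kind, sub)
            if best is None or fit.rss < best.rss:
                best = fit
        k = N_PARAMS[model_kind]  # the grid-searched delay counts as fitted
        return dataclasses.replace(
            best, k_params=k, aicc=aicc(max(best.rss, 1e-300), best.n_frames, k),
            fixed_delay=False,
        )
    if model_kind not in N_PARAMS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    sched = tac.schedule
    y = tac.values
    n = sched.n_frames

    if opts.weights is None:
        w = np.ones(n)
    elif opts.weights == "framevar":
        w = sched.durations / np.clip(np.abs(y), np.max(np.abs(y)) * 1e-3, None)
    else:
        raise ValueError(f"unknown weighting scheme {opts.weights!r}")
    sw = np.sqrt(w)

    # input knots covering the schedule for every admissible delay
    t_need = float(sched.ends[-1]) + opts.delay_bound + 1e-6
    tk, vk = inp.knots(t_need)

    fixed = opts.fixed_delay

    def residuals(x):
        p = KineticParams.from_vector(model_kind, x, fixed_delay=fixed)
        return sw * (_frame_avg_from_knots(tk, vk, p, sched) - y)

    lo, hi = _bounds(model_kind, opts)
    d = lo.size
    starts = [_default_start(model_kind, opts)]
    for s in opts.extra_starts:
        starts.append(np.clip(np.asarray(s, float), lo, hi))
    if opts.n_starts > len(starts):
        sampler = qmc.Sobol(d, scramble=True, seed=opts.seed)
        n_extra = opts.n_starts - len(starts)
        extra = sampler.random(int(2 ** np.ceil(np.log2(n_extra))))[:n_extra]
        starts.extend(lo + extra * (hi - lo))

    best = None
    tried = 0
    for x0 in starts:
        tried += 1
        try:
            res = least_squares(
                residuals,
                np.clip(x0, lo, hi),
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=opts.max_nfev,
            )
        except Exception as e:  # pragma: no cover
            logger.debug("start failed: %s", e)
            continue
        if best is None or res.cost < best.cost:
            best = res
        if opts.rss_early_stop is not None and 2 * best.cost < opts.rss_early_stop:
            break
    if best is None:
        raise RuntimeError(
            f"all {tried} starts failed for model {model_kind} on "
            f"'{tac.region_label}'"
        )

    params = KineticParams.from_vector(model_kind, best.x, fixed_delay=fixed)
    rss = float(2 * best.cost)
    k = N_PARAMS[model_kind] - (1 if fixed is not None else 0)
    names = ["v_b", "K_1", "k_2"]
    if model_kind in ("2T5P", "2T6P"):
        names.append("k_3")
    if model_kind == "2T6P":
        names.append("k_4")
    if fixed is None:
        names.append("t_d")
    tol = 1e-9 * np.maximum(1.0, np.abs(hi))
    pinned = tuple(
        nm
        for nm, xi, l, h, t in zip(names, best.x, lo, hi, tol)
        if (xi - l < t or h - xi < t) and not (nm in ("k_3", "k_4") and xi - l < t)
    )
    if pinned:
        logger.info("fit of '%s' (%s) pinned at bounds: %s", tac.region_label, model_kind, pinned)
    return KineticFit(
        params=params,
        rss=rss,
        n_frames=n,
        k_params=k,
        aicc=aicc(max(rss, 1e-300), n, k),
        converged=bool(best.success),
        n_restarts=tried,
        fixed_delay=fixed is not None,
        at_bounds=pinned,
    )


def fit_all_models(
    tac: TimeActivityCurve,
    inp: InputFunction,
    options: Optional[FitOptions] = None,
) -> list[KineticFit]:
    """Fit 1T4P, 2T5P and 2T6P to one TAC (in that order)."""
    return [fit_model(tac, inp, m, options) for m in ("1T4P", "2T5P", "2T6P")]


def select_model(fits: Sequence[KineticFit]) -> KineticFit:
    """Pick the fit with the strictly lowest AICc; ties (within 1e-9) go to
    the model with fewer parameters."""
    if len(fits) < 2:
        raise ValueError("model selection needs >= 2 fits")
    kinds = {f.params.model for f in fits}
    if len(kinds) != len(fits):
        raise ValueError("fits must be of distinct model kinds")
    ranked = sorted(fits, key=lambda f: (f.aicc, f.k_params))
    best, runner = ranked[0], ranked[1]
    if abs(best.aicc - runner.aicc) < 1e-9:
        logger.info("AICc tie between %s and %s; choosing fewer parameters",
                    best.params.model, runner.params.model)
        best = min((best, runner), key=lambda f: f.k_params)
    deltas = {f.params.model: f.aicc - best.aicc for f in fits}
    logger.debug("dAICc: %s", deltas)
    return best
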