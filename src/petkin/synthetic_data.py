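"""Synthetic dynamic-PET study generator with known ground truth.

Emulates the statistical structure of a 90-min total-body dynamic study:
two blood-pool inputs (aorta, right ventricle), ~15 organ regions, 7 tumor
subregions, 4 mediastinal lymph nodes plus axillary/pelvic nodes, and a
paired pre/post-therapy patient in which treatment raises tracer trapping
(k_3) and lowers dephosphorylation-driven efflux (k_4) in the tumor.

Noise model: independent Gaussian per frame with

    sigma_i = noise_scale * sqrt(Cbar_i * exp(lam_decay*t_i) / dt_i),

the count-statistics variance of decay-corrected framed PET data
(lam_decay = ln2 / 109.77 min for 18F; t_i the frame midpoint).  A region's
``noise_scale`` defaults to ``base_noise_frac * sqrt(Cbar_late)`` so that the
late-frame fractional noise is uptake-independent, emulating the
VOI-averaging of organ segmentations; ``BASE_NOISE_FRAC`` is calibrated so
the tumor-like region's V_T estimate has ~5% Monte-Carlo SD over 90 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .compartment_models import KineticParams, model_tac
from .input_function import InputFunction, fit_biexp_tail
from .macro_analysis import compute_vt, compute_vt_vb
from .tac_io import (
    AORTA,
    RIGHT_VENTRICLE,
    FrameSchedule,
    ScanRecord,
    TimeActivityCurve,
)

F18_DECAY_LAMBDA = np.log(2.0) / 109.77  # 1/min

#: late-frame fractional noise anchor (see module docstring; calibrated so
#: tumor V_T SD% over 100 noisy refits of the default 90-min study is ~5%)
BASE_NOISE_FRAC = 0.045


# ---------------------------------------------------------------------------
# blood input

@dataclass(frozen=True)
class InputShape:
    """Gamma-variate bolus + biexponential washout, all in SUV units.

    The bolus peaks ``t_peak`` min after onset ``t0``; the washout rises on a
    ``t_rise`` time constant and decays with a fast distribution component
    and a slow biologic component.
    """

    bolus_amp: float = 40.0
    t0: float = 0.15          # injection-to-aorta arrival, min
    t_peak: float = 0.25      # bolus time-to-peak after onset, min
    gamma: float = 3.0
    A1: float = 4.0
    lam1: float = 0.25        # fast distribution, t1/2 ~ 2.8 min
    A2: float = 0.8
    lam2: float = 0.0002      # slow biologic washout, t1/2 ~ 58 h
    t_rise: float = 0.3

    def __post_init__(self):
        for name in ("bolus_amp", "t_peak", "gamma", "A1", "lam1", "A2", "lam2", "t_rise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 for a physiologic input")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        ts = t - self.t0
        pos = ts > 0
        x = np.where(pos, ts / self.t_peak, 0.0)
        bolus = self.bolus_amp * x**self.gamma * np.exp(self.gamma * (1.0 - x))
        wash = (self.A1 * np.exp(-self.lam1 * np.where(pos, ts, 0.0))
                + self.A2 * np.exp(-self.lam2 * np.where(pos, ts, 0.0)))
        wash = wash * -np.expm1(-np.where(pos, ts, 0.0) / self.t_rise)
        out = np.where(pos, bolus + wash, 0.0)
        return out if t.ndim else float(out)


AORTA_SHAPE = InputShape()
#: right ventricle sees the bolus earlier and slightly less dispersed
RV_SHAPE = InputShape(bolus_amp=44.0, t0=0.08, t_peak=0.22)


def generate_input(
    shape: InputShape,
    schedule: FrameSchedule,
    seed: int = 0,
    label: str = AORTA,
    fit_tail: bool = True,
    biexp_window: tuple[float, float] = (14.0, 90.0),
) -> InputFunction:
    """Sample the continuous shape to frame averages and wrap it.

    The generated input is noiseless; its washout tail is refitted from the
    frame data (exactly the pipeline's own extrapolation path) so the result
    is usable beyond the scan end.
    """
    vals = np.empty(schedule.n_frames)
    for i, (s, e) in enumerate(zip(schedule.starts, schedule.ends)):
        ts = np.linspace(s, e, 65)
        vals[i] = np.trapezoid(shape(ts), ts) / (e - s)
    if np.any(vals[schedule.midpoints > shape.t0] <= 0):
        raise ValueError("input shape produced non-positive post-onset values")
    tac = TimeActivityCurve(label, schedule, vals, unit="SUV")
    inp = InputFunction(tac)
    if fit_tail:
        inp = replace(inp, tail=fit_biexp_tail(inp, biexp_window))
    return inp


# ---------------------------------------------------------------------------
# regions

@dataclass(frozen=True)
class RegionSpec:
    """Ground truth for one region: kinetics, blood supply, noise level."""

    label: str
    params: KineticParams
    input_label: str = AORTA
    noise_scale: Optional[float] = None  # None -> auto from late uptake

    def __post_init__(self):
        if self.input_label not in (AORTA, RIGHT_VENTRICLE):
            raise ValueError(f"unknown input label {self.input_label!r}")


def _p2t(v_b, K_1, k_2, k_3, k_4, t_d) -> KineticParams:
    return KineticParams("2T6P", v_b, K_1, k_2, k_3, k_4, t_d)


#: organ-like, node-like and tumor-like presets (synthetic — chosen to span
#: low/high blood volume, low/high uptake, and 1T- vs 2T-favored kinetics)
ORGAN_PRESETS: dict[str, RegionSpec] = {
    "cerebrum": RegionSpec("cerebrum", _p2t(0.04, 0.03, 0.20, 0.03, 0.025, 0.20)),
    "choroid_plexus": RegionSpec("choroid_plexus", _p2t(0.15, 0.35, 0.30, 0.08, 0.022, 0.15)),
    "pituitary": RegionSpec("pituitary", _p2t(0.10, 0.35, 0.30, 0.07, 0.022, 0.15)),
    "salivary_glands": RegionSpec("salivary_glands", _p2t(0.06, 0.30, 0.25, 0.10, 0.024, 0.15)),
    "thyroid": RegionSpec("thyroid", _p2t(0.08, 0.40, 0.35, 0.12, 0.024, 0.15)),
    "bone_marrow": RegionSpec("bone_marrow", _p2t(0.06, 0.25, 0.20, 0.10, 0.026, 0.20)),
    "lungs": RegionSpec("lungs", _p2t(0.15, 0.12, 0.30, 0.04, 0.025, 0.05), RIGHT_VENTRICLE),
    "myocardium_lv": RegionSpec("myocardium_lv", _p2t(0.30, 0.60, 0.40, 0.06, 0.02, 0.10)),
    "myocardium_rv": RegionSpec(
        "myocardium_rv", KineticParams("1T4P", 0.50, 0.50, 0.40, 0.0, 0.0, 0.05)
    ),
    "spleen": RegionSpec("spleen", _p2t(0.20, 0.80, 0.50, 0.10, 0.021, 0.20)),
    "liver": RegionSpec("liver", _p2t(0.25, 0.90, 0.60, 0.08, 0.021, 0.30)),
    "kidneys": RegionSpec("kidneys", _p2t(0.20, 0.70, 0.40, 0.15, 0.02, 0.20)),
    "muscle": RegionSpec("muscle", _p2t(0.03, 0.06, 0.15, 0.05, 0.023, 0.40)),
    "axillary_ln": RegionSpec("axillary_ln", _p2t(0.03, 0.30, 0.35, 0.15, 0.02, 0.25)),
    "pelvic_ln": RegionSpec("pelvic_ln", _p2t(0.03, 0.25, 0.30, 0.12, 0.02, 0.30)),
}

#: tumor-like preset (lung primary: RV blood supply)
TUMOR_PRESET = RegionSpec("tumor", _p2t(0.05, 0.40, 0.30, 0.06, 0.022, 0.10), RIGHT_VENTRICLE)
#: mediastinal-node-like preset
MEDIASTINAL_PRESET = RegionSpec("mediastinal_ln", _p2t(0.04, 0.35, 0.35, 0.14, 0.021, 0.15))

#: region panel for the Monte-Carlo identifiability study: spans low/high
#: blood volume, low/high uptake, both blood inputs, and 1T/2T kinetics
IDENTIFIABILITY_PANEL: tuple[str, ...] = (
    "tumor",
    "mediastinal_ln",
    "thyroid",
    "spleen",
    "liver",
    "kidneys",
    "bone_marrow",
    "choroid_plexus",
    "myocardium_lv",
    "myocardium_rv",
)


def preset_for(label: str) -> RegionSpec:
    """Look up a preset by label (organs, tumor, mediastinal node)."""
    if label == "tumor":
        return TUMOR_PRESET
    if label == "mediastinal_ln":
        return MEDIASTINAL_PRESET
    return ORGAN_PRESETS[label]


def input_for_region(label: str) -> str:
    """Lung tissue and lung-tumor subregions are supplied by the pulmonary
    artery (right ventricle); every other region uses the aorta."""
    return RIGHT_VENTRICLE if label.startswith(("lungs", "tumor")) else AORTA


def noise_sigma(noise_scale: float, model_values: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Per-frame Gaussian SD of the decay-corrected count-statistics model."""
    decay = np.exp(F18_DECAY_LAMBDA * schedule.midpoints)
    return noise_scale * np.sqrt(np.clip(model_values, 0.0, None) * decay / schedule.durations)


def auto_noise_scale(model_values: np.ndarray, schedule: FrameSchedule,
                     base_frac: float = BASE_NOISE_FRAC) -> float:
    """Uptake-matched noise scale: base_frac * sqrt(late-window mean)."""
    mid = schedule.midpoints
    sel = mid >= min(60.0, 0.66 * schedule.duration)
    late = float(np.sum(model_values[sel] * schedule.durations[sel])
                 / np.sum(schedule.durations[sel]))
    return base_frac * np.sqrt(max(late, 1e-6))


def generate_region_tac(
    spec: RegionSpec,
    inp: InputFunction,
    schedule: FrameSchedule,
    seed: int = 0,
) -> TimeActivityCurve:
    """Forward-model TAC for one region plus one noise draw (seeded)."""
    clean = model_tac(spec.params, inp, schedule)
    scale = spec.noise_scale
    if scale is None:
        scale = auto_noise_scale(clean.values, schedule)
    if scale == 0.0:
        vals = clean.values
    else:
        rng = np.random.default_rng(seed)
        sigma = noise_sigma(scale, clean.values, schedule)
        vals = clean.values + rng.normal(0.0, 1.0, schedule.n_frames) * sigma
    return TimeActivityCurve(spec.label, schedule, vals, unit=inp.tac.unit)


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Study layout: healthy controls plus one pre/post-therapy patient.

    Therapy multiplies tumor-subregion k_3 by (1+delta_k3) and k_4 by
    (1-delta_k4); enlarged vs non-enlarged mediastinal nodes get
    opposite-signed V_T shifts.
    """

    n_healthy: int = 4
    with_patient: bool = True
    n_tumor_subregions: int = 7
    n_mediastinal_ln: int = 4
    n_enlarged_ln: int = 2
    n_axillary: int = 3
    n_pelvic: int = 3
    delta_k3: float = 0.5
    delta_k4: float = 0.3
    jitter_cv: float = 0.15        # between-subject lognormal CV on kinetics
    subregion_cv: float = 0.20     # within-tumor heterogeneity
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_healthy < 1 or self.n_tumor_subregions < 1 or self.n_mediastinal_ln < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 <= self.delta_k4 < 1.0):
            raise ValueError("delta_k4 must be in [0, 1)")
        if self.delta_k3 < 0:
            raise ValueError("delta_k3 must be >= 0")
        if self.n_enlarged_ln > self.n_mediastinal_ln:
            raise ValueError("n_enlarged_ln cannot exceed n_mediastinal_ln")


def _jitter_params(p: KineticParams, rng: np.random.Generator, cv: float) -> KineticParams:
    """Lognormal multiplicative jitter on v_b and the rate constants."""
    if cv <= 0:
        return p
    sig = np.sqrt(np.log1p(cv**2))
    mu = -0.5 * sig**2  # unit-mean lognormal
    f = rng.lognormal(mu, sig, 5)
    return replace(
        p,
        v_b=float(min(p.v_b * f[0], 0.95)),
        K_1=float(p.K_1 * f[1]),
        k_2=float(p.k_2 * f[2]),
        k_3=float(p.k_3 * f[3] if p.k_3 > 0 else 0.0),
        k_4=float(p.k_4 * f[4] if p.k_4 > 0 else 0.0),
    )


def _apply_therapy(p: KineticParams, delta_k3: float, delta_k4: float) -> KineticParams:
    return replace(p, k_3=p.k_3 * (1.0 + delta_k3), k_4=p.k_4 * (1.0 - delta_k4))


def _patient_region_specs(cohort: CohortSpec, rng: np.random.Generator) -> list[RegionSpec]:
    specs = [replace(s, label=lbl) for lbl, s in ORGAN_PRESETS.items()]
    # individual axillary/pelvic nodes (beyond the organ-level node sets)
    for i in range(cohort.n_axillary):
        specs.append(replace(ORGAN_PRESETS["axillary_ln"], label=f"axillary_ln_{i + 1}"))
    for i in range(cohort.n_pelvic):
        specs.append(replace(ORGAN_PRESETS["pelvic_ln"], label=f"pelvic_ln_{i + 1}"))
    for i in range(cohort.n_tumor_subregions):
        p = _jitter_params(TUMOR_PRESET.params, rng, cohort.subregion_cv)
        specs.append(replace(TUMOR_PRESET, label=f"tumor_sub_{i + 1}", params=p))
    for i in range(cohort.n_mediastinal_ln):
        p = _jitter_params(MEDIASTINAL_PRESET.params, rng, cohort.subregion_cv)
        if i < cohort.n_enlarged_ln:  # enlarged nodes start hotter
            p = replace(p, k_3=p.k_3 * 1.4)
        specs.append(replace(MEDIASTINAL_PRESET, label=f"mediastinal_ln_{i + 1}", params=p))
    return specs


def _make_scan(
    subject_id: str,
    scan_id: str,
    specs: list[RegionSpec],
    inputs: dict[str, InputFunction],
    schedule: FrameSchedule,
    rng: np.random.Generator,
    noiseless: bool,
) -> tuple[ScanRecord, list[dict]]:
    tacs = {
        AORTA: inputs[AORTA].tac,
        RIGHT_VENTRICLE: inputs[RIGHT_VENTRICLE].tac,
    }
    truth_rows = []
    for spec in specs:
        if noiseless:
            spec = replace(spec, noise_scale=0.0)
        seed = int(rng.integers(0, 2**31 - 1))
        tacs[spec.label] = generate_region_tac(spec, inputs[spec.input_label], schedule, seed)
        p = spec.params
        row = {
            "subject": subject_id,
            "scan": scan_id,
            "region": spec.label,
            "model": p.model,
            "input": spec.input_label,
            "v_b": p.v_b,
            "K_1": p.K_1,
            "k_2": p.k_2,
            "k_3": p.k_3,
            "k_4": p.k_4,
            "t_d": p.t_d,
        }
        try:
            row["V_T"] = compute_vt(p)
            row["V_T_vb"] = compute_vt_vb(p)
        except ValueError:
            row["V_T"] = np.nan
            row["V_T_vb"] = np.nan
        truth_rows.append(row)
    return ScanRecord(subject_id, scan_id, tacs), truth_rows


def generate_cohort(
    cohort: CohortSpec,
    schedule: FrameSchedule,
) -> tuple[list[ScanRecord], pd.DataFrame]:
    """Generate all scans of the study plus the ground-truth table.

    Pure function of (cohort, schedule): every random stream is derived from
    ``cohort.seed``.
    """
    master = np.random.default_rng(cohort.seed)
    inputs = {
        AORTA: generate_input(AORTA_SHAPE, schedule, label=AORTA),
        RIGHT_VENTRICLE: generate_input(RV_SHAPE, schedule, label=RIGHT_VENTRICLE),
    }
    scans: list[ScanRecord] = []
    rows: list[dict] = []

    for i in range(cohort.n_healthy):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        specs = [
            replace(s, label=lbl, params=_jitter_params(s.params, rng, cohort.jitter_cv))
            for lbl, s in ORGAN_PRESETS.items()
        ]
        scan, tr = _make_scan(f"healthy_{i + 1}", "scan", specs, inputs, schedule, rng, cohort.noiseless)
        scans.append(scan)
        rows.extend(tr)

    if cohort.with_patient:
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        pre_specs = _patient_region_specs(cohort, rng)
        post_specs = []
        for spec in pre_specs:
            p = spec.params
            if spec.label.startswith("tumor_sub_"):
                p = _apply_therapy(p, cohort.delta_k3, cohort.delta_k4)
            elif spec.label.startswith("mediastinal_ln_"):
                idx = int(spec.label.rsplit("_", 1)[1]) - 1
                if idx < cohort.n_enlarged_ln:  # involved nodes: V_T decreases
                    p = replace(p, k_3=p.k_3 / (1.0 + cohort.delta_k3),
                                k_4=p.k_4 / (1.0 - cohort.delta_k4))
                else:                           # uninvolved nodes: V_T increases
                    p = _apply_therapy(p, cohort.delta_k3, cohort.delta_k4)
            post_specs.append(replace(spec, params=p))
        scan, tr = _make_scan("patient", "pre", pre_specs, inputs, schedule, rng, cohort.noiseless)
        scans.append(scan)
        rows.extend(tr)
        scan, tr = _make_scan("patient", "post", post_specs, inputs, schedule, rng, cohort.noiseless)
        scans.append(scan)
        rows.extend(tr)

    return scans, pd.DataFrame(rows)
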