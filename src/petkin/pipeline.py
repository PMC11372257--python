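"""End-to-end analysis stages shared by the CLI and the analysis scripts.

Stages mirror the study: simulate (or load) a cohort of scans, prepare the
blood inputs (tail fit + extrapolation), fit the three compartment models
per region with AICc selection, derive macroparameters, and run the group
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from .input_function import InputFunction, fit_biexp_tail
from .macro_analysis import compute_ki, compute_vt, compute_vt_vb, logan, suvr_window
from .model_fitting import FitOptions, fit_all_models, select_model
from .group_stats import surrogacy_analysis, wilcoxon_exact
from .synthetic_data import input_for_region
from .tac_io import AORTA, RIGHT_VENTRICLE, RunConfig, ScanRecord

logger = logging.getLogger("petkin")


def prepare_inputs(scan: ScanRecord, config: RunConfig) -> dict[str, InputFunction]:
    """Wrap both blood TACs as input functions with fitted washout tails."""
    out = {}
    for label in (AORTA, RIGHT_VENTRICLE):
        inp = InputFunction(scan.tacs[label])
        inp = replace(inp, tail=fit_biexp_tail(inp, config.biexp_window_min))
        out[label] = inp
    return out


def fit_scan(
    scan: ScanRecord,
    config: Optional[RunConfig] = None,
    options: Optional[FitOptions] = None,
    regions: Optional[list[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit all tissue regions of one scan; returns (fit table, macro table).

    Lung-supplied regions (``lungs*``, ``tumor*``) are fitted against the
    right-ventricle input, everything else against the aorta.  Per-region
    failures are recorded and the run continues.
    """
    config = config or RunConfig()
    options = options or FitOptions(delay_bound=config.delay_bound_min)
    inputs = prepare_inputs(scan, config)
    fit_rows: list[dict] = []
    macro_rows: list[dict] = []
    for label in regions if regions is not None else scan.tissue_labels:
        tac = scan.tacs[label]
        inp = inputs[input_for_region(label)]
        try:
            fits = fit_all_models(tac, inp, options)
            best = select_model(fits)
        except Exception as e:
            logger.error("region '%s' failed to fit: %s", label, e)
            fit_rows.append({"subject": scan.subject_id, "scan": scan.scan_id,
                             "region": label, "error": str(e)})
            continue
        for f in fits:
            p = f.params
            fit_rows.append({
                "subject": scan.subject_id, "scan": scan.scan_id, "region": label,
                "model": p.model, "selected": f is best,
                "v_b": p.v_b, "K_1": p.K_1, "k_2": p.k_2, "k_3": p.k_3,
                "k_4": p.k_4, "t_d": p.t_d, "rss": f.rss, "aicc": f.aicc,
                "converged": f.converged, "at_bounds": ",".join(f.at_bounds),
            })
        row = {"subject": scan.subject_id, "scan": scan.scan_id, "region": label,
               "selected_model": best.params.model}
        mid = tac.schedule.midpoints
        sel = (mid >= config.suvr_window_min[0]) & (mid <= config.suvr_window_min[1])
        dur = tac.schedule.durations[sel]
        row["SUV"] = float(np.sum(tac.values[sel] * dur) / np.sum(dur))
        row["SUVR"] = suvr_window(tac, inp, config.suvr_window_min)
        try:
            k_logan, icpt = logan(tac, inp, config.t_star_min)
        except ValueError as e:
            logger.warning("Logan failed for '%s': %s", label, e)
            k_logan, icpt = np.nan, np.nan
        row["K_Logan"] = k_logan
        row["logan_intercept"] = icpt
        row["t_star"] = config.t_star_min
        by_kind = {f.params.model: f for f in fits}
        row["Ki_2T6P"] = compute_ki(by_kind["2T6P"].params) if by_kind["2T6P"].params.k_2 + by_kind["2T6P"].params.k_3 > 0 else np.nan
        row["Ki_2T5P"] = compute_ki(by_kind["2T5P"].params) if by_kind["2T5P"].params.k_2 + by_kind["2T5P"].params.k_3 > 0 else np.nan
        p6 = by_kind["2T6P"].params
        try:
            row["V_T"] = compute_vt(p6)
            row["V_T_vb"] = compute_vt_vb(p6)
        except ValueError:
            row["V_T"] = np.nan
            row["V_T_vb"] = np.nan
        macro_rows.append(row)
    return pd.DataFrame(fit_rows), pd.DataFrame(macro_rows)


def paired_prepost_tests(
    macro_pre: pd.DataFrame,
    macro_post: pd.DataFrame,
    fit_pre: Optional[pd.DataFrame] = None,
    fit_post: Optional[pd.DataFrame] = None,
    region_prefix: str = "tumor_sub_",
) -> pd.DataFrame:
    """Exact Wilcoxon tests of post-minus-pre changes over matched regions.

    Tests SUV, SUVR, K_Logan, V_T from the macro tables and (when the fit
    tables are given) the selected-model rate constants k_3 and k_4.
    """
    pre = macro_pre[macro_pre.region.str.startswith(region_prefix)].set_index("region")
    post = macro_post[macro_post.region.str.startswith(region_prefix)].set_index("region")
    unmatched = sorted(set(pre.index) ^ set(post.index))
    if unmatched:
        raise ValueError(f"unmatched region labels between scans: {unmatched}")
    rows = []
    for col in ("SUV", "SUVR", "K_Logan", "V_T"):
        d = (post[col] - pre.loc[post.index, col]).dropna().values
        r = wilcoxon_exact(d)
        rows.append({"measure": col, "n": r.n, "statistic": r.statistic, "p": r.p,
                     "median_change": float(np.median(d))})
    if fit_pre is not None and fit_post is not None:
        fp = fit_pre[(fit_pre.region.str.startswith(region_prefix)) & (fit_pre.selected)].set_index("region")
        fq = fit_post[(fit_post.region.str.startswith(region_prefix)) & (fit_post.selected)].set_index("region")
        common = sorted(set(fp.index) & set(fq.index))
        for col in ("K_1", "k_2", "k_3", "k_4"):
            d = (fq.loc[common, col] - fp.loc[common, col]).dropna().values
            r = wilcoxon_exact(d)
            rows.append({"measure": col, "n": r.n, "statistic": r.statistic, "p": r.p,
                         "median_change": float(np.median(d))})
    return pd.DataFrame(rows)


def surrogacy_table(macro: pd.DataFrame) -> pd.DataFrame:
    """Surrogacy Spearman pair set as a tidy frame."""
    res = surrogacy_analysis(macro)
    return pd.DataFrame(
        [{"pair": r.label, "rho": r.rho, "p": r.p, "n": r.n} for r in res]
    )
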