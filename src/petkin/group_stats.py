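"""Group statistics: Spearman rank correlations and the exact paired
Wilcoxon signed-rank test.

Small samples dominate this kind of pilot study (e.g. 7 tumor subregions),
so the signed-rank test uses the full enumeration of the 2^n sign-flip null
— the printed p-values of such analyses (0.016 for 7/7 concordant changes)
are exactly these enumeration values.  No multiple-comparison correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

__all__ = [
    "SurrogacyResult",
    "PairedTestResult",
    "spearman",
    "wilcoxon_exact",
    "surrogacy_analysis",
    "SURROGACY_PAIRS",
]


@dataclass(frozen=True)
class SurrogacyResult:
    label: str
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    n: int
    statistic: float  # smaller signed-rank sum
    p: float


from functools import lru_cache


@lru_cache(maxsize=4)
def _perm_indices(n: int) -> np.ndarray:
    """All n! permutation index vectors (exact null; n <= 9)."""
    return np.array(list(permutations(range(n))), dtype=np.intp)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(x: Sequence[float], y: Sequence[float], label: str = "") -> SurrogacyResult:
    """Spearman rank correlation (midranks for ties).

    Two-sided p comes from the exact permutation null for n <= 9 and from
    the t approximation rho*sqrt((n-2)/(1-rho^2)) ~ t_{n-2} otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("spearman needs two equal-length 1-d samples, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman is undefined for a constant sample")
    n = x.size
    rx = rankdata(x)
    ry = rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= 9:
        perms = _perm_indices(n)
        ryc = ry - ry.mean()
        rxc = rx - rx.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        rho_all = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
    else:
        r = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return SurrogacyResult(label, rho, min(p, 1.0), n)


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of the positive-rank-sum over all 2^n sign assignments, on a
    doubled-rank integer grid (midranks are multiples of 1/2)."""
    total = int(round(ranks2.sum()))
    dp = np.zeros(total + 1)
    dp[0] = 1.0
    for r in ranks2:
        r = int(round(r))
        new = dp.copy()
        new[r:] += dp[: total + 1 - r]
        dp = new
    return dp


def wilcoxon_exact(differences: Sequence[float]) -> PairedTestResult:
    """Exact two-sided paired Wilcoxon signed-rank test (n <= 20 after
    dropping zero differences; midranks for tied magnitudes).

    p = P(W+ <= w) + P(W+ >= n(n+1)/2 - w) under the uniform sign-flip
    null, with w the smaller signed-rank sum, by full enumeration.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 1:
        raise ValueError("all differences are zero; the test is undefined")
    if n > 20:
        raise ValueError(f"exact enumeration supports n <= 20, got {n}")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    m = n * (n + 1) / 2.0
    w = min(w_pos, m - w_pos)

    ranks2 = np.round(2 * ranks).astype(int)
    dist = _signed_rank_distribution(ranks2)
    total2 = int(round(2 * m))
    w2 = 2 * w
    lo = float(dist[: int(math.floor(w2 + 1e-9)) + 1].sum())
    hi = float(dist[int(math.ceil(total2 - w2 - 1e-9)):].sum())
    p = (lo + hi) / 2.0**n
    return PairedTestResult(n=n, statistic=w, p=min(p, 1.0))


#: the surrogacy pair set: (column_x, column_y, label)
SURROGACY_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("SUV", "V_T", "SUV vs V_T"),
    ("SUVR", "V_T", "SUVR vs V_T"),
    ("SUVR", "V_T_vb", "SUVR vs V_T(v_b)"),
    ("K_Logan", "V_T", "K_Logan vs V_T"),
    ("K_Logan", "V_T_vb", "K_Logan vs V_T(v_b)"),
    ("Ki_2T6P", "SUVR", "K_i(2T6P) vs SUVR"),
    ("Ki_2T5P", "SUVR", "K_i(2T5P) vs SUVR"),
)


def surrogacy_analysis(macro_table: pd.DataFrame) -> list[SurrogacyResult]:
    """Spearman correlations of the uptake measures against V_T / V_T(v_b)
    over regions (the fixed 7-pair set)."""
    needed = {c for pair in SURROGACY_PAIRS for c in pair[:2]}
    missing = sorted(needed - set(macro_table.columns))
    if missing:
        raise KeyError(f"macro table is missing column(s) {missing}")
    out = []
    for cx, cy, label in SURROGACY_PAIRS:
        sub = macro_table[[cx, cy]].dropna()
        out.append(spearman(sub[cx].values, sub[cy].values, label=label))
    return out
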