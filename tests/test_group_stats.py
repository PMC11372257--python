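"""Exact signed-rank and Spearman statistics against brute-force oracles."""

from itertools import permutations, product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from petkin.group_stats import (
    SURROGACY_PAIRS,
    spearman,
    surrogacy_analysis,
    wilcoxon_exact,
)


def _wilcoxon_brute_force(d):
    """Independent oracle: enumerate all 2^n sign assignments directly."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    m = n * (n + 1) / 2
    w = min(w_pos, m - w_pos)
    count = 0
    for signs in product([0, 1], repeat=n):
        wp = sum(r for s, r in zip(signs, ranks) if s)
        if wp <= w + 1e-9 or wp >= m - w - 1e-9:
            count += 1
    return w, count / 2.0**n


class TestWilcoxonExact:
    def test_seven_concordant_changes(self):
        """All 7 paired differences in one direction: p = 2/2^7 = 0.015625,
        printed as 0.016."""
        r = wilcoxon_exact([0.3, 1.2, 0.7, 2.0, 0.1, 0.9, 0.5])
        assert r.n == 7
        assert r.statistic == 0
        assert r.p == 0.015625
        assert round(r.p, 3) == 0.016

    def test_seven_pairs_rank_sum_two(self):
        """One discordant pair carrying rank 2: p = 6/128 = 0.046875 -> 0.047."""
        r = wilcoxon_exact([1.0, -1.5, 3.0, 4.0, 5.0, 6.0, 7.0])
        assert r.statistic == 2
        assert r.p == 0.046875
        assert round(r.p, 3) == 0.047

    def test_five_concordant(self):
        assert wilcoxon_exact([1, 2, 3, 4, 5]).p == 0.0625

    def test_zeros_dropped_all_zero_rejected(self):
        assert wilcoxon_exact([0.0, 1.0, 2.0]).n == 2
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_exact([0.0, 0.0])

    @pytest.mark.parametrize("n", [3, 5, 8, 12])
    def test_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = np.round(rng.normal(0.3, 1.0, n), 1)
        d[d == 0] = 0.05
        w, p = _wilcoxon_brute_force(d)
        r = wilcoxon_exact(d)
        assert r.statistic == pytest.approx(w)
        assert r.p == pytest.approx(p, abs=1e-12)

    def test_ties_handled_with_midranks(self):
        d = [1.0, 1.0, -1.0, 2.0, 3.0, 3.0]
        w, p = _wilcoxon_brute_force(d)
        r = wilcoxon_exact(d)
        assert r.statistic == pytest.approx(w)
        assert r.p == pytest.approx(p, abs=1e-12)

    def test_scipy_agrees_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        d = [0.3, -1.2, 0.7, 2.0, -0.1, 0.9, 0.5, 1.1]
        assert wilcoxon_exact(d).p == pytest.approx(
            scipy_wilcoxon(d, mode="exact").pvalue
        )


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, [2.0, 4.0, 9.0, 16.0, 30.0]).rho == pytest.approx(1.0)
        assert spearman(x, [-1.0, -2.0, -3.0, -5.0, -9.0]).rho == pytest.approx(-1.0)

    def test_exhaustive_permutation_oracle_n6(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman(x, y)
        # independent oracle: no-tie closed form rho over all 720 orderings
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        n = 6

        def rho_closed(ra, rb):
            return 1 - 6 * np.sum((ra - rb) ** 2) / (n * (n**2 - 1))

        rho_obs = rho_closed(rx, ry)
        count = sum(
            abs(rho_closed(rx, np.asarray(p))) >= abs(rho_obs) - 1e-12
            for p in permutations(ry)
        )
        assert res.rho == pytest.approx(rho_obs)
        assert res.p == pytest.approx(count / 720.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        st.lists(st.integers(-500, 500), min_size=5, max_size=12, unique=True),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_invariant_under_monotone_transforms(self, xs, kind):
        rng = np.random.default_rng(7)
        x = np.asarray(xs, dtype=float) / 10.0  # well-spaced: transforms stay injective
        y = rng.permutation(len(x)).astype(float)
        if np.ptp(y) == 0:
            return
        f = {"exp": lambda v: np.exp(v / 50.0), "cube": lambda v: v**3,
             "affine": lambda v: 3.0 * v + 7.0}[kind]
        a = spearman(x, y)
        b = spearman(f(x), y)
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_t_approximation_for_larger_samples(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=25)
        y = x + rng.normal(scale=0.8, size=25)
        from scipy.stats import spearmanr

        res = spearman(x, y)
        ref = spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestSurrogacy:
    def _macro(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        vt = rng.uniform(1, 8, n)
        return pd.DataFrame(
            {
                "V_T": vt,
                "V_T_vb": 0.05 + 0.95 * vt,
                "SUVR": vt * 0.9 + rng.normal(0, 0.1, n),
                "SUV": rng.uniform(0.5, 3.0, n),
                "K_Logan": 0.05 + 0.93 * vt,
                "Ki_2T6P": rng.uniform(0.01, 0.2, n),
                "Ki_2T5P": rng.uniform(0.01, 0.2, n),
            }
        )

    def test_pair_set_has_seven_entries(self):
        res = surrogacy_analysis(self._macro())
        assert len(res) == len(SURROGACY_PAIRS) == 7

    def test_missing_column_named(self):
        with pytest.raises(KeyError, match="K_Logan"):
            surrogacy_analysis(self._macro().drop(columns=["K_Logan"]))

    def test_monotone_map_gives_perfect_rank_correlation(self):
        res = {r.label: r for r in surrogacy_analysis(self._macro())}
        assert res["K_Logan vs V_T(v_b)"].rho == pytest.approx(1.0)
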