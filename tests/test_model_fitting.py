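"""Model fitting: AICc, recovery on noiseless data, delay estimation,
model selection."""

import dataclasses
import math

import numpy as np
import pytest

from petkin.compartment_models import KineticParams, model_tac
from petkin.input_function import InputFunction, shift
from petkin.model_fitting import FitOptions, aicc, fit_all_models, fit_model, select_model
from petkin.synthetic_data import generate_region_tac, noise_sigma, RegionSpec
from petkin.tac_io import TimeActivityCurve


class TestAicc:
    def test_closed_form_example(self):
        # 20*ln(0.05) + 2*5 + 2*5*6/14
        expected = 20 * math.log(0.05) + 10 + 60 / 14
        assert aicc(1.0, 20, 5) == pytest.approx(expected)
        assert expected == pytest.approx(-45.629, abs=5e-4)

    def test_halving_rss_drops_n_ln2(self):
        n, k = 40, 6
        assert aicc(2.0, n, k) - aicc(1.0, n, k) == pytest.approx(n * math.log(2.0))

    def test_converges_to_uncorrected_aic(self):
        k = 5
        for n in (10_000, 1_000_000):
            plain = n * math.log(1.0 / n) + 2 * k
            assert aicc(1.0, n, k) - plain == pytest.approx(0.0, abs=2 * k * (k + 1) / (n - k - 1) + 1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(1.0, 6, 5)


@pytest.mark.parametrize(
    "truth",
    [
        KineticParams("1T4P", 0.08, 0.35, 0.22, t_d=0.15),
        KineticParams("2T5P", 0.05, 0.45, 0.3, 0.08, t_d=-0.1),
        KineticParams("2T6P", 0.05, 0.4, 0.3, 0.05, 0.02, 0.1),
    ],
    ids=lambda p: p.model,
)
def test_noiseless_recovery_within_one_percent(truth, aorta_input, schedule):
    tac = model_tac(truth, aorta_input, schedule)
    fit = fit_model(tac, aorta_input, truth.model,
                    FitOptions(seed=3, rss_early_stop=1e-16))
    rel = np.abs(fit.params.vector - truth.vector) / np.abs(truth.vector)
    assert np.all(rel < 0.01), dict(zip(range(len(rel)), rel))


def test_nested_models_never_fit_worse(aorta_input, schedule, tumor_params):
    spec = RegionSpec("t", tumor_params)
    tac = generate_region_tac(spec, aorta_input, schedule, seed=42)
    fits = {f.params.model: f for f in fit_all_models(tac, aorta_input, FitOptions(seed=0))}
    assert fits["2T6P"].rss <= fits["2T5P"].rss * (1 + 1e-9)
    assert fits["2T5P"].rss <= fits["1T4P"].rss * (1 + 1e-9)


def test_delay_shift_recovered_within_half_finest_frame(aorta_input, schedule):
    truth = KineticParams("2T6P", 0.05, 0.4, 0.3, 0.05, 0.02, t_d=0.1)
    shifted = shift(aorta_input, 6.0 / 60.0)  # +6 s on top of t_d
    tac = model_tac(truth, shifted, schedule)
    fit = fit_model(tac, aorta_input, "2T6P", FitOptions(seed=3, rss_early_stop=1e-16))
    finest = float(np.min(schedule.durations))  # 2-s early frames
    assert abs(fit.params.t_d - (0.1 + 0.1)) < 0.5 * finest


def test_delay_grid_fallback_brackets_truth(aorta_input, schedule):
    """Grid-searched delay lands on the grid point nearest the true delay
    and still counts t_d in the AICc parameter tally."""
    truth = KineticParams("2T6P", 0.05, 0.4, 0.3, 0.05, 0.02, t_d=0.25)
    tac = model_tac(truth, aorta_input, schedule)
    fit = fit_model(tac, aorta_input, "2T6P",
                    FitOptions(seed=4, n_starts=3, delay_grid=9))  # step 0.25 min
    assert fit.params.t_d == pytest.approx(0.25, abs=1e-9)
    assert fit.k_params == 6
    assert not fit.fixed_delay


def test_fit_invariant_to_unit_rescaling(aorta_input, schedule, tumor_params):
    spec = RegionSpec("t", tumor_params)
    tac = generate_region_tac(spec, aorta_input, schedule, seed=9)
    fit = fit_model(tac, aorta_input, "2T6P", FitOptions(seed=1))
    c = 37.0  # e.g. SUV -> kBq/mL-like rescaling of tissue and blood alike
    tac_c = TimeActivityCurve("t", schedule, c * tac.values, unit="kBq/mL")
    blood_c = InputFunction(
        TimeActivityCurve(
            aorta_input.tac.region_label,
            aorta_input.tac.schedule,
            c * aorta_input.tac.values,
            unit="kBq/mL",
        ),
        tail=dataclasses.replace(
            aorta_input.tail, A1=c * aorta_input.tail.A1, A2=c * aorta_input.tail.A2
        ),
    )
    fit_c = fit_model(tac_c, blood_c, "2T6P", FitOptions(seed=1))
    np.testing.assert_allclose(fit_c.params.vector, fit.params.vector, rtol=1e-4)


class TestSelectModel:
    def _mk(self, model, aicc_val, k):
        p = KineticParams(model, 0.05, 0.3, 0.2,
                          0.05 if model != "1T4P" else 0.0,
                          0.02 if model == "2T6P" else 0.0)
        from petkin.model_fitting import KineticFit

        return KineticFit(p, 1.0, 65, k, aicc_val, True, 1, False)

    def test_lowest_aicc_wins(self):
        fits = [self._mk("1T4P", -40, 4), self._mk("2T5P", -45, 5), self._mk("2T6P", -42, 6)]
        assert select_model(fits).aicc == -45

    def test_tie_prefers_fewer_parameters(self):
        fits = [self._mk("2T5P", -45.0, 5), self._mk("2T6P", -45.0 + 1e-12, 6)]
        assert select_model(fits).params.model == "2T5P"

    def test_distinct_kinds_required(self):
        with pytest.raises(ValueError, match="distinct"):
            select_model([self._mk("2T6P", -45, 6), self._mk("2T6P", -44, 6)])

    def test_true_generating_model_selected(self, aorta_input, schedule):
        """Data simulated from each generator kind is attributed to it:
        2T6P wins on well-separated reversible kinetics at low noise, and
        1T4P wins in the majority of moderately noisy 1-tissue replicates."""
        p6 = KineticParams("2T6P", 0.05, 0.5, 0.4, 0.15, 0.05, 0.0)
        clean = model_tac(p6, aorta_input, schedule)
        sigma = noise_sigma(0.005, clean.values, schedule)
        rng = np.random.default_rng(0)
        tac = TimeActivityCurve("r", schedule, clean.values + sigma * rng.standard_normal(65))
        best = select_model(fit_all_models(tac, aorta_input, FitOptions(seed=2, n_starts=4)))
        assert best.params.model == "2T6P"

        p1 = KineticParams("1T4P", 0.08, 0.35, 0.22, t_d=0.0)
        clean = model_tac(p1, aorta_input, schedule)
        sigma = noise_sigma(0.03, clean.values, schedule)
        wins = 0
        n_rep = 11
        for r in range(n_rep):
            tac = TimeActivityCurve(
                "r", schedule, clean.values + sigma * rng.standard_normal(65)
            )
            best = select_model(
                fit_all_models(tac, aorta_input, FitOptions(seed=2, n_starts=3))
            )
            wins += best.params.model == "1T4P"
        assert wins > n_rep / 2
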