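"""Ground-truth study generator: inputs, noise model, cohorts."""

import dataclasses

import numpy as np
import pytest

from petkin.compartment_models import model_tac
from petkin.input_function import fit_biexp_tail
from petkin.macro_analysis import compute_vt
from petkin.synthetic_data import (
    AORTA_SHAPE,
    ORGAN_PRESETS,
    TUMOR_PRESET,
    CohortSpec,
    InputShape,
    RegionSpec,
    generate_cohort,
    generate_input,
    generate_region_tac,
    noise_sigma,
)
from petkin.tac_io import AORTA, RIGHT_VENTRICLE


class TestGenerateInput:
    def test_single_early_peak_and_monotone_tail(self, schedule, aorta_input):
        vals = aorta_input.tac.values
        mid = schedule.midpoints
        assert mid[np.argmax(vals)] < 1.0  # peak within first 60 s
        late = vals[mid > 10.0]
        assert np.all(np.diff(late) < 0)

    def test_linear_in_amplitude(self, schedule):
        a = generate_input(AORTA_SHAPE, schedule, fit_tail=False)
        shape2 = dataclasses.replace(
            AORTA_SHAPE,
            bolus_amp=2 * AORTA_SHAPE.bolus_amp,
            A1=2 * AORTA_SHAPE.A1,
            A2=2 * AORTA_SHAPE.A2,
        )
        b = generate_input(shape2, schedule, fit_tail=False)
        np.testing.assert_allclose(b.tac.values, 2 * a.tac.values, rtol=1e-12)

    def test_tail_refit_recovers_washout_rates(self, schedule):
        inp = generate_input(AORTA_SHAPE, schedule, fit_tail=False)
        tail = fit_biexp_tail(inp, (14.0, 90.0))
        assert tail.lam1 == pytest.approx(AORTA_SHAPE.lam1, rel=0.02)
        assert tail.lam2 == pytest.approx(AORTA_SHAPE.lam2, rel=0.02)

    def test_strictly_positive_after_onset(self, aorta_input, schedule):
        sel = schedule.midpoints > AORTA_SHAPE.t0
        assert np.all(aorta_input.tac.values[sel] > 0)

    def test_nonphysiologic_shape_rejected(self):
        with pytest.raises(ValueError):
            InputShape(bolus_amp=-1.0)


class TestGenerateRegionTac:
    def test_zero_noise_reproduces_forward_model(self, aorta_input, schedule, tumor_params):
        spec = RegionSpec("t", tumor_params, noise_scale=0.0)
        tac = generate_region_tac(spec, aorta_input, schedule, seed=1)
        np.testing.assert_array_equal(
            tac.values, model_tac(tumor_params, aorta_input, schedule).values
        )

    def test_seed_reproducibility(self, aorta_input, schedule, tumor_params):
        spec = RegionSpec("t", tumor_params)
        a = generate_region_tac(spec, aorta_input, schedule, seed=7)
        b = generate_region_tac(spec, aorta_input, schedule, seed=7)
        c = generate_region_tac(spec, aorta_input, schedule, seed=8)
        np.testing.assert_array_equal(a.values, b.values)
        assert np.any(a.values != c.values)

    def test_empirical_sd_matches_noise_model(self, aorta_input, schedule, tumor_params):
        scale = 0.05
        spec = RegionSpec("t", tumor_params, noise_scale=scale)
        clean = model_tac(tumor_params, aorta_input, schedule).values
        sigma = noise_sigma(scale, clean, schedule)
        draws = np.array(
            [
                generate_region_tac(spec, aorta_input, schedule, seed=s).values
                for s in range(1000)
            ]
        )
        emp = draws.std(axis=0, ddof=1)
        sel = sigma > 1e-6
        np.testing.assert_allclose(emp[sel], sigma[sel], rtol=0.10)


class TestGenerateCohort:
    def test_default_cohort_layout(self, schedule):
        cohort = CohortSpec(seed=3, noiseless=True)
        scans, truth = generate_cohort(cohort, schedule)
        assert len(scans) == 4 + 2  # healthy + patient pre/post
        patient_pre = [s for s in scans if (s.subject_id, s.scan_id) == ("patient", "pre")][0]
        tum = [r for r in patient_pre.tissue_labels if r.startswith("tumor_sub_")]
        lns = [r for r in patient_pre.tissue_labels if r.startswith("mediastinal_ln_")]
        assert len(tum) == 7 and len(lns) == 4
        assert {AORTA, RIGHT_VENTRICLE} <= set(patient_pre.tacs)
        # ground truth emitted for every region of every scan
        assert len(truth) == sum(len(s.tissue_labels) for s in scans)

    def test_pure_function_of_spec_and_seed(self, schedule):
        cohort = CohortSpec(seed=11)
        s1, t1 = generate_cohort(cohort, schedule)
        s2, t2 = generate_cohort(cohort, schedule)
        assert t1.equals(t2)
        for a, b in zip(s1, s2):
            for lbl in a.tacs:
                np.testing.assert_array_equal(a.tacs[lbl].values, b.tacs[lbl].values)

    def test_zero_effect_leaves_truth_unchanged(self, schedule):
        cohort = CohortSpec(seed=5, delta_k3=0.0, delta_k4=0.0, noiseless=True)
        _, truth = generate_cohort(cohort, schedule)
        pre = truth[(truth.subject == "patient") & (truth.scan == "pre")].set_index("region")
        post = truth[(truth.subject == "patient") & (truth.scan == "post")].set_index("region")
        tum = [r for r in pre.index if r.startswith("tumor_sub_")]
        assert (pre.loc[tum, ["k_3", "k_4"]] == post.loc[tum, ["k_3", "k_4"]]).all().all()

    def test_therapy_raises_tumor_vt_in_every_subregion(self, schedule):
        cohort = CohortSpec(seed=5, noiseless=True)
        _, truth = generate_cohort(cohort, schedule)
        pre = truth[(truth.subject == "patient") & (truth.scan == "pre")].set_index("region")
        post = truth[(truth.subject == "patient") & (truth.scan == "post")].set_index("region")
        tum = [r for r in pre.index if r.startswith("tumor_sub_")]
        assert len(tum) == 7
        assert (post.loc[tum, "V_T"] > pre.loc[tum, "V_T"]).all()
        assert (post.loc[tum, "k_3"] > pre.loc[tum, "k_3"]).all()
        assert (post.loc[tum, "k_4"] < pre.loc[tum, "k_4"]).all()

    def test_enlarged_vs_nonenlarged_nodes_shift_oppositely(self, schedule):
        cohort = CohortSpec(seed=5, noiseless=True)
        _, truth = generate_cohort(cohort, schedule)
        pre = truth[(truth.subject == "patient") & (truth.scan == "pre")].set_index("region")
        post = truth[(truth.subject == "patient") & (truth.scan == "post")].set_index("region")
        enlarged = ["mediastinal_ln_1", "mediastinal_ln_2"]
        normal = ["mediastinal_ln_3", "mediastinal_ln_4"]
        assert (post.loc[enlarged, "V_T"] < pre.loc[enlarged, "V_T"]).all()
        assert (post.loc[normal, "V_T"] > pre.loc[normal, "V_T"]).all()

    def test_invalid_cohorts_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(delta_k4=1.5)
        with pytest.raises(ValueError):
            CohortSpec(n_healthy=0)


def test_presets_span_reversible_and_1t_kinetics():
    models = {s.params.model for s in ORGAN_PRESETS.values()}
    assert models == {"2T6P", "1T4P"}
    assert TUMOR_PRESET.params.model == "2T6P"
    assert compute_vt(TUMOR_PRESET.params) > 1.0
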