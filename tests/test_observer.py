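"""Generative observer: response probabilities, manipulations, simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import ndtr

import confdiag as cd
from confdiag.observer import NONE_MANIP


class TestDecisionProbability:
    def test_midpoint_is_half(self, params):
        assert cd.decision_probability(params.pse_mu, params) == pytest.approx(0.5)

    def test_sensory_shift_matches_normal_cdf(self, params):
        # shifting the PSE by +10 with sigma 6 puts the old midpoint at Phi(-10/6)
        m = cd.Manipulation(mode="sensory_shift", shift=10.0)
        assert cd.decision_probability(0.0, params, m) == pytest.approx(ndtr(-10 / 6), abs=1e-9)

    def test_full_compliance_resolves_ambiguous_trial(self, params):
        m = cd.Manipulation(mode="decision_bias", bias_direction="right", compliance=1.0)
        assert cd.decision_probability(params.conf_mu, params, m) == pytest.approx(1.0)
        m_left = cd.Manipulation(mode="decision_bias", bias_direction="left", compliance=1.0)
        assert cd.decision_probability(params.conf_mu, params, m_left) == pytest.approx(0.0)

    @pytest.mark.parametrize("mode_kwargs", [
        {},
        {"mode": "sensory_shift", "shift": 7.5},
    ])
    def test_monotone_nondecreasing(self, params, mode_kwargs):
        m = cd.Manipulation(**mode_kwargs)
        x = np.linspace(-40, 40, 401)
        p = cd.decision_probability(x, params, m)
        assert np.all(np.diff(p) >= -1e-12)

    @given(shift=st.floats(-15, 15), x=st.floats(-30, 30))
    def test_shift_is_pure_translation(self, shift, x):
        params = cd.ObserverParams()
        m = cd.Manipulation(mode="sensory_shift", shift=shift)
        assert cd.decision_probability(x, params, m) == pytest.approx(
            cd.decision_probability(x - shift, params), abs=1e-12
        )
        assert cd.low_confidence_probability(x, params, m) == pytest.approx(
            cd.low_confidence_probability(x - shift, params), abs=1e-12
        )

    def test_nonfinite_input_rejected(self, params):
        with pytest.raises(ValueError):
            cd.decision_probability(np.nan, params)
        with pytest.raises(ValueError):
            cd.decision_probability(np.inf, params)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            cd.Manipulation(mode="telepathy")

    def test_lapse_floors_and_caps_the_function(self):
        p = cd.ObserverParams(lapse=0.1)
        assert cd.decision_probability(-60.0, p) >= 0.049
        assert cd.decision_probability(60.0, p) <= 0.951


class TestLowConfidenceProbability:
    def test_peak_value(self, params):
        assert cd.low_confidence_probability(params.conf_mu, params) == pytest.approx(
            params.conf_floor + params.conf_amplitude
        )

    def test_tails_approach_floor(self, params):
        assert cd.low_confidence_probability(1e3, params) == pytest.approx(params.conf_floor, abs=1e-9)
        assert cd.low_confidence_probability(-1e3, params) == pytest.approx(params.conf_floor, abs=1e-9)

    @pytest.mark.parametrize("gamma", [0.2, 0.8, 1.0])
    def test_decision_bias_leaves_confidence_unchanged(self, params, gamma):
        # the diagnostic signature: the bias acts after perception
        m = cd.Manipulation(mode="decision_bias", bias_direction="left", compliance=gamma)
        x = np.linspace(-40, 40, 101)
        np.testing.assert_array_equal(
            cd.low_confidence_probability(x, params, m),
            cd.low_confidence_probability(x, params, NONE_MANIP),
        )


class TestObserverParamsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"sigma": 0.0},
        {"conf_sigma": -1.0},
        {"conf_amplitude": 0.0},
        {"conf_floor": 0.5, "conf_amplitude": 0.6},
        {"lapse": 0.5},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cd.ObserverParams(**kwargs)


class TestSimulateExperiment:
    def test_exp1_trial_count_and_balance(self, params):
        manips = {lab: NONE_MANIP for lab in cd.EXP1_DESIGN.condition_labels}
        t = cd.simulate_experiment(cd.EXP1_DESIGN, params, manips, seed=7)
        assert len(t) == 220
        per_cell = t.groupby(["condition", "coherence"]).size()
        assert (per_cell == 10).all()
        assert t["trial_index"].is_monotonic_increasing

    def test_exp3_trial_count(self, params):
        t = cd.simulate_experiment(cd.EXP3_DESIGN, params, {"test": NONE_MANIP}, seed=7)
        assert len(t) == 440
        assert 0.0 not in set(t["coherence"])

    def test_half_block_condition_reversal(self, params):
        manips = {lab: NONE_MANIP for lab in cd.EXP1_DESIGN.condition_labels}
        t = cd.simulate_experiment(cd.EXP1_DESIGN, params, manips, seed=7)
        assert set(t.iloc[:110]["condition"]) == {"adapt_left"}
        assert set(t.iloc[110:]["condition"]) == {"adapt_right"}

    def test_same_seed_identical_tables(self, params):
        manips = {lab: NONE_MANIP for lab in cd.EXP1_DESIGN.condition_labels}
        a = cd.simulate_experiment(cd.EXP1_DESIGN, params, manips, seed=42)
        b = cd.simulate_experiment(cd.EXP1_DESIGN, params, manips, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_condition_mapping_errors(self, params):
        with pytest.raises(ValueError, match="adapt_right"):
            cd.simulate_experiment(cd.EXP1_DESIGN, params, {"adapt_left": NONE_MANIP}, seed=1)

    def test_choice_frequencies_converge_to_model(self, params):
        # empirical proportions within 3 binomial SEs of the latent function
        design = cd.ExperimentDesign(coherence_levels=(-10, -3, 0, 3, 10), repeats_per_level=2000)
        t = cd.simulate_experiment(design, params, {"test": NONE_MANIP}, seed=99)
        counts = cd.tabulate(t)
        p = cd.decision_probability(counts["coherence"].to_numpy(), params)
        se = np.sqrt(p * (1 - p) / counts["n_trials"].to_numpy())
        phat = counts["n_right"].to_numpy() / counts["n_trials"].to_numpy()
        assert np.all(np.abs(phat - p) < 3 * se + 1e-9)


class TestSerialObserver:
    def test_too_short_design_errors(self, params):
        tiny = cd.ExperimentDesign(coherence_levels=(-1, 1), repeats_per_level=1)
        with pytest.raises(ValueError):
            cd.simulate_serial_observer(tiny, params, 3.0, 0.3, seed=1)

    def test_null_mechanisms_match_plain_simulation_statistically(self, params):
        design = cd.ExperimentDesign(coherence_levels=(-5, -1, 1, 5), repeats_per_level=3000)
        t = cd.simulate_serial_observer(design, params, 0.0, 0.0, seed=11)
        counts = cd.tabulate(t)
        p = cd.decision_probability(counts["coherence"].to_numpy(), params)
        se = np.sqrt(p * (1 - p) / counts["n_trials"].to_numpy())
        phat = counts["n_right"].to_numpy() / counts["n_trials"].to_numpy()
        assert np.all(np.abs(phat - p) < 4 * se)

    def test_one_back_shift_moves_decisions_contrastively(self, params):
        # after rightward tests the observer needs more rightward coherence
        t = cd.simulate_serial_observer(cd.EXP3_DESIGN, params, 5.0, 0.0, seed=21)
        parts = cd.split_by_nback(t, 1)
        pl = cd.tabulate(parts["prev_left"])
        pr = cd.tabulate(parts["prev_right"])
        frac = lambda c: c["n_right"].sum() / c["n_trials"].sum()
        assert frac(pl) > frac(pr)


def test_cohort_per_subject_streams_reproducible(params):
    observers = [params, cd.ObserverParams(pse_mu=1.0)]
    manips = {lab: NONE_MANIP for lab in cd.EXP1_DESIGN.condition_labels}
    a = cd.simulate_cohort(cd.EXP1_DESIGN, observers, manips, seed=5)
    b = cd.simulate_cohort(cd.EXP1_DESIGN, observers, manips, seed=5)
    pd.testing.assert_frame_equal(a, b)
    assert sorted(a["subject_id"].unique()) == ["s01", "s02"]
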