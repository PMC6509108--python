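"""Psychometric fitting: tabulation, MLE recovery, adequacy screen."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

import confdiag as cd
from confdiag.fits import STIMULUS_RANGE


class TestTabulate:
    def test_exp1_baseline_tabulation(self, baseline_table):
        counts = cd.tabulate(baseline_table)
        assert len(counts) == 11
        assert (counts["n_trials"] == 20).all()
        assert counts["coherence"].is_monotonic_increasing

    def test_counts_conserve_trials(self, baseline_table):
        counts = cd.tabulate(baseline_table, "adapt_left")
        assert counts["n_trials"].sum() == (baseline_table["condition"] == "adapt_left").sum()

    def test_single_trial(self):
        t = pd.DataFrame(
            {
                "subject_id": ["s01"], "block": [1], "trial_index": [0],
                "condition": ["test"], "coherence": [30.0],
                "choice": ["right"], "confidence": ["high"],
            }
        )
        counts = cd.tabulate(t)
        assert counts.iloc[0].tolist() == [30.0, 1, 1, 0]

    def test_empty_selection_errors(self, baseline_table):
        with pytest.raises(ValueError):
            cd.tabulate(baseline_table, "no_such_condition")


class TestFitDecision:
    def test_recovers_generating_function(self, exp1_levels, make_pseudo_counts):
        counts = make_pseudo_counts(exp1_levels, ndtr((exp1_levels - 2) / 6), 0.0)
        fit = cd.fit_decision(counts)
        assert fit.converged
        assert fit.mu == pytest.approx(2.0, abs=0.05)
        assert fit.sigma == pytest.approx(6.0, abs=0.05)

    def test_symmetric_counts_give_zero_pse(self, exp1_levels, make_pseudo_counts):
        counts = make_pseudo_counts(exp1_levels, ndtr(exp1_levels / 6), 0.0)
        assert abs(cd.fit_decision(counts).mu) < 1e-6

    def test_pse_is_the_half_point_of_the_fit(self, exp1_levels, make_pseudo_counts):
        counts = make_pseudo_counts(exp1_levels, ndtr((exp1_levels + 4) / 8), 0.0)
        fit = cd.fit_decision(counts)
        assert fit.predict(fit.mu) == pytest.approx(0.5, abs=1e-12)

    def test_no_crossing_flags_nonconvergence(self, exp1_levels, make_pseudo_counts):
        counts = make_pseudo_counts(exp1_levels, np.full(len(exp1_levels), 1.0), 0.0)
        assert not cd.fit_decision(counts).converged

    def test_too_few_levels_rejected(self, make_pseudo_counts):
        counts = make_pseudo_counts(np.array([-3.0, 0.0, 3.0]), [0.2, 0.5, 0.8], 0.0)
        with pytest.raises(ValueError):
            cd.fit_decision(counts)

    def test_optimum_beats_every_grid_start(self, baseline_table):
        # optimizer sanity: the returned loglik dominates the coarse grid
        counts = cd.tabulate(baseline_table)
        fit = cd.fit_decision(counts)
        x = counts["coherence"].to_numpy()
        n = counts["n_trials"].to_numpy()
        k = counts["n_right"].to_numpy()
        for mu in np.linspace(-40, 40, 17):
            for sigma in np.geomspace(1, 40, 8):
                p = np.clip(ndtr((x - mu) / sigma), 1e-10, 1 - 1e-10)
                ll = np.sum(k * np.log(p) + (n - k) * np.log(1 - p))
                assert fit.loglik >= ll - 1e-6


class TestFitConfidence:
    def test_recovers_generating_function(self, exp1_levels, make_pseudo_counts):
        q = 0.05 + 0.8 * np.exp(-((exp1_levels + 1) ** 2) / (2 * 25.0))
        fit = cd.fit_confidence(make_pseudo_counts(exp1_levels, 0.0, q))
        assert fit.converged
        assert fit.mu_c == pytest.approx(-1.0, rel=0.02)
        assert fit.sigma_c == pytest.approx(5.0, rel=0.02)
        assert fit.amplitude == pytest.approx(0.8, rel=0.02)
        assert fit.floor == pytest.approx(0.05, rel=0.02)

    def test_mirror_symmetric_counts_give_zero_peak(self, exp1_levels, make_pseudo_counts):
        q = 0.1 + 0.7 * np.exp(-(exp1_levels**2) / (2 * 36.0))
        assert abs(cd.fit_confidence(make_pseudo_counts(exp1_levels, 0.0, q)).mu_c) < 1e-6

    def test_peak_is_attained_at_mu_c(self, exp1_levels, make_pseudo_counts):
        q = 0.05 + 0.6 * np.exp(-((exp1_levels - 3) ** 2) / (2 * 16.0))
        fit = cd.fit_confidence(make_pseudo_counts(exp1_levels, 0.0, q))
        x = np.linspace(-30, 30, 2001)
        assert fit.predict(fit.mu_c) >= fit.predict(x).max() - 1e-12

    def test_flat_profile_flags_nonconvergence(self, exp1_levels, make_pseudo_counts):
        fit = cd.fit_confidence(make_pseudo_counts(exp1_levels, 0.0, np.full(len(exp1_levels), 0.3)))
        assert not fit.converged

    def test_floor_plus_amplitude_bounded(self, exp1_levels, make_pseudo_counts):
        q = np.clip(0.5 + 0.6 * np.exp(-(exp1_levels**2) / (2 * 36.0)), 0, 1)
        fit = cd.fit_confidence(make_pseudo_counts(exp1_levels, 0.0, q))
        assert fit.floor + fit.amplitude <= 1 + 1e-9


class TestAdequacy:
    def _fits(self, mu=-0.4, sigma=6.0, mu_c=-0.5, sigma_c=5.0, amp=0.8,
              dec_conv=True, conf_conv=True):
        dec = cd.PsychometricFit(mu=mu, sigma=sigma, loglik=-10.0, converged=dec_conv, n_levels=11)
        conf = cd.ConfidenceFit(mu_c=mu_c, sigma_c=sigma_c, amplitude=amp, floor=0.05,
                                loglik=-10.0, converged=conf_conv, n_levels=11)
        return dec, conf

    def test_good_fits_pass(self):
        ok, reason = cd.adequacy(*self._fits(), cd.EXP1_DESIGN)
        assert ok and reason == "ok"

    @pytest.mark.parametrize("kwargs,reason_part", [
        ({"mu": 75.0}, "PSE outside"),
        ({"mu_c": -45.0}, "peak uncertainty outside"),
        ({"sigma": STIMULUS_RANGE + 1}, "slope"),
        ({"amp": 0.02}, "uncertainty peak"),
        ({"dec_conv": False}, "decision fit"),
        ({"conf_conv": False}, "confidence fit"),
    ])
    def test_each_screen_rule_fires(self, kwargs, reason_part):
        ok, reason = cd.adequacy(*self._fits(**kwargs), cd.EXP1_DESIGN)
        assert not ok and reason_part in reason

    def test_zero_amplitude_observer_is_excluded(self):
        # an observer who never modulates confidence cannot be peak-fit
        params = cd.ObserverParams(conf_amplitude=0.01, conf_floor=0.3)
        t = cd.simulate_experiment(
            cd.EXP3_DESIGN, params, {"test": cd.Manipulation()}, seed=2
        )
        conf = cd.fit_confidence(cd.tabulate(t))
        dec = cd.fit_decision(cd.tabulate(t))
        ok, _ = cd.adequacy(dec, conf, cd.EXP3_DESIGN)
        assert not ok


def test_matched_observer_gives_matched_pse_estimates(params):
    """The two PSE estimates agree when decision and confidence share a center."""
    design = cd.ExperimentDesign(
        coherence_levels=cd.EXP1_DESIGN.coherence_levels, repeats_per_level=500
    )
    t = cd.simulate_experiment(design, params, {"test": cd.Manipulation()}, seed=17)
    counts = cd.tabulate(t)
    dec, conf = cd.fit_decision(counts), cd.fit_confidence(counts)
    assert abs(dec.mu - conf.mu_c) < 1.0
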