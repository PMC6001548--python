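"""Convolution GLM: design construction, pseudoinverse inversion, scoring rules."""

import numpy as np
import pytest

import rarmodel as rm
from rarmodel.rar_glm import GlmFit
from rarmodel.response_function import BasisSet


def single_component_basis(sr=10.0, duration=20.0):
    n = int(round(duration * sr)) + 1
    t = np.arange(n) / sr
    comp = np.exp(-((t - 5.0) ** 2) / 2.0)
    comp /= np.abs(comp).max()
    return BasisSet("G1", comp[None, :], ("ER",), sr)


def events_at(onsets, conditions=None, soa=3.5):
    onsets = np.asarray(onsets, float)
    if conditions is None:
        conditions = ["CS+"] * onsets.size
    return rm.EventSchedule(onsets, np.asarray(conditions, object), soa=soa)


class TestBuildDesign:
    def test_unit_impulse_reproduces_component(self):
        basis = single_component_basis()
        events = events_at([0.0])
        design = rm.build_design_matrix(events, basis, 400, 10.0, filter_regressors=False)
        col = design.X[:, design.column_map[("CS+", "ER")]]
        np.testing.assert_array_equal(col[:201], basis.component("ER"))
        assert np.all(col[201:] == 0.0)

    def test_linearity_two_events_sum_of_shifts(self):
        basis = single_component_basis()
        events = events_at([0.0, 15.0])
        design = rm.build_design_matrix(events, basis, 500, 10.0, filter_regressors=False)
        col = design.X[:, 0]
        expected = np.zeros(500)
        expected[:201] += basis.component("ER")
        expected[150:351] += basis.component("ER")
        np.testing.assert_allclose(col, expected, atol=1e-12)

    def test_time_invariance_one_step_shift(self):
        """Shifting all onsets by one grid step shifts the convolution columns
        by one row (before the data filter, whose edge transients are not
        shift-invariant on a finite record)."""
        basis = single_component_basis()
        d1 = rm.build_design_matrix(events_at([20.0, 40.0]), basis, 700, 10.0, filter_regressors=False)
        d2 = rm.build_design_matrix(events_at([20.1, 40.1]), basis, 700, 10.0, filter_regressors=False)
        np.testing.assert_allclose(d2.X[1:, 0], d1.X[:-1, 0], atol=1e-12)

    def test_event_outside_span_rejected(self):
        basis = single_component_basis()
        with pytest.raises(ValueError, match="event outside data span"):
            rm.build_design_matrix(events_at([20.0, 80.0]), basis, 500, 10.0)

    def test_intercept_column_appended(self):
        basis = single_component_basis()
        design = rm.build_design_matrix(events_at([20.0, 40.0]), basis, 700, 10.0)
        assert np.all(design.X[:, design.intercept_index] == 1.0)
        assert design.X.shape[1] == 2  # 1 condition x 1 component + intercept


class TestInvertGlm:
    def test_exact_recovery_noiseless(self, noiseless_session, noiseless_fit):
        """Y built from the design recovers the generating betas to 1e-10."""
        ts, events, truth = noiseless_session
        fit = noiseless_fit
        design = rm.build_design_matrix(
            events,
            rm.build_basis("G3", ts.sampling_rate, soa=events.soa),
            len(ts),
            ts.sampling_rate,
            sample_times=truth.sample_times,
        )
        beta_star = np.array([0.3, -0.7, 1.2, 0.4, 0.05])
        y = design.X @ beta_star
        recovered = rm.invert_glm(design, y).betas
        np.testing.assert_allclose(recovered, beta_star, rtol=1e-10, atol=1e-12)

    def test_fitted_plus_residuals_is_data(self, noiseless_session, noiseless_fit):
        ts, _, _ = noiseless_session
        np.testing.assert_allclose(
            noiseless_fit.fitted + noiseless_fit.residuals, ts.values, atol=1e-12
        )

    def test_end_to_end_linearity(self, noiseless_session):
        """Doubling the data doubles every beta and score exactly."""
        ts, events, truth = noiseless_session
        basis = rm.build_basis("G3", ts.sampling_rate, soa=events.soa)
        design = rm.build_design_matrix(
            events, basis, len(ts), ts.sampling_rate, sample_times=truth.sample_times
        )
        f1 = rm.invert_glm(design, ts.values)
        f2 = rm.invert_glm(design, 2.0 * ts.values)
        np.testing.assert_allclose(f2.betas, 2.0 * f1.betas, rtol=1e-9)
        for cond in f1.conditions:
            assert rm.score_lr_minus_er(f2, cond) == pytest.approx(
                2.0 * rm.score_lr_minus_er(f1, cond), abs=1e-9
            )

    def test_betas_within_analytic_standard_errors(self):
        """Monte-Carlo coverage matches the analytic OLS covariance."""
        cfg = rm.SimulationConfig(n_trials_per_condition=20, noise_sd=0.0, drift_sd=0.0, seed=33)
        ts, events, truth = rm.simulate_amplitude_session(cfg)
        basis = rm.build_basis("G3", ts.sampling_rate, soa=events.soa)
        design = rm.build_design_matrix(
            events, basis, len(ts), ts.sampling_rate, sample_times=truth.sample_times
        )
        beta_star = np.array([-1.0, 1.0, 0.0, 0.0, 0.0])
        mu = design.X @ beta_star
        sigma = float(np.abs(mu).max())  # SNR ~ 1
        pinvX = np.linalg.pinv(design.X)
        se = sigma * np.sqrt(np.diag(pinvX @ pinvX.T))
        rng = np.random.default_rng(8)
        n_sim, inside = 400, 0
        for _ in range(n_sim):
            betas = pinvX @ (mu + rng.normal(0, sigma, mu.size))
            inside += int(np.sum(np.abs(betas - beta_star) <= 3 * se))
        assert inside / (n_sim * beta_star.size) >= 0.99

    def test_rank_deficiency_warns_not_errors(self):
        basis = single_component_basis()
        events = events_at([20.0, 40.0])
        design = rm.build_design_matrix(events, basis, 700, 10.0)
        design.X[:, 0] = design.X[:, 1]  # duplicate the intercept
        with pytest.warns(UserWarning, match="rank-deficient"):
            rm.invert_glm(design, np.zeros(700))


def make_fit(reconstructed, basis, sr=10.0):
    return GlmFit(
        betas=np.zeros(1), column_map={("CS+", "ER"): 0}, intercept_index=1,
        residuals=np.zeros(1), fitted=np.zeros(1), reconstructed=reconstructed,
        model_id=basis.model_id, sampling_rate=sr, basis=basis,
    )


class TestScoring:
    def test_reconstruction_score_examples(self):
        sr = 10.0
        basis = rm.build_basis("G1", sr)
        n11 = int(11 * sr) + 1
        t = np.arange(n11) / sr
        zero = make_fit({"CS+": np.zeros(n11)}, basis)
        assert rm.score_reconstruction(zero, "CS+") == 0.0
        neg_er = make_fit({"CS+": -basis.component("ER")[:n11]}, basis)
        assert rm.score_reconstruction(neg_er, "CS+") == pytest.approx(-1.0, abs=1e-9)
        biphasic = 0.5 * np.exp(-((t - 3) ** 2)) - 0.8 * np.exp(-((t - 9) ** 2))
        fit = make_fit({"CS+": biphasic}, basis)
        assert rm.score_reconstruction(fit, "CS+") == pytest.approx(-0.8, abs=1e-6)

    def test_lr_minus_er_noiseless_condition_scores(self, noiseless_fit):
        """True betas (-1, +1) for CS+ and (0, 0) for CS- give scores 2 and 0."""
        assert rm.score_lr_minus_er(noiseless_fit, "CS+") == pytest.approx(2.0, abs=1e-6)
        assert rm.score_lr_minus_er(noiseless_fit, "CS-") == pytest.approx(0.0, abs=1e-6)

    def test_lr_score_undefined_without_lr(self, noiseless_session):
        ts, events, truth = noiseless_session
        basis = rm.build_basis("G1", ts.sampling_rate, soa=events.soa)
        design = rm.build_design_matrix(
            events, basis, len(ts), ts.sampling_rate, sample_times=truth.sample_times
        )
        fit = rm.invert_glm(design, ts)
        with pytest.raises(ValueError, match="score undefined"):
            rm.score_lr_minus_er(fit, "CS+")

    def test_g2_score_invariant_under_basis_recombination(self, noiseless_session):
        """Any invertible recombination of {ER, dER} spans the same space and
        leaves the reconstruction-based score unchanged."""
        ts, events, truth = noiseless_session
        sr = ts.sampling_rate
        g2 = rm.build_basis("G2", sr, soa=events.soa)
        M = np.array([[1.0, 0.4], [-0.3, 1.1]])
        mixed = BasisSet("G2", M @ g2.components, ("ER", "dER"), sr)
        scores = []
        for basis in (g2, mixed):
            design = rm.build_design_matrix(
                events, basis, len(ts), sr, sample_times=truth.sample_times
            )
            fit = rm.invert_glm(design, ts)
            scores.append([rm.score_reconstruction(fit, c) for c in fit.conditions])
        np.testing.assert_allclose(scores[0], scores[1], atol=1e-8)


class TestModelStructure:
    def test_g3_rss_below_g1_on_g3_data(self):
        """G1's column space is nested in G3's, so G3 never fits worse; with a
        true late response it fits strictly better on every replicate."""
        for seed in range(5):
            cfg = rm.SimulationConfig(n_trials_per_condition=10, noise_sd=0.3, seed=100 + seed)
            ts, events, truth = rm.simulate_amplitude_session(cfg)
            rss = {}
            for model in ("G1", "G3"):
                basis = rm.build_basis(model, ts.sampling_rate, soa=events.soa)
                design = rm.build_design_matrix(
                    events, basis, len(ts), ts.sampling_rate, sample_times=truth.sample_times
                )
                fit = rm.invert_glm(design, ts)
                rss[model] = float(fit.residuals @ fit.residuals)
            assert rss["G3"] < rss["G1"]

    def test_betas_invariant_under_iti_shuffle(self):
        """The LTI forward model makes betas independent of the ITI sequence."""
        results = []
        for seed in (77, 78):  # different schedules, same true betas
            cfg = rm.SimulationConfig(
                n_trials_per_condition=15, noise_sd=0.0, drift_sd=0.0, seed=seed
            )
            ts, events, truth = rm.simulate_amplitude_session(cfg)
            basis = rm.build_basis("G3", ts.sampling_rate, soa=events.soa)
            design = rm.build_design_matrix(
                events, basis, len(ts), ts.sampling_rate, sample_times=truth.sample_times
            )
            fit = rm.invert_glm(design, ts)
            results.append([fit.beta(c, l) for c in fit.conditions for l in ("ER", "LR")])
        np.testing.assert_allclose(results[0], results[1], atol=0.02)
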