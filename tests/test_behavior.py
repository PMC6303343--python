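"""Trial-level design coding, mixed-model estimation, and EB shrinkage."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from dmnstab import behavior, synth
from dmnstab.behavior import (
    build_design,
    build_design_table,
    design_from_trials,
    extract_learning_indices,
    fit_mixed_model,
    unpooled_slopes,
)

GAMMA = (5.0, -0.05, -1.0, 1.5, 0.8)


def _session_with_pumps(pumps, outcomes=None):
    """Build a 24-trial session with the given final pump counts."""
    trials = []
    for i, p in enumerate(pumps):
        if outcomes is not None and outcomes[i] == "explosion":
            trials.append(synth.BARTTrial(i, p, "explosion", p))
        else:
            trials.append(synth.BARTTrial(i, p, "cash_out", min(p + 1, 10)))
    events = pd.DataFrame(
        {"onset": np.arange(len(pumps), dtype=float), "duration": 0.0,
         "type": "pump", "pump_number": 1}
    )
    return synth.BARTSession("S001", trials, events)


class TestDesign:
    def test_value_coding_strictly_above_threshold(self):
        # 24 pump counts whose 75th percentile is 6
        pumps = [4] * 9 + [5] * 5 + [6] * 5 + [7] * 5
        assert np.percentile(pumps, 75) == 6.0
        session = _session_with_pumps(pumps)
        design = build_design(session)
        # rows are indexed by the current trial; prev_value looks back one
        for t in range(1, 24):
            expected = 1.0 if pumps[t - 1] > 6 else 0.0
            assert design.iloc[t - 1]["prev_value"] == expected

    def test_ties_at_threshold_are_low_value(self):
        pumps = [4] * 17 + [6] * 7  # 75th percentile = 6; sixes are ties
        assert np.percentile(pumps, 75) == 6.0
        design = build_design(_session_with_pumps(pumps))
        assert (design["prev_value"] == 0.0).all()

    def test_first_trial_emits_no_row(self, small_sessions):
        for s in small_sessions[:5]:
            assert len(build_design(s)) == 23

    def test_prev_valence_coding_positive_feedback_is_one(self):
        pumps = [5, 4, 5, 6] + [5] * 20
        outcomes = ["cash_out", "explosion", "cash_out", "cash_out"] + ["cash_out"] * 20
        design = build_design(_session_with_pumps(pumps, outcomes))
        assert design.iloc[0]["prev_valence"] == 1.0  # after a cash-out
        assert design.iloc[1]["prev_valence"] == 0.0  # after an explosion
        assert design.iloc[0]["current_outcome"] == 1.0  # explosion trial

    def test_design_from_trials_matches_session_route(self, small_sessions):
        table = synth.trials_table(small_sessions)
        a = design_from_trials(table).sort_values(["subject_id", "trial_number"])
        b = build_design_table(small_sessions).sort_values(["subject_id", "trial_number"])
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True), check_dtype=False
        )

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            design_from_trials(
                pd.DataFrame(
                    {"subject": ["a"], "balloon": [0], "pumps": [3],
                     "outcome": ["cash_out"], "explosion_point": [5]}
                )
            )


class TestMixedModel:
    @pytest.fixture(scope="class")
    def sim_fit(self):
        rows, truth = synth.simulate_learning_rows(
            GAMMA, 1.0, 0.25, 0.25, 1.0, 60, 24, seed=2
        )
        return rows, truth, fit_mixed_model(rows)

    def test_zero_variance_truth_collapses_eb_to_fixed_effects(self):
        rows, _ = synth.simulate_learning_rows(GAMMA, 0.0, 0.0, 0.0, 1.0, 30, 24, seed=1)
        fit = fit_mixed_model(rows)
        assert np.allclose(fit.eb_valence, fit.gamma_hat["prev_valence"], atol=1e-3)
        assert np.allclose(fit.eb_value, fit.gamma_hat["prev_value"], atol=1e-3)

    def test_fixed_effects_recovered_within_ci(self, sim_fit):
        rows, _, fit = sim_fit
        for name, true in zip(behavior.FIXED_EFFECTS, GAMMA):
            est, se = fit.gamma_hat[name], fit.gamma_se[name]
            assert abs(est - true) < 1.96 * se, name

    def test_agrees_with_general_purpose_mixed_fitter(self, sim_fit):
        rows, _, fit = sim_fit
        md = smf.mixedlm(
            "pumps ~ trial_number + current_outcome + prev_valence + prev_value",
            rows,
            groups=rows["subject_id"],
            re_formula="1",
            vc_formula={"pv": "0 + prev_valence", "pval": "0 + prev_value"},
        )
        mf = md.fit(reml=True)
        assert np.allclose(fit.gamma_hat.to_numpy(), mf.fe_params.to_numpy(), atol=1e-2)
        assert fit.loglik == pytest.approx(mf.llf, abs=1e-3)

    def test_eb_equals_brute_force_blup(self, sim_fit):
        """BLUPs must equal the joint-Gaussian conditional mean computed
        from the full per-subject covariance at the fitted components."""
        rows, _, fit = sim_fit
        d = np.diag([fit.tau00_hat, fit.tau33_hat, fit.tau44_hat])
        gamma = fit.gamma_hat.to_numpy()
        for sid in fit.eb_valence.index[::7]:
            grp = rows[rows["subject_id"] == sid]
            x = np.column_stack(
                [np.ones(len(grp)), grp["trial_number"], grp["current_outcome"],
                 grp["prev_valence"], grp["prev_value"]]
            )
            z = x[:, [0, 3, 4]]
            v = fit.sigma2_hat * np.eye(len(grp)) + z @ d @ z.T
            u = d @ z.T @ np.linalg.solve(v, grp["pumps"].to_numpy() - x @ gamma)
            assert fit.eb_valence[sid] == pytest.approx(gamma[3] + u[1], abs=1e-6)
            assert fit.eb_value[sid] == pytest.approx(gamma[4] + u[2], abs=1e-6)

    def test_objective_not_worse_than_start_or_perturbations(self, sim_fit):
        rows, _, fit = sim_fit
        ss = behavior._Suffstats(rows)
        theta_hat = np.array([fit.tau00_hat, fit.tau33_hat, fit.tau44_hat]) / fit.sigma2_hat
        best = behavior._criterion(theta_hat, ss, True)
        assert best <= behavior._criterion(np.array([1.0, 0.25, 0.25]), ss, True) + 1e-8
        rng = np.random.default_rng(0)
        for _ in range(5):
            theta = np.abs(theta_hat + rng.normal(0, 0.1, 3))
            assert best <= behavior._criterion(theta, ss, True) + 1e-8

    def test_ml_flag_gives_different_but_close_estimates(self, sim_fit):
        rows, _, reml_fit = sim_fit
        ml_fit = fit_mixed_model(rows, reml=False)
        assert ml_fit.loglik != reml_fit.loglik
        assert np.allclose(
            ml_fit.gamma_hat.to_numpy(), reml_fit.gamma_hat.to_numpy(), atol=0.05
        )

    def test_random_slopes_zero_matches_brute_force_gls(self):
        """With (near-)zero slope variances the fixed effects must equal
        the random-intercept GLS solution computed from scratch."""
        rows, _ = synth.simulate_learning_rows(GAMMA, 1.0, 0.0, 0.0, 1.0, 30, 24, seed=5)
        fit = fit_mixed_model(rows)
        xs, vs, ys = [], [], []
        lhs = np.zeros((5, 5))
        rhs = np.zeros(5)
        d = np.diag([fit.tau00_hat, fit.tau33_hat, fit.tau44_hat])
        for _, grp in rows.groupby("subject_id"):
            x = np.column_stack(
                [np.ones(len(grp)), grp["trial_number"], grp["current_outcome"],
                 grp["prev_valence"], grp["prev_value"]]
            )
            z = x[:, [0, 3, 4]]
            v = fit.sigma2_hat * np.eye(len(grp)) + z @ d @ z.T
            vi_x = np.linalg.solve(v, x)
            lhs += x.T @ vi_x
            rhs += vi_x.T @ grp["pumps"].to_numpy()
        gamma_gls = np.linalg.solve(lhs, rhs)
        assert np.allclose(fit.gamma_hat.to_numpy(), gamma_gls, atol=1e-6)

    def test_boundary_flagged_when_no_slope_variance(self):
        rows, _ = synth.simulate_learning_rows(GAMMA, 1.0, 0.0, 0.0, 1.0, 30, 24, seed=5)
        fit = fit_mixed_model(rows)
        assert fit.boundary["tau33"] or fit.tau33_hat < 0.02

    def test_errors_on_degenerate_inputs(self):
        rows, _ = synth.simulate_learning_rows(GAMMA, 1.0, 0.25, 0.25, 1.0, 1, 24, seed=0)
        with pytest.raises(ValueError, match="2 subjects"):
            fit_mixed_model(rows)


class TestShrinkage:
    def test_exact_conditional_shrinkage_theorem(self):
        """Each BLUP equals k times the conditional unpooled estimate with
        k strictly inside (0, 1): u_i = tau_i z_i'(r - Z u)/sigma2, the
        mixed-model normal equations."""
        rows, _ = synth.simulate_learning_rows(GAMMA, 1.0, 0.25, 0.25, 1.0, 30, 24, seed=2)
        fit = fit_mixed_model(rows)
        gamma = fit.gamma_hat.to_numpy()
        tau = np.array([fit.tau00_hat, fit.tau33_hat, fit.tau44_hat])
        for j, sid in enumerate(fit.random_effects["subject_id"]):
            grp = rows[rows["subject_id"] == sid]
            x = np.column_stack(
                [np.ones(len(grp)), grp["trial_number"], grp["current_outcome"],
                 grp["prev_valence"], grp["prev_value"]]
            )
            z = x[:, [0, 3, 4]]
            u = fit.random_effects.iloc[j][["u0", "u3", "u4"]].to_numpy(float)
            r = grp["pumps"].to_numpy() - x @ gamma
            for i in range(3):
                zi = z[:, i]
                cond = zi @ (r - z @ u + zi * u[i]) / (zi @ zi)
                k = tau[i] * (zi @ zi) / (fit.sigma2_hat + tau[i] * (zi @ zi))
                assert u[i] == pytest.approx(k * cond, abs=1e-8)
                assert 0.0 < k < 1.0

    def test_no_pooling_limit_matches_unpooled_slopes(self):
        """BLUPs at imposed variances tau = 1e6 sigma2 (no pooling)
        equal the subject's own no-pooling slope estimates within 1%."""
        rows, _ = synth.simulate_learning_rows(
            GAMMA, 1.0, 0.25, 0.25, 1.0, 30, 24, seed=4
        )
        fit = fit_mixed_model(rows)
        g = fit.gamma_hat.to_numpy()
        big = 1e6 * fit.sigma2_hat
        eb = behavior.empirical_bayes_slopes(
            rows, g, fit.sigma2_hat, big, big, big
        ).set_index("subject_id")
        for sid in eb.index:
            grp = rows[rows["subject_id"] == sid]
            x = np.column_stack(
                [np.ones(len(grp)), grp["trial_number"], grp["current_outcome"],
                 grp["prev_valence"], grp["prev_value"]]
            )
            z = x[:, [0, 3, 4]]
            yp = grp["pumps"].to_numpy() - g[1] * x[:, 1] - g[2] * x[:, 2]
            b, *_ = np.linalg.lstsq(z, yp, rcond=None)
            unpooled_slope = b[1]
            if abs(unpooled_slope) > 0.5:
                eb_slope = g[3] + eb.loc[sid, "u3"]
                assert eb_slope == pytest.approx(unpooled_slope, rel=0.01)


class TestIndices:
    def test_extract_indices_keyed_by_subject(self, small_sessions):
        fit = fit_mixed_model(build_design_table(small_sessions))
        idx = extract_learning_indices(fit)
        assert list(idx.columns) == ["subject_id", "valence_sensitivity", "value_sensitivity"]
        assert len(idx) == 40
        assert idx["subject_id"].is_unique

    def test_coupled_study_eb_recovers_true_slopes(self):
        """With coupling 0.5, EB valence must track the true per-subject
        slope deviations (r >= 0.6 at n = 65, averaged over seeds)."""
        from dmnstab.config import TruthConfig

        rs = []
        for seed in range(20):
            bundle = synth.make_coupled_study(TruthConfig(), 65, (180, 300), seed=300 + seed)
            fit = fit_mixed_model(build_design_table(bundle.sessions))
            sub = bundle.subjects.set_index("subject_id")
            r = np.corrcoef(fit.eb_valence, sub.loc[fit.eb_valence.index, "u3"])[0, 1]
            rs.append(r)
        assert np.mean(rs) >= 0.6
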