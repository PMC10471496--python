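import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import make_population_state, simple_tensor
from optoprop import synth
from optoprop.metrics import (
    PopulationState,
    hit_rate_by_variance,
    outcome_contrast,
    prestim_population_metrics,
    select_transform,
    snr_logistic_model,
    snr_surface,
    variance_covariates,
    zscore_metrics,
)
from optoprop.session import TrialRecord


def go_trials(n, outcome="hit"):
    return [TrialRecord(trial_id=i, onset_frame=100 + 400 * i, trial_type="go",
                        n_targets=10, targeted_cell_ids=list(range(10)),
                        outcome=outcome, stim_duration_ms=250.0)
            for i in range(n)]


class TestPrestimMetrics:
    def test_constant_cells(self):
        data = np.full((3, 4, 100), 0.2)
        state = prestim_population_metrics(simple_tensor(data, go_trials(3),
                                                         pre_frames=20))
        assert np.allclose(state.table.pop_mean, 0.2)
        assert np.allclose(state.table.pop_var, 0.0)

    def test_two_cell_sample_variance(self):
        data = np.zeros((1, 2, 100))
        data[0, 1, :] = 1.0
        state = prestim_population_metrics(simple_tensor(data, go_trials(1),
                                                         pre_frames=20))
        assert state.table.pop_var.iloc[0] == pytest.approx(0.5)   # ddof=1

    def test_uses_exactly_15_frames_at_30_hz(self):
        # value differs between the last 15 pre frames and the rest
        data = np.zeros((1, 3, 300))
        data[0, :, 45:60] = 1.0           # exactly frames -15..-1
        tensor = simple_tensor(data, go_trials(1), pre_frames=60)
        state = prestim_population_metrics(tensor, window_s=0.5)
        assert state.table.pop_mean.iloc[0] == pytest.approx(1.0)

    def test_blanked_pre_pad_frames_excluded(self):
        data = np.zeros((1, 3, 300))
        data[0, :, 43:58] = 1.0           # last 15 *unblanked* pre frames
        data[0, :, 58:60] = 99.0          # poisoned laser pad
        blank = np.zeros((1, 300), dtype=bool)
        blank[0, 58:70] = True
        tensor = simple_tensor(data, go_trials(1), pre_frames=60,
                               blank_mask=blank)
        state = prestim_population_metrics(tensor, window_s=0.5)
        assert state.table.pop_mean.iloc[0] == pytest.approx(1.0)

    def test_single_cell_rejected(self):
        data = np.zeros((2, 1, 100))
        with pytest.raises(ValueError, match="fewer than 2 cells"):
            prestim_population_metrics(simple_tensor(data, go_trials(2),
                                                     pre_frames=20))

    def test_variance_invariant_to_common_offset(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 6, 100))
        t1 = simple_tensor(data, go_trials(4), pre_frames=20)
        t2 = simple_tensor(data + 3.7, go_trials(4), pre_frames=20)
        s1 = prestim_population_metrics(t1).table
        s2 = prestim_population_metrics(t2).table
        assert np.allclose(s1.pop_var, s2.pop_var)
        assert np.allclose(s2.pop_mean - s1.pop_mean, 3.7)


class TestTransformSelection:
    def test_lognormal_draws_choose_log(self):
        x = np.exp(np.random.default_rng(1).standard_normal(5000))
        assert select_transform(x) == "log"

    def test_normal_draws_choose_identity(self):
        x = 10.0 + np.random.default_rng(2).standard_normal(5000)
        assert select_transform(x) == "identity"

    def test_constant_values_warn_identity(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert select_transform(np.full(100, 2.0)) == "identity"

    def test_nonpositive_values_force_identity(self):
        with pytest.warns(UserWarning, match="non-positive"):
            assert select_transform(np.array([-1.0, 1.0] * 50)) == "identity"


class TestZscore:
    def _state(self, values):
        trials = go_trials(len(values))
        return make_population_state(trials,
                                     {t.trial_id: v for t, v in zip(trials, values)},
                                     zscored=False)

    def test_two_values(self):
        out = zscore_metrics(self._state([1.0, 3.0]))
        assert np.allclose(sorted(out.table.z_pop_var),
                           [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_idempotent_on_standardized_input(self):
        vals = np.random.default_rng(3).standard_normal(50)
        vals = (vals - vals.mean()) / vals.std(ddof=1)
        out = zscore_metrics(self._state(list(vals)))
        assert np.allclose(out.table.z_pop_var, vals, atol=1e-10)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            zscore_metrics(self._state([1.0]))

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError, match="zero spread"):
            zscore_metrics(self._state([2.0, 2.0, 2.0]))


def _generated_states(model, n_sessions=8, n_trials=200, seed0=0):
    states = []
    for s in range(n_sessions):
        trials = synth.make_trial_schedule(n_trials, seed=seed0 + s)
        rng = np.random.default_rng(seed0 + 100 + s)
        prestim = {t.trial_id: float(rng.standard_normal())
                   for t in trials if t.trial_type == "go"}
        scored = synth.simulate_outcomes(trials, prestim, model,
                                         seed=seed0 + 200 + s)
        states.append(make_population_state(scored, prestim))
    return states


class TestOutcomeContrast:
    def test_variance_higher_before_miss_when_generated_so(self):
        model = synth.OutcomeModel(beta_logvar=-1.0)
        per, test = outcome_contrast(_generated_states(model))
        assert (per.miss_mean > per.hit_mean).mean() > 0.5
        assert test.pvalue < 0.05

    def test_mean_metric_shows_no_difference(self):
        model = synth.OutcomeModel(beta_logvar=-1.0)
        per, test = outcome_contrast(_generated_states(model), metric="z_pop_mean")
        # z_pop_mean is identically 0 in the generated tables -> no contrast
        assert test is None or test.pvalue > 0.05

    def test_identical_distributions_give_null(self):
        model = synth.OutcomeModel(beta_logvar=0.0)
        per, test = outcome_contrast(_generated_states(model, seed0=40))
        assert abs((per.miss_mean - per.hit_mean).median()) < 0.3


class TestHitRateByVariance:
    def test_negative_slope_detected(self):
        model = synth.OutcomeModel(beta_logvar=-1.0)
        [state] = _generated_states(model, n_sessions=1, n_trials=600)
        bins, slope, p = hit_rate_by_variance(state)
        assert slope < 0 and p < 0.05

    def test_independent_outcome_gives_flat_slope(self):
        model = synth.OutcomeModel(beta_logvar=0.0)
        [state] = _generated_states(model, n_sessions=1, n_trials=600, seed0=7)
        bins, slope, p = hit_rate_by_variance(state)
        assert p > 0.01

    def test_all_hits_give_zero_slope(self):
        trials = go_trials(60)
        state = make_population_state(
            trials, {t.trial_id: float(i) for i, t in enumerate(trials)})
        bins, slope, p = hit_rate_by_variance(state)
        assert np.allclose(bins.p_hit, 1.0) and slope == pytest.approx(0.0)

    def test_small_bins_merged(self):
        trials = go_trials(26)
        state = make_population_state(
            trials, {t.trial_id: float(i) for i, t in enumerate(trials)})
        bins, _, _ = hit_rate_by_variance(state, n_bins=5, min_per_bin=6)
        assert (bins.n >= 5).all()


class TestSnrSurface:
    def test_monotone_projection_with_active_model(self):
        model = synth.OutcomeModel()   # positive count, negative variance betas
        states = _generated_states(model, n_sessions=10, n_trials=300)
        grid, proj = snr_surface(states)
        rho = spearmanr(proj.snr, proj.p_hit).statistic
        assert rho > 0

    def test_single_occupied_bin_projection(self):
        trials = go_trials(30)
        state = make_population_state(trials, {t.trial_id: 0.0 for t in trials})
        grid, proj = snr_surface([state])
        assert len(proj) == 1 and proj.p_hit.iloc[0] == 1.0

    def test_count_only_dependence_keeps_projection_monotone(self):
        model = synth.OutcomeModel(beta0=-2.0, beta_ntargets=0.15,
                                   beta_logvar=0.0)
        states = _generated_states(model, n_sessions=10, n_trials=300, seed0=60)
        grid, proj = snr_surface(states)
        assert spearmanr(proj.snr, proj.p_hit).statistic > 0


class TestSnrModel:
    def test_known_coefficients_recovered(self):
        model = synth.OutcomeModel()
        states = _generated_states(model, n_sessions=10, n_trials=400)
        fit = snr_logistic_model(states)
        assert fit.beta_ntargets > 0 and fit.p_values["beta_ntargets"] < 1e-6
        assert fit.beta_popvar < 0 and fit.p_values["beta_popvar"] < 1e-3
        assert fit.beta_ntargets == pytest.approx(model.beta_ntargets, rel=0.3)

    def test_full_model_r2_dominates_single_regressors(self):
        states = _generated_states(synth.OutcomeModel(), n_sessions=6)
        fit = snr_logistic_model(states)
        assert fit.mcfadden_r2 >= fit.mcfadden_r2_ntargets_only - 1e-12
        assert fit.mcfadden_r2 >= fit.mcfadden_r2_popvar_only - 1e-12
        assert fit.mcfadden_r2 == pytest.approx(1 - fit.ll_model / fit.ll_null)

    def test_independent_labels_give_near_zero_r2(self):
        model = synth.OutcomeModel(beta0=0.0, beta_ntargets=0.0, beta_logvar=0.0)
        states = _generated_states(model, n_sessions=8, seed0=30)
        fit = snr_logistic_model(states)
        assert fit.mcfadden_r2 < 0.02

    def test_duplicated_regressor_rejected(self):
        trials = go_trials(50)
        state = make_population_state(
            trials, {t.trial_id: 10.0 for t in trials})   # z_pop_var constant
        state.table["z_pop_var"] = state.table["n_targets"] * 1.0
        with pytest.raises(ValueError, match="rank"):
            snr_logistic_model([state])


class TestVarianceCovariates:
    def test_shuffled_order_decorrelates_trial_index(self):
        rng = np.random.default_rng(5)
        trials = go_trials(200)
        vals = {t.trial_id: float(v) for t, v in zip(trials, rng.standard_normal(200))}
        state = make_population_state(trials, vals)
        out = variance_covariates(state)
        assert abs(out.loc[out.covariate == "trial_index", "r"].iloc[0]) < 0.2

    def test_paired_region_correlation_detected(self):
        rng = np.random.default_rng(6)
        trials = go_trials(200)
        base = rng.standard_normal(200)
        s1 = make_population_state(trials, {t.trial_id: float(b)
                                            for t, b in zip(trials, base)})
        s2 = make_population_state(trials, {t.trial_id: float(b + 0.3 * rng.standard_normal())
                                            for t, b in zip(trials, base)})
        out = variance_covariates(s1, other_region=s2)
        r = out.loc[out.covariate == "other_region", "r"].iloc[0]
        assert r > 0.8

    def test_constant_covariate_flagged(self):
        trials = go_trials(50)
        state = make_population_state(trials, {t.trial_id: 1.0 for t in trials})
        out = variance_covariates(state, recent_rewards=np.ones(50))
        assert (out.flag == "degenerate").any()
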