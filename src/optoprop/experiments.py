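"""Self-contained validation experiments on synthetic data.

Each experiment generates its own inputs with the synthetic-data module,
runs the corresponding analysis path end to end, and returns summary
numbers. They are what the test suite and the reproduction script execute;
problem sizes are chosen so the whole set runs in minutes on one CPU
(documented in docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from . import behavior, synth
from .metrics import snr_logistic_model
from .recurrence import (
    covariance_width,
    estimate_recurrence,
    fit_response_timescale,
    relate_timescale_recurrence,
    remove_shared_activity,
)
from .session import TrialRecord


def recurrence_recovery(
    R_values=(0.5, 0.8, 0.95),
    n_seeds: int = 10,
    N: int = 500,
    n_frames: int = 30_000,
    n_factors: int = 3,
    seed: int = 0,
) -> dict:
    """Spectral-bound recovery through the full estimation loop.

    For each R_true, simulate rate data from a linear recurrent network
    with shared input, remove shared activity by factor analysis, estimate
    the bias-corrected covariance width and invert for R. The networks use
    the zero-mean i.i.d. coupling ensemble the width theory describes
    (no collective mean-coupling mode). Returns per-R estimates and the
    median signed error over seeds.
    """
    out = {}
    for R in R_values:
        estimates = []
        for s in range(n_seeds):
            net = synth.NetworkConfig(N_cells=N, R_true=R, n_latent=1,
                                      shared_gain=0.5,
                                      uniform_coupling_frac=0.0)
            rates, _ = synth.simulate_rates(net, n_frames, seed=seed + 7919 * s,
                                            dtype=np.float32)
            dec = remove_shared_activity(rates, n_factors=n_factors,
                                         n_report_factors=n_factors,
                                         max_fit_frames=8000)
            scc, abar = covariance_width(dec.residuals)
            estimates.append(estimate_recurrence(scc, abar, N_assumed=N).R)
        estimates = np.asarray(estimates)
        out[R] = {
            "estimates": estimates,
            "median_R_hat": float(np.median(estimates)),
            "median_error": float(np.median(estimates - R)),
        }
    return out


def covariance_null_ratio(n_cells: int = 50, n_frames: int = 50_000,
                          seed: int = 0) -> float:
    """Bias-corrected width ratio on pure white noise (should be ~0)."""
    x = np.random.default_rng(seed).standard_normal((n_cells, n_frames))
    scc, abar = covariance_width(x)
    return float(scc / abar)


def _photostim_trial_block(N, n_trials, n_targets, rng, frame0=300,
                           spacing=330):
    trials, frame = [], frame0
    for i in range(n_trials):
        ids = sorted(int(j) for j in rng.choice(N, size=n_targets, replace=False))
        trials.append(TrialRecord(
            trial_id=i, onset_frame=frame, trial_type="go",
            n_targets=n_targets, targeted_cell_ids=ids,
            outcome="hit", stim_duration_ms=250.0))
        frame += spacing
    return trials, frame + 300


def timescale_grid(
    R_grid=(0.5, 0.6, 0.7, 0.8, 0.9, 0.95),
    N: int = 200,
    n_trials: int = 80,
    stim_amplitude: float = 40.0,
    n_subsamples: int = 100,
    seed: int = 0,
) -> dict:
    """Network response timescale across a recurrence grid + model comparison.

    Simulates photostimulation of 50-cell groups on each grid network,
    fits the exponential decay of the mean targeted-cell response on
    post-blanking frames, then compares tau = c/(1-R) against a linear
    regression.
    """
    pairs = []
    for i, R in enumerate(R_grid):
        rng = np.random.default_rng(seed + 131 * i)
        net = synth.NetworkConfig(N_cells=N, R_true=R, n_latent=1,
                                  shared_gain=0.3)
        trials, n_frames = _photostim_trial_block(N, n_trials, 50, rng)
        ext = synth.stim_input_matrix(
            (N, n_frames), trials,
            {t.trial_id: t.targeted_cell_ids for t in trials},
            stim_amplitude, synth.FRAME_RATE_HZ)
        rates, _ = synth.simulate_rates(net, n_frames, seed=seed + 131 * i + 1,
                                        ext_input=ext)
        fit = fit_response_timescale(
            rates, trials, synth.FRAME_RATE_HZ, {j: j for j in range(N)},
            seed=seed + 131 * i + 2, n_subsamples=n_subsamples,
            trials_per_subsample=15)
        pairs.append((R, fit.tau_post))
    comparison = relate_timescale_recurrence(pairs)
    comparison["pairs"] = pairs
    return comparison


def psychometric_recovery(n_seeds: int = 10, n_trials: int = 500,
                          seed: int = 0) -> dict:
    """Half-point recovery from schedule + outcome simulation alone."""
    model = synth.OutcomeModel()
    ref = synth.calibrate_outcome_model(model, n_trials=n_trials,
                                        seed=seed)["x50"]
    x50s = []
    for s in range(n_seeds):
        trials = synth.make_trial_schedule(n_trials, seed=seed + 31 * s)
        rng = np.random.default_rng(seed + 31 * s + 1)
        prestim = {t.trial_id: float(rng.standard_normal())
                   for t in trials if t.trial_type == "go"}
        scored = behavior.score_trials(
            synth.simulate_outcomes(trials, prestim, model,
                                    seed=seed + 31 * s + 2))
        summary = behavior.summarize_behavior(scored)
        fit = behavior.fit_psychometric(
            list(zip(summary.per_n_targets.n_targets,
                     summary.per_n_targets.dprime)))
        x50s.append(fit.x50)
    return {"x50_reference": float(ref), "x50_estimates": x50s,
            "median_x50": float(np.median(x50s)),
            "median_error": float(np.median(np.asarray(x50s) - ref))}


def _snr_states(model, n_sessions, n_trials, seed):
    import pandas as pd

    from .metrics import PopulationState
    states = []
    for s in range(n_sessions):
        trials = synth.make_trial_schedule(n_trials, seed=seed + 17 * s)
        rng = np.random.default_rng(seed + 17 * s + 1)
        prestim = {t.trial_id: float(rng.standard_normal())
                   for t in trials if t.trial_type == "go"}
        scored = synth.simulate_outcomes(trials, prestim, model,
                                         seed=seed + 17 * s + 2)
        tbl = pd.DataFrame({
            "trial_id": [t.trial_id for t in scored],
            "trial_type": [t.trial_type for t in scored],
            "outcome": [t.outcome for t in scored],
            "n_targets": [t.n_targets for t in scored],
            "pop_mean": 0.0,
            "pop_var": np.exp([prestim.get(t.trial_id, np.nan) for t in scored]),
            "pop_var_log": [prestim.get(t.trial_id, np.nan) for t in scored],
            "z_pop_var": [prestim.get(t.trial_id, np.nan) for t in scored],
            "z_pop_mean": 0.0,
        })
        states.append(PopulationState(table=tbl, transform="log", zscored=True))
    return states


def snr_recovery(n_sessions: int = 8, n_trials: int = 400, seed: int = 0) -> dict:
    """Logistic SNR model recovery on pooled generated sessions."""
    model = synth.OutcomeModel()
    states = _snr_states(model, n_sessions, n_trials, seed)
    fit = snr_logistic_model(states)
    n_go = int(sum(((s.table.trial_type == "go")
                    & s.table.outcome.isin(["hit", "miss"])).sum()
                   for s in states))
    return {"fit": fit, "true_beta_ntargets": model.beta_ntargets,
            "true_beta_logvar": model.beta_logvar, "n_go_trials": n_go}


def _decoding_tensor(n_per_class=24, n_cells=20, n_frames=30, seed=0,
                     signal=1.5, with_reward_only=False):
    from .preprocess import TrialTensor
    rng = np.random.default_rng(seed)
    labels = [("hit", "go")] * n_per_class \
        + [("correct_rejection", "catch")] * n_per_class
    if with_reward_only:
        labels += [("unscored", "reward_only")] * (n_per_class // 2)
    trials = []
    for i, (outcome, ttype) in enumerate(labels):
        trials.append(TrialRecord(
            trial_id=i, onset_frame=100 + 400 * i, trial_type=ttype,
            n_targets=10 if ttype == "go" else 0,
            targeted_cell_ids=list(range(10)) if ttype == "go" else [],
            outcome=outcome))
    data = rng.standard_normal((len(trials), n_cells, n_frames))
    pre = n_frames // 3
    hit_rows = [i for i, t in enumerate(trials) if t.outcome == "hit"]
    data[hit_rows, :6, pre:] += signal
    time_axis = (np.arange(n_frames) - pre) / 30.0
    return TrialTensor(data=data, time_axis_s=time_axis,
                       blank_mask=np.zeros((len(trials), n_frames), bool),
                       trials=trials, cell_ids=list(range(n_cells)),
                       frame_rate_hz=30.0, baselined=True), pre


def decoding_checks(seed: int = 0, n_permutations: int = 100) -> dict:
    """Chance level under label permutation; injected-signal dynamics;
    reward-only cross-evaluation."""
    from .decoding import cross_condition_evaluate, train_timepoint_decoders

    # permutation null at a single timepoint
    tensor, pre = _decoding_tensor(n_per_class=50, n_cells=10, n_frames=4,
                                   seed=seed, signal=0.0)
    rng = np.random.default_rng(seed)
    perm_accs = []
    for p in range(n_permutations):
        labels = np.array([t.outcome for t in tensor.trials])
        rng.shuffle(labels)
        for t, lab in zip(tensor.trials, labels):
            t.outcome = lab
        prof = train_timepoint_decoders(tensor, ("correct_rejection", "hit"),
                                        seed=seed + p, timepoints=[2])
        perm_accs.append(prof.accuracy[2])

    # injected post-stimulus signal + reward-only evaluation
    tensor, pre = _decoding_tensor(seed=seed + 1, with_reward_only=True)
    prof = train_timepoint_decoders(tensor, ("correct_rejection", "hit"),
                                    seed=seed)
    frac_ro = cross_condition_evaluate(prof, tensor, "reward_only")
    return {
        "permutation_mean_accuracy": float(np.mean(perm_accs)),
        "pre_accuracy": float(np.nanmean(prof.accuracy[:pre])),
        "post_accuracy": float(np.nanmean(prof.accuracy[pre:])),
        "reward_only_pre_fraction": float(np.nanmean(frac_ro[:pre])),
        "reward_only_post_fraction": float(np.nanmean(frac_ro[pre:])),
    }


def dprime_checks() -> dict:
    """Closed-form d' values and the antisymmetry identity."""
    return {
        "dprime_equal_rates": behavior.compute_dprime(0.5, 0.5),
        "dprime_one_sigma": behavior.compute_dprime(0.8413, 0.1587),
        "dprime_two_sigma": behavior.compute_dprime(0.9772, 0.5),
        "antisymmetry_residual": abs(
            behavior.compute_dprime(0.7, 0.2)
            + behavior.compute_dprime(0.2, 0.7)),
    }
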