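"""Synthetic session generator.

Emulates the statistical structure of a dual-region all-optical detection
experiment so that every analysis stage can be exercised without real data:

* linear recurrent population dynamics ``r[t+1] = W r[t] + shared + noise``
  with a controllable spectral bound ``R_true`` (the effective recurrence
  that the covariance-based estimator should recover),
* a low-dimensional AR(1) shared input standing in for global state
  fluctuations (arousal, motivation),
* additive photostimulation drive into targeted cells,
* GCaMP6s-like fluorescence rendering (Poisson spikes, difference-of-
  exponentials kernel, neuropil contamination, shot noise),
* the behavioral trial schedule (1/3 strong-go / 1/3 variable-go / 1/3
  catch, plus a pre-session reward-only block), and
* trial outcomes drawn from a logistic model of stimulus strength and
  pre-stimulus population variance.

Dynamics are discrete-time at the imaging frame rate: the downstream
covariance-width theory is formulated on the same linear map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .session import CellMeta, SessionData, TrialRecord

FRAME_RATE_HZ = 30.0
#: variable-count go trials draw the target count from this set
VARIABLE_TARGET_SET = (5, 10, 20, 30, 40, 50)
STIM_DURATION_MS = {"variable": 250.0, "strong": 760.0}


# ---------------------------------------------------------------------------
# configs

@dataclass
class NetworkConfig:
    """Linear recurrent network with spectral bound ``R_true``.

    With ``uniform_coupling_frac > 0`` a rank-one uniform (mean excitatory)
    component is added and tuned so the network's leading eigenvalue is
    real at exactly ``R_true`` — a slow collective mode whose decay time
    tracks the spectral bound, the substrate of the post-stimulation
    response timescale. The i.i.d. bulk is then shrunk to
    ``bulk_radius_frac * R_true`` to keep a spectral gap: without it the
    collective mode hybridizes with edge bulk modes into a complex
    (oscillating) pair. For the covariance-width estimator the collective
    mode behaves like shared activity (removed by factor analysis).
    """

    N_cells: int = 280
    R_true: float = 0.9
    n_latent: int = 2
    latent_ar_coeff: float = 0.9
    private_noise_sd: float = 1.0
    shared_gain: float = 0.7
    uniform_coupling_frac: float = 1.0
    bulk_radius_frac: float = 0.9
    dt_s: float = 1.0 / FRAME_RATE_HZ
    W: Optional[np.ndarray] = None

    def weights(self, seed: int) -> np.ndarray:
        if self.W is None:
            if self.uniform_coupling_frac > 0 and self.R_true > 0:
                bulk = make_connectivity(self.N_cells,
                                         self.bulk_radius_frac * self.R_true,
                                         seed)
                self.W = _add_tuned_uniform_mode(bulk, self.R_true)
            else:
                self.W = make_connectivity(self.N_cells, self.R_true, seed)
        return self.W


@dataclass
class CalciumConfig:
    """GCaMP6s-like forward model from rates to fluorescence."""

    kernel_rise_s: float = 0.18
    kernel_decay_s: float = 1.4
    baseline_F: float = 100.0
    gain: float = 20.0
    shot_noise_sd: float = 2.0
    neuropil_mix: float = 0.5
    spike_gain_hz: float = 3.0   # scales softplus(rate) into a Poisson intensity
    spike_bias: float = 0.0


@dataclass
class OutcomeModel:
    """P(hit) = logistic(beta0 + beta_ntargets * n + beta_logvar * v).

    ``v`` is the z-scored log population variance in the 0.5 s before
    stimulation. Defaults are calibrated by simulation (see
    ``calibrate_outcome_model``) so the synthetic psychometric 50% point
    lands near 22 targeted cells.
    """

    beta0: float = -2.0
    beta_ntargets: float = 0.15
    beta_logvar: float = -0.5
    fa_rate: float = 0.1

    def p_hit(self, n_targets, v):
        x = self.beta0 + self.beta_ntargets * np.asarray(n_targets, dtype=float) \
            + self.beta_logvar * np.asarray(v, dtype=float)
        return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SessionConfig:
    """Bundle of everything ``synthesize_session`` needs."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    calcium: CalciumConfig = field(default_factory=CalciumConfig)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    n_trials: int = 135
    frac_s1: float = 0.6
    n_target_candidates: int = 150
    stim_amplitude: float = 3.0
    frame_rate_hz: float = FRAME_RATE_HZ
    session_id: str = "synthetic"


def config_from_yaml(path) -> SessionConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    cfg = SessionConfig()
    if "network" in raw:
        cfg.network = NetworkConfig(**raw["network"])
    if "calcium" in raw:
        cfg.calcium = CalciumConfig(**raw["calcium"])
    if "outcome" in raw:
        cfg.outcome = OutcomeModel(**raw["outcome"])
    for key in ("n_trials", "frac_s1", "n_target_candidates", "stim_amplitude",
                "frame_rate_hz", "session_id"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


# ---------------------------------------------------------------------------
# network

def make_connectivity(N_cells: int, R_true: float, seed: int) -> np.ndarray:
    """I.i.d. Gaussian weights rescaled to spectral radius ``R_true``.

    ``R_true = 0`` returns the zero matrix; ``R_true >= 1`` is rejected
    because the linear dynamics would diverge.
    """
    if N_cells < 2:
        raise ValueError("need at least 2 cells")
    if not 0.0 <= R_true < 1.0:
        raise ValueError(f"R_true must be in [0, 1), got {R_true}")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((N_cells, N_cells)) / np.sqrt(N_cells)
    if R_true == 0.0:
        return np.zeros_like(W)
    radius = np.abs(np.linalg.eigvals(W)).max()
    return W * (R_true / radius)


def _add_tuned_uniform_mode(bulk: np.ndarray, R_target: float) -> np.ndarray:
    """Make the uniform vector an exact eigenvector with eigenvalue R_target.

    W = B + (R u - B u) u^T with u the normalized uniform vector: then
    W u = R u exactly (a real collective mode at the spectral bound),
    while the deflated spectrum stays at the bulk radius. If a bulk
    fluctuation still exceeds R_target, the bulk is shrunk slightly and
    the construction repeated.
    """
    N = bulk.shape[0]
    u = np.ones(N) / np.sqrt(N)
    for _ in range(8):
        W = bulk + np.outer(R_target * u - bulk @ u, u)
        radius = np.abs(np.linalg.eigvals(W)).max()
        if radius <= R_target + 1e-9:
            return W
        bulk = 0.97 * bulk
    return W


def simulate_rates(
    net: NetworkConfig,
    n_frames: int,
    seed: int,
    ext_input: Optional[np.ndarray] = None,
    divergence_bound: float = 1e6,
    dtype=np.float64,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the linear dynamics; returns (rates cells x frames, latent traces).

    ``r[t+1] = W r[t] + shared_gain * B f[t] + ext[t] + xi[t]`` with AR(1)
    latent ``f`` (n_latent dims, unit innovations) and i.i.d. Gaussian
    private noise. ``ext_input`` (cells x frames), if given, is injected as
    input so that perturbations relax through the network. Rates are in
    arbitrary units centered on zero.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    N = net.N_cells
    W = net.weights(seed)

    B = rng.standard_normal((N, net.n_latent)) / np.sqrt(N)
    phi = net.latent_ar_coeff
    # stationary-variance-normalized AR(1) latents
    innov = rng.standard_normal((net.n_latent, n_frames)) * np.sqrt(1.0 - phi**2)
    latent = np.empty((net.n_latent, n_frames))
    f = rng.standard_normal(net.n_latent)
    for t in range(n_frames):
        f = phi * f + innov[:, t]
        latent[:, t] = f

    shared_drive = net.shared_gain * (B @ latent) * np.sqrt(N)  # O(1) per-cell drive
    noise = rng.standard_normal((N, n_frames)) * net.private_noise_sd
    drive = noise + shared_drive
    if ext_input is not None:
        if ext_input.shape != (N, n_frames):
            raise ValueError("ext_input shape mismatch")
        drive = drive + ext_input

    drive = np.asarray(drive, dtype=dtype, order="F")
    Wd = np.asarray(W, dtype=dtype)
    rates = np.empty((N, n_frames), dtype=dtype, order="F")
    r = np.zeros(N, dtype=dtype)
    check_every = 256
    for t in range(n_frames):
        r = Wd @ r + drive[:, t]
        rates[:, t] = r
        if t % check_every == 0 and np.abs(r).max() > divergence_bound:
            raise FloatingPointError(
                f"rate dynamics diverged at frame {t} (|r| > {divergence_bound}); "
                f"check R_true={net.R_true} and input amplitudes"
            )
    if not np.all(np.isfinite(rates[:, -1])) or np.abs(rates[:, -1]).max() > divergence_bound:
        raise FloatingPointError(
            f"rate dynamics diverged (|r| > {divergence_bound}); "
            f"check R_true={net.R_true} and input amplitudes"
        )
    return rates, latent


# ---------------------------------------------------------------------------
# trial schedule

def make_trial_schedule(
    n_trials: int,
    frame_rate_hz: float = FRAME_RATE_HZ,
    seed: int = 0,
    reward_only_block: int = 10,
) -> list[TrialRecord]:
    """Pseudorandom schedule with outcomes left unscored.

    A pre-session block of ``reward_only_block`` reward-only trials at 10-s
    spacing, then ``n_trials`` drawn with probability 1/3 each from
    {strong go (150 targets), variable go (5..50 targets), catch}, with no
    more than three consecutive trials of the same trial_type. Consecutive
    onsets are separated by the 1-s response period, a fixed 5-s inter-trial
    interval and a 4-6-s uniform lick-withhold period.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    trial_id = 0

    frame = int(round(8.0 * frame_rate_hz))  # leave pre-trial history
    for _ in range(reward_only_block):
        trials.append(TrialRecord(
            trial_id=trial_id, onset_frame=frame, trial_type="reward_only",
            n_targets=0, reward_time_ms=0.0,
        ))
        trial_id += 1
        frame += int(round(10.0 * frame_rate_hz))

    # extra gap before active behavior
    frame += int(round(5.0 * frame_rate_hz))

    kind_seq = _constrained_kind_sequence(n_trials, rng)
    for kind in kind_seq:
        ttype = "catch" if kind == "catch" else "go"
        if kind == "strong":
            n_targets, dur = 150, STIM_DURATION_MS["strong"]
        elif kind == "variable":
            n_targets = int(rng.choice(VARIABLE_TARGET_SET))
            dur = STIM_DURATION_MS["variable"]
        else:
            n_targets, dur = 0, 0.0
        trials.append(TrialRecord(
            trial_id=trial_id, onset_frame=frame, trial_type=ttype,
            n_targets=n_targets, stim_duration_ms=dur,
        ))
        trial_id += 1
        withhold_s = rng.uniform(4.0, 6.0)
        frame += int(round((1.0 + 5.0 + withhold_s) * frame_rate_hz))
    return trials


def _constrained_kind_sequence(n_trials: int, rng) -> list[str]:
    """Trial kinds at exact 1/3 proportions, no run of > 3 equal trial_types.

    Draws without replacement from fixed per-kind pools, excluding kinds
    that would extend a go or catch run past three; rare dead ends (only
    the running type left) trigger a restart.
    """
    base = n_trials // 3
    counts = {"strong": base, "variable": base, "catch": n_trials - 2 * base}

    def completable(g, c, run_type, run):
        # remaining go (g) fits into the slots the remaining catches open,
        # and vice versa, under the max-run-3 constraint
        cap_go = 3 * c + (3 - run if run_type == "go" else 3)
        cap_catch = 3 * g + (3 - run if run_type == "catch" else 3)
        return g <= cap_go and c <= cap_catch

    seq: list[str] = []
    run_type, run = None, 0
    for _ in range(n_trials):
        allowed = []
        for k, cnt in counts.items():
            if cnt == 0:
                continue
            ttype = "catch" if k == "catch" else "go"
            new_run = run + 1 if ttype == run_type else 1
            if new_run > 3:
                continue
            g = counts["strong"] + counts["variable"] - (ttype == "go")
            c = counts["catch"] - (ttype == "catch")
            if completable(g, c, ttype, new_run):
                allowed.append(k)
        weights = np.array([counts[k] for k in allowed], dtype=float)
        kind = allowed[int(rng.choice(len(allowed), p=weights / weights.sum()))]
        counts[kind] -= 1
        ttype = "catch" if kind == "catch" else "go"
        run = run + 1 if ttype == run_type else 1
        run_type = ttype
        seq.append(kind)
    return seq


def stim_frame_count(stim_duration_ms: float, frame_rate_hz: float) -> int:
    return int(np.ceil(stim_duration_ms / 1000.0 * frame_rate_hz))


def apply_photostim(
    rates: np.ndarray,
    trials: Sequence[TrialRecord],
    targets_per_trial: dict[int, Sequence[int]],
    stim_amplitude: float,
    frame_rate_hz: float = FRAME_RATE_HZ,
    cell_index: Optional[dict[int, int]] = None,
) -> np.ndarray:
    """Additive rate injection into targeted rows during each stim window.

    ``targets_per_trial`` maps trial_id -> targeted cell ids; ``cell_index``
    maps cell id -> row (identity if omitted). Raises if a stimulation
    window overlaps the previous trial's window.
    """
    out = rates.copy()
    n_frames = rates.shape[1]
    prev_end = -1
    for t in trials:
        if t.n_targets == 0 or t.stim_duration_ms <= 0:
            continue
        nf = stim_frame_count(t.stim_duration_ms, frame_rate_hz)
        start, end = t.onset_frame, min(t.onset_frame + nf, n_frames)
        if start < prev_end:
            raise ValueError(
                f"trial {t.trial_id}: stim window starting at frame {start} "
                f"overlaps previous window ending at {prev_end}"
            )
        ids = targets_per_trial.get(t.trial_id, t.targeted_cell_ids)
        rows = [cell_index[i] if cell_index else i for i in ids]
        out[np.asarray(rows, dtype=int), start:end] += stim_amplitude
        prev_end = end
    return out


def stim_input_matrix(
    shape: tuple[int, int],
    trials: Sequence[TrialRecord],
    targets_per_trial: dict[int, Sequence[int]],
    stim_amplitude: float,
    frame_rate_hz: float = FRAME_RATE_HZ,
    cell_index: Optional[dict[int, int]] = None,
) -> np.ndarray:
    """Photostimulation drive as an external-input matrix for the dynamics."""
    return apply_photostim(
        np.zeros(shape), trials, targets_per_trial, stim_amplitude,
        frame_rate_hz, cell_index,
    )


# ---------------------------------------------------------------------------
# calcium rendering

def calcium_kernel(rise_s: float, decay_s: float, frame_rate_hz: float,
                   duration_s: float = 10.0) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak."""
    if decay_s <= rise_s:
        raise ValueError("decay must exceed rise")
    t = np.arange(int(round(duration_s * frame_rate_hz))) / frame_rate_hz
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def render_fluorescence(
    rates: np.ndarray,
    cal: CalciumConfig,
    seed: int,
    frame_rate_hz: float = FRAME_RATE_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Render (F_soma, F_neuropil) from a rate matrix.

    Spikes are Poisson with intensity ``spike_gain_hz * softplus(rate +
    spike_bias)``; spike trains are convolved with the indicator kernel.
    The soma channel carries the cell's own transient plus
    ``neuropil_mix`` of the population-average signal (contamination);
    the neuropil channel measures that contamination with independent noise.
    """
    if not np.all(np.isfinite(rates)):
        raise ValueError("rates must be finite")
    rng = np.random.default_rng(seed)
    n_cells, n_frames = rates.shape
    dt = 1.0 / frame_rate_hz
    lam = cal.spike_gain_hz * np.logaddexp(0.0, rates + cal.spike_bias)  # softplus
    spikes = rng.poisson(lam * dt).astype(float)

    kernel = calcium_kernel(cal.kernel_rise_s, cal.kernel_decay_s, frame_rate_hz)
    from scipy.signal import fftconvolve
    conv = fftconvolve(spikes, kernel[None, :], axes=1)[:, :n_frames]

    signal = cal.gain * conv
    pop = signal.mean(axis=0)
    F_soma = cal.baseline_F + signal + cal.neuropil_mix * pop[None, :]
    F_neuropil = cal.baseline_F + np.tile(cal.neuropil_mix * pop, (n_cells, 1))
    if cal.shot_noise_sd > 0:
        F_soma = F_soma + rng.standard_normal(F_soma.shape) * cal.shot_noise_sd
        F_neuropil = F_neuropil + rng.standard_normal(F_neuropil.shape) * cal.shot_noise_sd
    return F_soma, F_neuropil


# ---------------------------------------------------------------------------
# outcomes

def simulate_outcomes(
    trials: Sequence[TrialRecord],
    prestim_logvar: dict[int, float],
    model: OutcomeModel,
    seed: int,
) -> list[TrialRecord]:
    """Score a schedule with Bernoulli outcomes from the logistic model.

    Go trials are hit with P = logistic(beta0 + beta_ntargets*n +
    beta_logvar*v); catch trials are false positives at the model's base
    rate. Responders lick uniformly in 150-1000 ms; hits are rewarded at
    the lick time.
    """
    rng = np.random.default_rng(seed)
    out = []
    for t in trials:
        t = TrialRecord(**{**t.__dict__})
        if t.trial_type == "go":
            if t.trial_id not in prestim_logvar:
                raise ValueError(f"missing prestim_logvar for go trial {t.trial_id}")
            p = float(model.p_hit(t.n_targets, prestim_logvar[t.trial_id]))
            if rng.uniform() < p:
                t.outcome = "hit"
                t.first_lick_ms = float(rng.uniform(150.0, 1000.0))
                t.reward_time_ms = t.first_lick_ms
            else:
                t.outcome = "miss"
                t.first_lick_ms = None
        elif t.trial_type == "catch":
            if rng.uniform() < model.fa_rate:
                t.outcome = "false_positive"
                t.first_lick_ms = float(rng.uniform(150.0, 1000.0))
            else:
                t.outcome = "correct_rejection"
                t.first_lick_ms = None
        else:  # reward_only
            t.outcome = "unscored"
            t.reward_time_ms = 0.0
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# full session

def synthesize_session(config: Optional[SessionConfig] = None, seed: int = 0) -> SessionData:
    """Generate a complete synthetic session, deterministic given ``seed``."""
    cfg = config or SessionConfig()
    rng = np.random.default_rng(seed)
    net, cal = cfg.network, cfg.calcium
    N = net.N_cells
    fr = cfg.frame_rate_hz

    n_s1 = int(round(cfg.frac_s1 * N))
    if cfg.n_target_candidates > n_s1:
        raise ValueError("more target candidates than S1 cells")
    cells = []
    cand = set(rng.choice(n_s1, size=cfg.n_target_candidates, replace=False).tolist())
    for i in range(N):
        in_s1 = i < n_s1
        is_cand = i in cand
        cells.append(CellMeta(
            cell_id=i,
            region="S1" if in_s1 else "S2",
            x_um=float(rng.uniform(0, 700) if in_s1 else rng.uniform(700, 1400)),
            y_um=float(rng.uniform(0, 700)),
            min_target_distance_um=float(rng.uniform(0, 15) if is_cand
                                         else rng.uniform(20, 300)),
            is_target_candidate=is_cand,
        ))
    cand_ids = sorted(cand)

    trials = make_trial_schedule(cfg.n_trials, fr, seed=seed + 1)
    targets_per_trial = {}
    for t in trials:
        if t.n_targets > 0:
            chosen = rng.choice(cand_ids, size=t.n_targets, replace=False)
            t.targeted_cell_ids = sorted(int(i) for i in chosen)
            targets_per_trial[t.trial_id] = t.targeted_cell_ids

    n_frames = trials[-1].onset_frame + int(round(10.0 * fr))
    ext = stim_input_matrix((N, n_frames), trials, targets_per_trial,
                            cfg.stim_amplitude, fr)
    rates, _ = simulate_rates(net, n_frames, seed=seed + 2, ext_input=ext)

    # pre-stimulus log population variance, z-scored across go trials
    pre = int(round(0.5 * fr))
    logvars, go_ids = [], []
    for t in trials:
        if t.trial_type == "go":
            win = rates[:, t.onset_frame - pre:t.onset_frame]
            logvars.append(np.log(win.mean(axis=1).var(ddof=1)))
            go_ids.append(t.trial_id)
    logvars = np.asarray(logvars)
    z = (logvars - logvars.mean()) / logvars.std(ddof=1)
    prestim = dict(zip(go_ids, z))

    trials = simulate_outcomes(trials, prestim, cfg.outcome, seed=seed + 3)
    F_soma, F_neuropil = render_fluorescence(rates, cal, seed=seed + 4, frame_rate_hz=fr)

    return SessionData(
        F_soma=F_soma, F_neuropil=F_neuropil, cells=cells, trials=trials,
        frame_rate_hz=fr, session_id=f"{cfg.session_id}-{seed}",
    )


def calibrate_outcome_model(
    model: OutcomeModel,
    n_trials: int = 500,
    n_mc: int = 200_000,
    seed: int = 0,
) -> dict:
    """Analytic psychometric reference of an OutcomeModel under the schedule.

    Computes the exact expected hit rate per target count (marginalizing
    the variance covariate over its standard-normal reference
    distribution by Monte Carlo), applies the identical d' pipeline —
    including the extreme-rate correction at the expected per-condition
    trial counts of an ``n_trials``-trial schedule — and fits the
    psychometric function to these noiseless points. The returned ``x50``
    is the half-point a session of that size estimates, free of sampling
    noise. Used to choose defaults such that the synthetic psychometric
    50% point lands near 22 targets.
    """
    from scipy.stats import norm
    from .behavior import fit_psychometric
    v = np.random.default_rng(seed).standard_normal(n_mc)
    counts = tuple(VARIABLE_TARGET_SET) + (150,)
    c150 = n_trials / 3.0
    cvar = n_trials / (3.0 * len(VARIABLE_TARGET_SET))
    ncatch = n_trials / 3.0
    fa = min(max(model.fa_rate, 1.0 / (2 * ncatch)), 1.0 - 1.0 / (2 * ncatch))
    points = []
    hit = {}
    for n in counts:
        h = float(model.p_hit(n, v).mean())
        hit[n] = h
        c = c150 if n == 150 else cvar
        h = min(max(h, 1.0 / (2 * c)), 1.0 - 1.0 / (2 * c))
        points.append((n, norm.ppf(h) - norm.ppf(fa)))
    fit = fit_psychometric(points)
    return {"hit_rate": hit, "points": points, "dmax": fit.dmax,
            "k": fit.k, "x50": fit.x50}
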