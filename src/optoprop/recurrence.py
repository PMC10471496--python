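"""Effective recurrence from non-shared covariance width; response timescale.

The estimator treats the population as a linear recurrent network observed
at the frame rate, ``r[t+1] = W r[t] + input``, with i.i.d. random coupling
of spectral bound R < 1. Three steps:

1. Latent factor analysis splits activity into a low-dimensional *shared*
   component (putative common external input) and *non-shared* residuals.
2. From the residuals, the width sigma_CC of the off-diagonal
   cross-covariance distribution and the mean variance abar are estimated.
   Finite recordings inflate the raw width with estimation noise, so the
   width is bias-corrected by a split-half product: covariances computed on
   two disjoint temporal halves have independent noise, and the
   cross-product of their off-diagonal entries isolates the true width.
3. The ratio delta = sigma_CC / abar is inverted for R. For the linear map
   with i.i.d. Gaussian coupling (entry variance R^2/N), summing the
   leading-order path pairings of the stationary covariance
   C = sum_k W^k (W^T)^k gives

       abar      = sigma_in^2 / (1 - R^2)
       sigma_CC^2 = sigma_in^2 ** 2 * R^4 / (N (1-R^4) (1-R^2)^2)

   hence  delta^2 = R^4 / (N (1 - R^4))  and the closed-form inversion

       R = ( N delta^2 / (1 + N delta^2) ) ** (1/4).

   A simulation-calibrated inversion table (exact stationary covariances
   from the discrete Lyapunov equation on an R grid) is shipped as an
   independent cross-check; at moderate network sizes it also captures the
   finite-size offset between the realized spectral radius and the
   ensemble bound.

Wider cross-covariance distributions therefore mean stronger effective
recurrence; R -> 1 is the near-unstable, strongly amplifying regime.

The complementary *network response timescale* tau_post is the exponential
decay time of the targeted cells' mean response after photostimulation;
for the same linear model the slowest mode decays with
tau_post ~ 1 / (1 - R).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_discrete_lyapunov
from scipy.optimize import curve_fit
from scipy import stats
from sklearn.decomposition import FactorAnalysis

from .session import TrialRecord
from .synth import stim_frame_count

SEGMENT_LENGTH_S = 6.5
TRIALS_PER_SUBSAMPLE = 15
N_SUBSAMPLES = 1000
N_ASSUMED_DEFAULT = 50_000
TAU_RESPONSE_WINDOW_S = 5.5
TAU_BASELINE_WINDOW_S = 6.5
TAU_TRIALS_PER_SUBSAMPLE = 10


@dataclass
class PretrialSegmentSet:
    """Concatenated pre-trial activity for one subsample draw."""

    segments: list[np.ndarray]            # one cells x frames matrix per subsample
    condition: str
    segment_length_s: float = SEGMENT_LENGTH_S
    trials_per_subsample: int = TRIALS_PER_SUBSAMPLE


@dataclass
class SharedActivityDecomposition:
    n_factors: int
    factor_variance_explained: np.ndarray  # non-increasing shares of total variance
    shared_component: np.ndarray           # cells x frames
    residuals: np.ndarray                  # cells x frames, input - shared
    factor_scores: np.ndarray              # n_factors x frames


@dataclass
class RecurrenceEstimate:
    R: float
    sigma_cc: float
    abar: float
    N_assumed: int
    per_subsample: np.ndarray = field(default_factory=lambda: np.empty(0))
    clamped: bool = False


@dataclass
class TimescaleFit:
    tau_post: float
    A: float
    fit_r2: float
    per_subsample: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_failed: int = 0
    flagged: bool = False


# ---------------------------------------------------------------------------
# segments

def session_blank_mask(trials: Sequence[TrialRecord], n_frames: int,
                       frame_rate_hz: float, pad: int = 2) -> np.ndarray:
    """Boolean mask over session frames that are laser-contaminated."""
    mask = np.zeros(n_frames, dtype=bool)
    for t in trials:
        if t.stim_duration_ms > 0 and t.trial_type == "go":
            nstim = stim_frame_count(t.stim_duration_ms, frame_rate_hz)
            a = max(t.onset_frame - pad, 0)
            b = min(t.onset_frame + nstim + pad, n_frames)
            mask[a:b] = True
    return mask


def _condition_trials(trials: Sequence[TrialRecord], condition: str) -> list[TrialRecord]:
    if condition == "all":
        return [t for t in trials if t.trial_type == "go"]
    return [t for t in trials if t.outcome == condition]


def extract_pretrial_segments(
    activity: np.ndarray,
    trials: Sequence[TrialRecord],
    frame_rate_hz: float,
    condition: str = "all",
    seed: int = 0,
    n_subsamples: int = N_SUBSAMPLES,
    trials_per_subsample: int = TRIALS_PER_SUBSAMPLE,
    segment_length_s: float = SEGMENT_LENGTH_S,
) -> PretrialSegmentSet:
    """Concatenate pre-trial activity windows for repeated subsampling.

    For each subsample, ``trials_per_subsample`` trials of the condition
    are drawn without replacement (with replacement across subsamples) and
    their ``segment_length_s`` pre-onset windows concatenated. Trials whose
    window leaves the recording or touches a laser-blanked frame are
    excluded up front. Raises if fewer eligible trials than one subsample
    needs.
    """
    rng = np.random.default_rng(seed)
    n_frames = activity.shape[1]
    blank = session_blank_mask(trials, n_frames, frame_rate_hz)
    seg = int(round(segment_length_s * frame_rate_hz))

    eligible = []
    for t in _condition_trials(trials, condition):
        # end the window just before any pre-onset laser pad so segments
        # never touch blanked frames
        end = t.onset_frame
        while end > 0 and blank[end - 1]:
            end -= 1
        lo = end - seg
        if lo < 0:
            continue
        if blank[lo:end].any():
            continue
        eligible.append((t, lo, end))
    if len(eligible) < trials_per_subsample:
        raise ValueError(
            f"condition {condition!r}: only {len(eligible)} eligible trials, "
            f"need {trials_per_subsample}"
        )
    segments = []
    for _ in range(n_subsamples):
        pick = rng.choice(len(eligible), size=trials_per_subsample, replace=False)
        windows = [activity[:, eligible[i][1]:eligible[i][2]] for i in sorted(pick)]
        segments.append(np.concatenate(windows, axis=1))
    return PretrialSegmentSet(segments=segments, condition=condition,
                              segment_length_s=segment_length_s,
                              trials_per_subsample=trials_per_subsample)


# ---------------------------------------------------------------------------
# shared-activity removal

def remove_shared_activity(segments: np.ndarray, n_factors: int = 3,
                           n_report_factors: int = 5,
                           max_restarts: int = 3,
                           max_fit_frames: Optional[int] = None,
                           ) -> SharedActivityDecomposition:
    """Maximum-likelihood factor analysis; residuals are the non-shared activity.

    ``segments`` is cells x frames. Loadings are estimated by ML factor
    analysis (optionally on an evenly strided subset of at most
    ``max_fit_frames`` frames — the loadings need far fewer samples than
    the covariance statistics downstream); per-factor variance-explained
    shares (of total variance) are reported for up to
    ``n_report_factors`` factors, ordered non-increasing.
    """
    n_cells, n_frames = segments.shape
    if n_cells < 10:
        raise ValueError("factor analysis needs at least 10 cells")
    if n_frames <= n_factors:
        raise ValueError("need more frames than factors")
    X = segments.T                                     # samples x features
    mean = X.mean(axis=0)
    X_fit = X
    if max_fit_frames is not None and n_frames > max_fit_frames:
        X_fit = X[:: int(np.ceil(n_frames / max_fit_frames))]
    k_fit = max(n_factors, min(n_report_factors, n_cells - 1))
    last_err: Exception | None = None
    for attempt in range(max_restarts):
        try:
            fa = FactorAnalysis(n_components=k_fit, random_state=attempt, max_iter=2000)
            scores = fa.fit_transform(X_fit)
            break
        except Exception as err:   # pragma: no cover - rare numerical failure
            last_err = err
    else:   # pragma: no cover
        raise RuntimeError(f"factor analysis failed after {max_restarts} restarts: {last_err}")

    loadings = fa.components_                          # k x cells
    total_var = X_fit.var(axis=0, ddof=0).sum()
    per_factor = np.array([
        (np.var(scores[:, j], ddof=0) * np.sum(loadings[j] ** 2)) / total_var
        for j in range(k_fit)
    ])
    order = np.argsort(per_factor)[::-1]
    per_factor = per_factor[order]
    loadings = loadings[order]
    scores = scores[:, order]

    # reconstruct the shared component by orthogonal projection onto the
    # estimated factor subspace (posterior-mean scores are shrunk by the
    # factor posterior covariance and would leave shared leakage in the
    # residuals, which the covariance-width step must not see)
    L = loadings[:n_factors].T                        # cells x k
    Xc = segments - mean[:, None]
    proj_scores, *_ = np.linalg.lstsq(L, Xc, rcond=None)   # k x frames
    shared = L @ proj_scores
    residuals = Xc - shared
    return SharedActivityDecomposition(
        n_factors=n_factors,
        factor_variance_explained=per_factor[:n_report_factors],
        shared_component=shared,
        residuals=residuals,
        factor_scores=proj_scores,
    )


def nonshared_pairwise_stats(residuals: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """(mean off-diagonal correlation, correlation matrix, covariance matrix).

    Zero-variance cells are excluded with a warning.
    """
    if residuals.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    v = residuals.var(axis=1)
    keep = v > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance cells")
        residuals = residuals[keep]
    corr = np.corrcoef(residuals)
    cov = np.cov(residuals)
    off = ~np.eye(corr.shape[0], dtype=bool)
    return float(corr[off].mean()), corr, cov


# ---------------------------------------------------------------------------
# covariance width with split-half bias correction

def covariance_width(residuals: np.ndarray) -> tuple[float, float]:
    """Bias-corrected width of the off-diagonal cross-covariances, and abar.

    ``abar`` is the mean variance (diagonal of the full-data covariance).
    The raw off-diagonal spread mixes the true cross-covariance width with
    finite-sample estimation noise; covariances from two disjoint temporal
    halves carry independent noise, so the mean centered cross-product of
    their off-diagonal entries estimates the squared true width. Negative
    corrected values (correction exceeding the raw width) floor at zero.
    """
    n_cells, n_frames = residuals.shape
    if n_cells < 2 or n_frames < 4:
        raise ValueError("too little data for covariance width")
    half = n_frames // 2
    ca = np.cov(residuals[:, :half])
    cb = np.cov(residuals[:, half:])
    abar = float(np.mean(residuals.var(axis=1, ddof=1)))
    off = ~np.eye(n_cells, dtype=bool)
    a, b = ca[off], cb[off]
    s2 = float(np.mean((a - a.mean()) * (b - b.mean())))
    return float(np.sqrt(max(s2, 0.0))), abar


# ---------------------------------------------------------------------------
# inversion: closed form and simulation-calibrated table

def width_from_spectral_bound(R, N: int):
    """Forward relation delta^2 = R^4 / (N (1 - R^4)) for the linear map."""
    R = np.asarray(R, dtype=float)
    return R**4 / (N * (1.0 - R**4))


def spectral_bound_from_width(delta2, N: int):
    """Closed-form inversion R = (N d2 / (1 + N d2))^(1/4)."""
    d2 = np.maximum(np.asarray(delta2, dtype=float), 0.0)
    return (N * d2 / (1.0 + N * d2)) ** 0.25


@dataclass
class InversionTable:
    """Monotone delta^2(R) lookup calibrated by exact Lyapunov covariances."""

    R_grid: np.ndarray
    delta2: np.ndarray
    N: int

    def invert(self, delta2: float) -> tuple[float, bool]:
        d2 = max(float(delta2), 0.0)
        mono = np.maximum.accumulate(self.delta2)
        if d2 >= mono[-1]:
            return float(self.R_grid[-1]), True
        return float(np.interp(d2, mono, self.R_grid)), False


def calibration_table(N: int, R_grid: Optional[np.ndarray] = None,
                      n_seeds: int = 3, seed: int = 0) -> InversionTable:
    """Measure delta^2(R) on an R grid from exact stationary covariances.

    For each grid point, i.i.d. Gaussian coupling matrices rescaled to
    spectral radius R are drawn and the discrete Lyapunov equation
    C = W C W^T + I solved exactly, so the table carries no sampling noise
    from finite recordings (only ensemble spread, reduced by averaging
    over ``n_seeds`` draws).
    """
    from .synth import make_connectivity
    if R_grid is None:
        R_grid = np.arange(0.0, 0.9951, 0.005)
    deltas = np.zeros(len(R_grid))
    for i, R in enumerate(R_grid):
        if R == 0:
            continue
        vals = []
        for s in range(n_seeds):
            W = make_connectivity(N, float(R), seed + 1000 * i + s)
            C = solve_discrete_lyapunov(W, np.eye(N))
            off = C[~np.eye(N, dtype=bool)]
            vals.append((off.std() / np.mean(np.diag(C))) ** 2)
        deltas[i] = np.mean(vals)
    return InversionTable(R_grid=np.asarray(R_grid, dtype=float), delta2=deltas, N=N)


def estimate_recurrence(sigma_cc: float, abar: float,
                        N_assumed: int = N_ASSUMED_DEFAULT,
                        table: Optional[InversionTable] = None) -> RecurrenceEstimate:
    """Invert the width ratio for R (closed form, or a calibration table)."""
    if abar <= 0:
        raise ValueError("abar must be positive")
    if sigma_cc < 0:
        raise ValueError("sigma_cc must be non-negative")
    d2 = (sigma_cc / abar) ** 2
    if table is not None:
        R, clamped = table.invert(d2)
    else:
        R, clamped = float(spectral_bound_from_width(d2, N_assumed)), False
    return RecurrenceEstimate(R=R, sigma_cc=sigma_cc, abar=abar,
                              N_assumed=N_assumed, clamped=clamped)


def estimate_recurrence_from_activity(
    activity: np.ndarray,
    trials: Sequence[TrialRecord],
    frame_rate_hz: float,
    condition: str = "all",
    seed: int = 0,
    n_subsamples: int = 100,
    n_factors: int = 1,
    N_assumed: int = N_ASSUMED_DEFAULT,
    table: Optional[InversionTable] = None,
) -> RecurrenceEstimate:
    """Full per-session estimator: subsample -> factor removal -> width -> R."""
    segs = extract_pretrial_segments(activity, trials, frame_rate_hz, condition,
                                     seed=seed, n_subsamples=n_subsamples)
    Rs, sccs, abars = [], [], []
    for seg in segs.segments:
        dec = remove_shared_activity(seg, n_factors=n_factors)
        scc, abar = covariance_width(dec.residuals)
        est = estimate_recurrence(scc, abar, N_assumed, table=table)
        Rs.append(est.R)
        sccs.append(scc)
        abars.append(abar)
    return RecurrenceEstimate(
        R=float(np.mean(Rs)), sigma_cc=float(np.mean(sccs)),
        abar=float(np.mean(abars)), N_assumed=N_assumed,
        per_subsample=np.asarray(Rs),
    )


def recurrence_condition_contrast(pairs: Sequence[tuple[float, float]]):
    """Two-sided Wilcoxon signed-rank on per-session (hit, miss) R pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or len(pairs) < 2:
        raise ValueError("need paired estimates from at least 2 sessions")
    if len(pairs) < 6:
        warnings.warn(f"only {len(pairs)} sessions; paired test has low power")
    if np.allclose(pairs[:, 0], pairs[:, 1]):
        return None
    return stats.wilcoxon(pairs[:, 0], pairs[:, 1], alternative="two-sided")


# ---------------------------------------------------------------------------
# network response timescale

def fit_response_timescale(
    activity: np.ndarray,
    trials: Sequence[TrialRecord],
    frame_rate_hz: float,
    cell_index: dict[int, int],
    condition: str = "all",
    seed: int = 0,
    n_subsamples: int = N_SUBSAMPLES,
    trials_per_subsample: int = TAU_TRIALS_PER_SUBSAMPLE,
    apply_blanking: bool = True,
) -> TimescaleFit:
    """Exponential decay time of the mean targeted-cell response.

    Restricted to 250-ms-stimulation trials (5-50 targets) of the given
    condition. Per trial the targeted cells' traces are averaged over the
    5.5 s after onset, baselined to their mean over the 6.5-s pre-trial
    window; per subsample the mean over ``trials_per_subsample`` drawn
    trials is fit with A exp(-t / tau) on unblanked frames. The reported
    tau_post averages over subsamples; diverged fits are dropped and
    counted, and the session is flagged if more than half fail.
    """
    rng = np.random.default_rng(seed)
    n_frames_total = activity.shape[1]
    resp = int(round(TAU_RESPONSE_WINDOW_S * frame_rate_hz))
    base = int(round(TAU_BASELINE_WINDOW_S * frame_rate_hz))
    blank = session_blank_mask(trials, n_frames_total, frame_rate_hz) if apply_blanking \
        else np.zeros(n_frames_total, dtype=bool)

    pool = [t for t in _condition_trials(trials, condition)
            if 5 <= t.n_targets <= 50 and t.onset_frame - base >= 0
            and t.onset_frame + resp <= n_frames_total]
    if len(pool) < trials_per_subsample:
        raise ValueError(f"only {len(pool)} eligible trials for timescale fit")

    traces, masks = [], []
    for t in pool:
        rows = np.array([cell_index[i] for i in t.targeted_cell_ids], dtype=int)
        pre_ok = ~blank[t.onset_frame - base:t.onset_frame]
        b = activity[rows, t.onset_frame - base:t.onset_frame][:, pre_ok].mean()
        traces.append(activity[rows, t.onset_frame:t.onset_frame + resp].mean(axis=0) - b)
        masks.append(~blank[t.onset_frame:t.onset_frame + resp])
    traces = np.asarray(traces)
    masks = np.asarray(masks)
    tgrid = np.arange(resp) / frame_rate_hz

    taus, amps, r2s, failed = [], [], [], 0
    for _ in range(n_subsamples):
        pick = rng.choice(len(pool), size=trials_per_subsample, replace=False)
        m = masks[pick].all(axis=0)
        y = traces[pick].mean(axis=0)[m]
        t = tgrid[m]
        if y.std() == 0:
            failed += 1
            continue
        try:
            popt, _ = curve_fit(lambda tt, A, tau: A * np.exp(-tt / tau), t, y,
                                p0=[max(y[0], 1e-3), 1.0],
                                bounds=([-np.inf, 1e-3], [np.inf, 60.0]),
                                maxfev=5000)
        except RuntimeError:
            failed += 1
            continue
        A, tau = popt
        if tau >= 59.9 or A <= 0:          # unbounded decay or no response
            failed += 1
            continue
        pred = A * np.exp(-t / tau)
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum((y - pred) ** 2) / sst if sst > 0 else np.nan
        taus.append(tau)
        amps.append(A)
        r2s.append(r2)
    n_ok = len(taus)
    flagged = failed > n_ok
    if n_ok == 0:
        return TimescaleFit(tau_post=np.nan, A=np.nan, fit_r2=np.nan,
                            n_failed=failed, flagged=True)
    return TimescaleFit(
        tau_post=float(np.mean(taus)), A=float(np.mean(amps)),
        fit_r2=float(np.nanmean(r2s)), per_subsample=np.asarray(taus),
        n_failed=failed, flagged=flagged,
    )


def relate_timescale_recurrence(pairs: Sequence[tuple[float, float]]) -> dict:
    """Compare tau = c/(1-R) against a plain linear regression tau = a + b R.

    ``pairs`` are per-session (R, tau_post). The single-scale theory fit is
    linear in c, solved in closed form; r^2 is reported for both models.
    """
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 3:
        raise ValueError("need at least 3 sessions")
    R, tau = pairs[:, 0], pairs[:, 1]
    if np.any(R >= 1):
        raise ValueError("R >= 1 is outside the stable regime")
    u = 1.0 / (1.0 - R)
    c = float(np.sum(tau * u) / np.sum(u * u))
    sst = float(np.sum((tau - tau.mean()) ** 2))
    r2_theory = 1.0 - float(np.sum((tau - c * u) ** 2)) / sst if sst > 0 else 0.0
    lin = stats.linregress(R, tau)
    r2_linear = float(lin.rvalue ** 2) if sst > 0 else 0.0
    return {"c": c, "r2_theory": r2_theory,
            "slope": float(lin.slope), "intercept": float(lin.intercept),
            "r2_linear": r2_linear}
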