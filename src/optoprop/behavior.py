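"""Behavioral scoring, d', session QC and psychometric fitting.

Detection performance is quantified with signal detection theory:
``d' = z(hit rate) - z(false alarm rate)`` with the z-transform the
standard-normal quantile. Hit rates are computed per number of targeted
cells and compared against the false-alarm rate pooled over all catch
trials of the session. The psychometric curve is a logistic in the number
of targeted cells with its lower bound adjusted to d' = 0:

    d'(n) = dmax / (1 + exp(-k (n - x50)))    clamped at 0

where x50 is the half-maximum ("50% point") in units of targeted cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm

from .session import TrialRecord

RESPONSE_WINDOW_MS = (150.0, 1000.0)


@dataclass
class BehaviorSummary:
    per_n_targets: pd.DataFrame      # columns: n_targets, n_go, hit_rate, dprime
    false_alarm_rate: float
    n_catch: int
    n_too_soon: int


@dataclass
class PsychometricFit:
    dmax: float
    k: float
    x50: float
    converged: bool
    degenerate: bool = False
    points: Optional[pd.DataFrame] = None

    def predict(self, n):
        return np.maximum(logistic_dprime(np.asarray(n, dtype=float),
                                          self.dmax, self.k, self.x50), 0.0)


def score_trials(trials: Sequence[TrialRecord]) -> list[TrialRecord]:
    """Assign outcomes from first-lick times.

    Go trials: a lick in [150 ms, 1 s) is a hit; a lick before 150 ms is
    almost certainly random rather than perception-driven and is marked
    too_soon (excluded downstream); no lick in the window is a miss.
    Catch trials: lick in window -> false_positive, else correct_rejection.
    Reward-only trials are left unscored.
    """
    lo, hi = RESPONSE_WINDOW_MS
    out = []
    for t in trials:
        t = TrialRecord(**{**t.__dict__})
        lick = t.first_lick_ms
        in_window = lick is not None and lo <= lick < hi
        if t.trial_type == "go":
            if lick is not None and lick < lo:
                t.outcome = "too_soon"
            elif in_window:
                t.outcome = "hit"
            else:
                t.outcome = "miss"
        elif t.trial_type == "catch":
            t.outcome = "false_positive" if in_window else "correct_rejection"
        else:
            t.outcome = "unscored"
        out.append(t)
    return out


def _corrected_rate(rate: float, n: Optional[int]) -> float:
    """Log-linear correction of extreme rates: 0 -> 1/(2n), 1 -> 1 - 1/(2n)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate {rate} outside [0, 1]")
    if rate in (0.0, 1.0):
        if n is None or n <= 0:
            raise ValueError("extreme rate needs a trial count for correction")
        rate = 1.0 / (2 * n) if rate == 0.0 else 1.0 - 1.0 / (2 * n)
    return rate


def compute_dprime(hit_rate: float, fa_rate: float,
                   n_go: Optional[int] = None, n_catch: Optional[int] = None) -> float:
    """d' = z(hit rate) - z(false alarm rate), with extreme-rate correction."""
    h = _corrected_rate(hit_rate, n_go)
    f = _corrected_rate(fa_rate, n_catch)
    return float(norm.ppf(h) - norm.ppf(f))


def summarize_behavior(trials: Sequence[TrialRecord]) -> BehaviorSummary:
    """Hit rate and d' per target count; FA rate over all catch trials.

    Too-soon trials are excluded from all rates.
    """
    go = [t for t in trials if t.trial_type == "go" and t.outcome in ("hit", "miss")]
    catch = [t for t in trials if t.trial_type == "catch"
             and t.outcome in ("false_positive", "correct_rejection")]
    n_too_soon = sum(t.outcome == "too_soon" for t in trials)
    n_catch = len(catch)
    n_fp = sum(t.outcome == "false_positive" for t in catch)
    fa = n_fp / n_catch if n_catch else np.nan

    rows = []
    for n in sorted({t.n_targets for t in go}):
        sub = [t for t in go if t.n_targets == n]
        n_go = len(sub)
        hits = sum(t.outcome == "hit" for t in sub)
        hr = hits / n_go
        dp = compute_dprime(hr, fa, n_go=n_go, n_catch=n_catch) if n_catch else np.nan
        rows.append({"n_targets": n, "n_go": n_go, "hit_rate": hr, "dprime": dp})
    return BehaviorSummary(
        per_n_targets=pd.DataFrame(rows, columns=["n_targets", "n_go", "hit_rate", "dprime"]),
        false_alarm_rate=fa, n_catch=n_catch, n_too_soon=n_too_soon,
    )


def session_qc(summary: BehaviorSummary, trials: Sequence[TrialRecord]) -> Optional[bool]:
    """Include a session iff d'(150) >= 0.95 and pooled d'(40 u 50) >= 0.5.

    Returns None (decision deferred) with a warning if either condition has
    no trials.
    """
    go = [t for t in trials if t.trial_type == "go" and t.outcome in ("hit", "miss")]
    strong = [t for t in go if t.n_targets == 150]
    mid = [t for t in go if t.n_targets in (40, 50)]
    if not strong or not mid or not summary.n_catch:
        warnings.warn("session QC deferred: missing 150-target, 40/50-target or catch trials")
        return None
    fa, nc = summary.false_alarm_rate, summary.n_catch
    d150 = compute_dprime(sum(t.outcome == "hit" for t in strong) / len(strong),
                          fa, n_go=len(strong), n_catch=nc)
    d4050 = compute_dprime(sum(t.outcome == "hit" for t in mid) / len(mid),
                           fa, n_go=len(mid), n_catch=nc)
    return bool(d150 >= 0.95 and d4050 >= 0.5)


def logistic_dprime(n, dmax, k, x50):
    return dmax / (1.0 + np.exp(-k * (n - x50)))


def fit_psychometric(points: Sequence[tuple[float, float]],
                     pooled: bool = True) -> PsychometricFit:
    """Least-squares logistic fit of d' versus number of targeted cells.

    ``points`` are (n_targets, dprime) pairs; with ``pooled`` they are all
    weighted equally (sessions contribute one point per target count).
    Outputs are clamped at d' = 0 during fitting, implementing the
    adjusted lower bound. Requires >= 3 distinct target counts.
    """
    pts = pd.DataFrame(points, columns=["n", "d"]).dropna()
    if pts["n"].nunique() < 3:
        raise ValueError("need at least 3 distinct target counts")
    x = pts["n"].to_numpy(dtype=float)
    y = pts["d"].to_numpy(dtype=float)
    if np.allclose(y, 0.0) or np.ptp(y) < 1e-12:
        return PsychometricFit(dmax=0.0, k=np.nan, x50=np.nan, converged=False,
                               degenerate=True, points=pts)

    def model(n, dmax, k, x50):
        return np.maximum(logistic_dprime(n, dmax, k, x50), 0.0)

    dmax0 = max(y.max(), 0.1)
    x50_0 = float(np.interp(dmax0 / 2, np.sort(y), x[np.argsort(y)]))
    try:
        popt, _ = curve_fit(
            model, x, y,
            p0=[dmax0, 0.1, np.clip(x50_0, x.min(), x.max())],
            bounds=([0.0, 1e-4, 0.0], [10 * dmax0, 10.0, 1e4]),
            maxfev=20000,
        )
        return PsychometricFit(dmax=float(popt[0]), k=float(popt[1]),
                               x50=float(popt[2]), converged=True, points=pts)
    except RuntimeError:
        return PsychometricFit(dmax=np.nan, k=np.nan, x50=np.nan,
                               converged=False, points=pts)
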