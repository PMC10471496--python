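"""Excitation-inhibition balance statistics.

Photostimulation drives both excited and inhibited cells; across sessions
and stimulation strengths (number of targeted cells) the fractions of
excited and inhibited cells track each other, a signature of
inhibition-stabilized dynamics. This module classifies single-cell
response signs, relates the fractions to stimulation strength with a
weighted least-squares line, and compares excitation-inhibition
correlations between regions with Steiger's test for dependent
correlations (a permutation oracle backs the implementation in tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import TrialTensor
from .session import CellMeta

RESPONSE_WINDOW_S = (0.0, 1.5)
ALPHA = 0.05
TARGET_DISTANCE_UM = 15.0   # inclusive boundary


@dataclass
class ResponseClassification:
    cell_id: int
    label: str          # excited / inhibited / neutral
    statistic: float
    p_value: float
    n_trials: int
    flagged: bool = False


def _window_response(tensor: TrialTensor, trial_idx: Sequence[int],
                     window_s=RESPONSE_WINDOW_S) -> np.ndarray:
    """Trial-wise mean baselined response per cell over unblanked window frames."""
    if not tensor.baselined:
        raise ValueError("classification requires a baselined tensor")
    lo = np.searchsorted(tensor.time_axis_s, window_s[0])
    hi = np.searchsorted(tensor.time_axis_s, window_s[1])
    sub = tensor.data[list(trial_idx), :, lo:hi]
    mask = ~tensor.blank_mask[list(trial_idx), lo:hi]
    w = mask[:, None, :].astype(float)
    with np.errstate(invalid="ignore"):
        resp = (sub * w).sum(axis=2) / np.maximum(w.sum(axis=2), 1e-12)
    return resp                       # trials x cells


def classify_response_sign(tensor: TrialTensor, trial_idx: Sequence[int],
                           alpha: float = ALPHA,
                           window_s=RESPONSE_WINDOW_S) -> list[ResponseClassification]:
    """Excited / inhibited / neutral per cell over a trial set.

    Two-sided Wilcoxon signed-rank of the trial-wise mean baselined
    response (0-1.5 s of unblanked frames) against zero at ``alpha``; the
    sign of the median sets the label. Fewer than 5 trials -> neutral,
    flagged.
    """
    resp = _window_response(tensor, trial_idx, window_s)
    out = []
    few = resp.shape[0] < 5
    for j, cid in enumerate(tensor.cell_ids):
        x = resp[:, j]
        if few or np.allclose(x, 0):
            out.append(ResponseClassification(cid, "neutral", np.nan, np.nan,
                                              resp.shape[0], flagged=few))
            continue
        res = stats.wilcoxon(x, alternative="two-sided")
        med = float(np.median(x))
        if res.pvalue < alpha and med != 0:
            label = "excited" if med > 0 else "inhibited"
        else:
            label = "neutral"
        out.append(ResponseClassification(cid, label, float(res.statistic),
                                          float(res.pvalue), resp.shape[0]))
    return out


def response_fractions(tensor: TrialTensor, outcome: str,
                       region_of: Optional[dict[int, str]] = None,
                       alpha: float = ALPHA) -> pd.DataFrame:
    """Fractions of excited/inhibited cells per stimulation strength.

    Rows: one per (region, n_targets) with columns frac_excited,
    frac_inhibited, n_trials. Catch/reward-only sets use n_targets = 0.
    """
    rows = []
    by_strength: dict[int, list[int]] = {}
    for i, t in enumerate(tensor.trials):
        if t.outcome == outcome or t.trial_type == outcome:
            by_strength.setdefault(t.n_targets, []).append(i)
    for n, idx in sorted(by_strength.items()):
        if len(idx) < 5:
            continue
        cls = classify_response_sign(tensor, idx, alpha=alpha)
        regions = sorted({region_of[c.cell_id] for c in cls}) if region_of else ["all"]
        for reg in regions:
            sub = [c for c in cls if region_of is None or region_of[c.cell_id] == reg]
            ntot = len(sub)
            rows.append({
                "region": reg, "n_targets": n, "n_trials": len(idx),
                "frac_excited": sum(c.label == "excited" for c in sub) / ntot,
                "frac_inhibited": sum(c.label == "inhibited" for c in sub) / ntot,
            })
    return pd.DataFrame(rows, columns=["region", "n_targets", "n_trials",
                                       "frac_excited", "frac_inhibited"])


def wls_fraction_fit(x: Sequence[float], y: Sequence[float],
                     point_variances: Optional[Sequence[float]] = None) -> dict:
    """Weighted least-squares line with percentile-clipped inverse-variance weights.

    Weights are the inverse variances of the trials constituting each
    point, bound between their 25th and 75th percentiles to prevent
    extreme values; without variances all weights are equal and the fit
    reduces exactly to OLS. Returns slope/intercept with a two-sided
    t-test p-value on the slope.
    """
    import statsmodels.api as sm
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 strength levels")
    if point_variances is None:
        w = np.ones_like(x)
    else:
        w = 1.0 / np.asarray(point_variances, dtype=float)
        lo, hi = np.percentile(w, [25, 75])
        w = np.clip(w, lo, hi)
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return {"slope": float(res.params[1]), "intercept": float(res.params[0]),
            "p_slope": float(res.pvalues[1]), "weights": w}


def pearson_with_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 paired points")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def steiger_z(r_jk: float, r_hm: float, r_jh: float, r_jm: float,
              r_kh: float, r_km: float, n: int) -> tuple[float, float]:
    """Two-tailed Steiger Z comparing dependent correlations r_jk vs r_hm.

    The two correlations share the sample (n observations of variables
    j, k, h, m) but share no variable; the covariance of the two
    correlation estimates follows Pearson-Filon as used by Steiger's
    method, and the comparison is made on Fisher-z transformed values.
    Comparing a correlation with itself gives Z = 0, p = 1.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if (r_jk, r_jh, r_jm) == (r_hm, r_kh, r_km) and r_jk == r_hm:
        pass  # degenerate self-comparison handled by the formula (psi -> var)
    psi = (0.5 * r_jk * r_hm * (r_jh**2 + r_jm**2 + r_kh**2 + r_km**2)
           + r_jh * r_km + r_jm * r_kh
           - r_jk * (r_jh * r_jm + r_kh * r_km)
           - r_hm * (r_jh * r_kh + r_jm * r_km))
    denom = (1 - r_jk**2) * (1 - r_hm**2)
    s = psi / denom if denom > 0 else 0.0
    s = float(np.clip(s, -0.999999, 0.999999))
    z1 = np.arctanh(np.clip(r_jk, -0.999999, 0.999999))
    z2 = np.arctanh(np.clip(r_hm, -0.999999, 0.999999))
    if z1 == z2:
        return 0.0, 1.0
    Z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - s)))
    p = 2.0 * stats.norm.sf(abs(Z))
    return float(Z), float(p)


def compare_ei_correlations(a: np.ndarray, b: np.ndarray) -> dict:
    """Compare corr(a1,a2) with corr(b1,b2) on the same observations.

    ``a`` and ``b`` are (n, 2) arrays, e.g. S1 (excited, inhibited)
    fractions and S2 (excited, inhibited) fractions over the same
    session x strength points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("expect two (n, 2) arrays over the same observations")
    n = a.shape[0]
    r1, p1 = pearson_with_test(a[:, 0], a[:, 1])
    r2, p2 = pearson_with_test(b[:, 0], b[:, 1])
    cm = np.corrcoef(np.column_stack([a, b]).T)   # order: j=a1, k=a2, h=b1, m=b2
    Z, p = steiger_z(cm[0, 1], cm[2, 3], cm[0, 2], cm[0, 3], cm[1, 2], cm[1, 3], n)
    return {"r1": r1, "p1": p1, "r2": r2, "p2": p2, "steiger_z": Z, "steiger_p": p}


def permutation_correlation_comparison(a: np.ndarray, b: np.ndarray,
                                       n_permutations: int = 10000,
                                       seed: int = 0) -> float:
    """Permutation analogue of the Steiger comparison (oracle for tests).

    Under the null that the (a1,a2) and (b1,b2) pairs are exchangeable,
    swapping the two pairs independently per observation leaves the
    distribution of r(a) - r(b) invariant; the two-sided p-value is the
    fraction of swap-resampled |differences| at least as large as observed.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[0]

    def rdiff(x, yarr):
        return np.corrcoef(x[:, 0], x[:, 1])[0, 1] - np.corrcoef(yarr[:, 0], yarr[:, 1])[0, 1]

    obs = rdiff(a, b)
    count = 0
    for _ in range(n_permutations):
        swap = rng.uniform(size=n) < 0.5
        ap, bp = a.copy(), b.copy()
        ap[swap], bp[swap] = b[swap], a[swap]
        if abs(rdiff(ap, bp)) >= abs(obs) - 1e-15:
            count += 1
    return (count + 1) / (n_permutations + 1)


def target_response_summary(tensor: TrialTensor, cells: Sequence[CellMeta],
                            window_s: tuple[float, float] = (0.0, 8.0)) -> pd.DataFrame:
    """Per-group area under the mean post-stimulus response curve.

    Groups per go trial: directly targeted cells (the trial's targets, all
    within 15 um of a beam center), S1 non-targets (targeted cells leave
    the non-target pool on the trials they are targeted), and S2 cells.
    Returns one row per group with the session AUC (dF/F x s).
    """
    region = {c.cell_id: c.region for c in cells}
    col = {cid: j for j, cid in enumerate(tensor.cell_ids)}
    go = [(i, t) for i, t in enumerate(tensor.trials)
          if t.trial_type == "go" and t.n_targets > 0]
    if not go:
        return pd.DataFrame(columns=["group", "auc", "n_trials"])
    lo = np.searchsorted(tensor.time_axis_s, window_s[0])
    hi = np.searchsorted(tensor.time_axis_s, window_s[1])
    dt = 1.0 / tensor.frame_rate_hz

    sums = {g: [] for g in ("s1_targets", "s1_nontargets", "s2")}
    for i, t in go:
        valid = ~tensor.blank_mask[i, lo:hi]
        tgt = [col[c] for c in t.targeted_cell_ids if c in col]
        s1_non = [col[c] for c in tensor.cell_ids
                  if region[c] == "S1" and c not in t.targeted_cell_ids]
        s2 = [col[c] for c in tensor.cell_ids if region[c] == "S2"]
        for g, rows in (("s1_targets", tgt), ("s1_nontargets", s1_non), ("s2", s2)):
            if not rows:
                continue
            trace = tensor.data[i, rows, lo:hi].mean(axis=0)
            sums[g].append(trace[valid].sum() * dt)
    rows = []
    for g, vals in sums.items():
        if vals:
            rows.append({"group": g, "auc": float(np.mean(vals)), "n_trials": len(vals)})
        else:
            warnings.warn(f"group {g} empty; skipped")
    return pd.DataFrame(rows, columns=["group", "auc", "n_trials"])


def group_significance(session_aucs: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank vs 0 per group across sessions, Bonferroni corrected.

    ``session_aucs`` has columns (session, group, auc).
    """
    groups = sorted(session_aucs.group.unique())
    rows = []
    for g in groups:
        vals = session_aucs.loc[session_aucs.group == g, "auc"].to_numpy()
        if len(vals) < 2 or np.allclose(vals, 0):
            rows.append({"group": g, "p_raw": np.nan, "p_bonf": np.nan, "n": len(vals)})
            continue
        p = stats.wilcoxon(vals, alternative="two-sided").pvalue
        rows.append({"group": g, "p_raw": float(p),
                     "p_bonf": float(min(p * len(groups), 1.0)), "n": len(vals)})
    return pd.DataFrame(rows)
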