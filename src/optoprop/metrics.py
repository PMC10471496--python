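"""Pre-stimulus population metrics and the SNR model of perception.

For each trial, cell activity is averaged over the 0.5 s immediately
preceding stimulation; the mean and the across-cell variance of the
resulting vector are the population mean and population variance. Variance
is log-transformed when a log-normal fits its distribution better than a
normal (Kullback-Leibler divergence against the empirical histogram), then
z-scored across trials within a session.

The SNR framework: the probability of a hit rises with stimulus strength
(number of targeted cells) and falls with pre-stimulus population variance
("noise"). It is quantified with (a) a 2-D hit-probability surface over
variance bins x target counts plus its projection onto the anti-diagonal
SNR axis, and (b) a logistic regression of outcome on both regressors with
McFadden's pseudo-R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import TrialTensor

VARIANCE_DDOF = 1  # across-cell sample variance


@dataclass
class PopulationState:
    """Per-trial scalar population metrics (go/catch trials)."""

    table: pd.DataFrame  # trial_id, trial_type, outcome, n_targets, pop_mean, pop_var, pop_var_log, z_*
    transform: str = "log"
    zscored: bool = False


@dataclass
class SNRModel:
    beta0: float
    beta_ntargets: float
    beta_popvar: float
    p_values: dict
    mcfadden_r2: float
    mcfadden_r2_ntargets_only: float
    mcfadden_r2_popvar_only: float
    ll_model: float
    ll_null: float


def prestim_population_metrics(tensor: TrialTensor, window_s: float = 0.5) -> PopulationState:
    """Population mean and variance over the pre-stimulus window, per trial.

    Each cell is averaged over the last ``window_s`` seconds before onset;
    the mean and across-cell sample variance of that vector give one scalar
    pair per trial. The variance is also returned log-transformed (the
    default downstream transform).
    """
    n_cells = tensor.data.shape[1]
    if n_cells < 2:
        raise ValueError("population variance undefined with fewer than 2 cells")
    pre = tensor.pre_frames
    nwin = int(round(window_s * tensor.frame_rate_hz))
    if nwin < 1 or nwin > pre:
        raise ValueError(f"window of {nwin} frames does not fit in {pre} pre frames")
    # last nwin unblanked pre-onset frames per trial (the 2-frame laser pad
    # before stimulation is excluded on go trials)
    per_cell = np.empty((tensor.data.shape[0], n_cells))
    for i in range(tensor.data.shape[0]):
        ok = np.flatnonzero(~tensor.blank_mask[i, :pre])
        sel = ok[-nwin:]
        per_cell[i] = tensor.data[i, :, sel].mean(axis=0)
    pop_mean = per_cell.mean(axis=1)
    pop_var = per_cell.var(axis=1, ddof=VARIANCE_DDOF)
    with np.errstate(divide="ignore"):
        pop_var_log = np.where(pop_var > 0, np.log(pop_var), -np.inf)
    table = pd.DataFrame({
        "trial_id": [t.trial_id for t in tensor.trials],
        "trial_type": [t.trial_type for t in tensor.trials],
        "outcome": [t.outcome for t in tensor.trials],
        "n_targets": [t.n_targets for t in tensor.trials],
        "pop_mean": pop_mean,
        "pop_var": pop_var,
        "pop_var_log": pop_var_log,
    })
    return PopulationState(table=table)


def select_transform(values: Sequence[float], n_bins: int = 50) -> str:
    """Choose 'log' or 'identity' by KL divergence against the empirical histogram.

    Normal and log-normal families are fit by maximum likelihood; the KL
    divergence from the empirical distribution (equal-width histogram with
    Laplace smoothing) to each fitted density is compared. Non-positive or
    degenerate inputs force 'identity' with a warning.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10 or np.ptp(x) == 0:
        warnings.warn("degenerate distribution; identity transform forced")
        return "identity"
    if np.any(x <= 0):
        warnings.warn("non-positive values; identity transform forced")
        return "identity"
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    p = (counts + 1.0) / (counts.sum() + n_bins)      # Laplace smoothing

    def kl_to(cdf):
        q = np.diff(cdf(edges))
        q = np.maximum(q, 1e-300)
        q = q / q.sum()
        return float(np.sum(p * np.log(p / q)))

    mu, sd = x.mean(), x.std(ddof=1)
    kl_norm = kl_to(lambda e: stats.norm.cdf(e, mu, sd))
    lmu, lsd = np.log(x).mean(), np.log(x).std(ddof=1)
    kl_lognorm = kl_to(lambda e: stats.lognorm.cdf(e, s=lsd, scale=np.exp(lmu)))
    return "log" if kl_lognorm < kl_norm else "identity"


def zscore_metrics(state: PopulationState) -> PopulationState:
    """Z-score pop_mean and the transformed variance across trials in-session.

    Standardization uses the sample s.d. (ddof=1) over all trials with a
    defined value, before any split by outcome.
    """
    df = state.table.copy()
    if len(df) < 2:
        raise ValueError("z-scoring needs at least 2 trials")
    var_col = "pop_var_log" if state.transform == "log" else "pop_var"
    for src, dst in (("pop_mean", "z_pop_mean"), (var_col, "z_pop_var")):
        vals = df[src].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        sd = np.std(vals[ok], ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero spread in {src}; z-score undefined")
        z = np.full_like(vals, np.nan)
        z[ok] = (vals[ok] - vals[ok].mean()) / sd
        df[dst] = z
    return PopulationState(table=df, transform=state.transform, zscored=True)


def outcome_contrast(states: Sequence[PopulationState], metric: str = "z_pop_var"):
    """Hit-vs-miss contrast of a z-scored metric across sessions.

    Returns (per-session DataFrame, Wilcoxon signed-rank result on the
    paired session means). Sessions without both outcomes are skipped.
    """
    rows = []
    for i, st in enumerate(states):
        df = st.table
        hit = df.loc[df.outcome == "hit", metric].dropna()
        miss = df.loc[df.outcome == "miss", metric].dropna()
        if len(hit) == 0 or len(miss) == 0:
            continue
        rows.append({"session": i, "hit_mean": hit.mean(), "miss_mean": miss.mean()})
    per = pd.DataFrame(rows, columns=["session", "hit_mean", "miss_mean"])
    if len(per) < 6:
        warnings.warn(f"only {len(per)} sessions; paired test has low power")
    if len(per) < 2 or np.allclose(per.hit_mean, per.miss_mean):
        return per, None
    test = stats.wilcoxon(per.hit_mean, per.miss_mean, alternative="two-sided")
    return per, test


def hit_rate_by_variance(state: PopulationState, n_bins: int = 5, min_per_bin: int = 5):
    """Binned P(hit) versus z-scored population variance, with a slope test.

    Go trials are split into equal-count bins of ``z_pop_var``; bins with
    fewer than ``min_per_bin`` trials are merged with their neighbor. The
    result holds the per-bin hit probability, the OLS slope of P(hit) on
    bin center, and the one-sided p-value for a negative slope.
    """
    df = state.table
    go = df[(df.trial_type == "go") & df.outcome.isin(["hit", "miss"])].copy()
    if len(go) < 2 * min_per_bin:
        raise ValueError("too few scored go trials for binning")
    go = go.sort_values("z_pop_var")
    edges = np.array_split(np.arange(len(go)), n_bins)
    edges = [e for e in edges if len(e)]
    merged: list[np.ndarray] = []
    for e in edges:
        if merged and len(e) < min_per_bin:
            merged[-1] = np.concatenate([merged[-1], e])
        else:
            merged.append(e)
    centers, phit, counts = [], [], []
    z = go.z_pop_var.to_numpy()
    hit = (go.outcome == "hit").to_numpy()
    for e in merged:
        centers.append(z[e].mean())
        phit.append(hit[e].mean())
        counts.append(len(e))
    centers, phit = np.asarray(centers), np.asarray(phit)
    if len(centers) < 3 or np.ptp(phit) == 0:
        slope = 0.0 if np.ptp(phit) == 0 else np.nan
        return pd.DataFrame({"bin_center": centers, "p_hit": phit,
                             "n": counts}), slope, 1.0
    res = stats.linregress(centers, phit)
    # one-sided test for a negative slope
    p_neg = res.pvalue / 2 if res.slope < 0 else 1 - res.pvalue / 2
    return pd.DataFrame({"bin_center": centers, "p_hit": phit, "n": counts}), \
        res.slope, float(p_neg)


def snr_surface(states: Sequence[PopulationState], var_bin_width: float = 0.5):
    """Hit-probability grid over (z-variance bin x target count) + SNR projection.

    Go trials are pooled across sessions (z-scores computed within session
    first). The SNR axis is the normalized anti-diagonal: low variance and
    high target count = high SNR. Each occupied grid bin projects
    orthogonally onto that axis; bins sharing a projection coordinate are
    averaged. Empty bins are left as NaN and excluded.
    """
    pooled = pd.concat([s.table for s in states], ignore_index=True)
    go = pooled[(pooled.trial_type == "go") & pooled.outcome.isin(["hit", "miss"])].copy()
    if go.empty:
        raise ValueError("no scored go trials")
    zv = go.z_pop_var.to_numpy()
    vbin = np.floor(zv / var_bin_width).astype(int)
    go["var_bin"] = vbin
    counts = sorted(go.n_targets.unique())
    vbins = sorted(go.var_bin.unique())
    grid = pd.DataFrame(np.nan, index=vbins, columns=counts)
    nobs = pd.DataFrame(0, index=vbins, columns=counts)
    for (vb, n), sub in go.groupby(["var_bin", "n_targets"]):
        grid.loc[vb, n] = (sub.outcome == "hit").mean()
        nobs.loc[vb, n] = len(sub)

    # orthogonal projection of (count rank, -variance bin rank) onto the diagonal
    crank = {c: i / max(len(counts) - 1, 1) for i, c in enumerate(counts)}
    vrank = {v: i / max(len(vbins) - 1, 1) for i, v in enumerate(vbins)}
    proj_rows = []
    for vb in vbins:
        for c in counts:
            val = grid.loc[vb, c]
            if np.isnan(val):
                continue
            snr = (crank[c] + (1.0 - vrank[vb])) / np.sqrt(2.0)
            proj_rows.append({"snr": round(snr, 9), "p_hit": val, "n": nobs.loc[vb, c]})
    proj = (pd.DataFrame(proj_rows).groupby("snr", as_index=False)
            .agg(p_hit=("p_hit", "mean"), n=("n", "sum")).sort_values("snr"))
    return grid, proj


def snr_logistic_model(states: Sequence[PopulationState]) -> SNRModel:
    """Logistic regression of outcome on n_targets and z-scored log-variance.

    Fit by maximum likelihood on all pooled hit/miss trials; per-coefficient
    two-sided tests and McFadden's pseudo-R^2 (1 - ll_model/ll_null) for the
    full model and each single-regressor model.
    """
    import statsmodels.api as sm

    pooled = pd.concat([s.table for s in states], ignore_index=True)
    go = pooled[(pooled.trial_type == "go") & pooled.outcome.isin(["hit", "miss"])]
    y = (go.outcome == "hit").astype(int).to_numpy()
    X = go[["n_targets", "z_pop_var"]].to_numpy(dtype=float)
    mask = np.all(np.isfinite(X), axis=1)
    X, y = X[mask], y[mask]
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < 3:
        raise ValueError("rank-deficient design matrix")

    def fit(cols):
        Xc = sm.add_constant(X[:, cols], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        return res

    full = fit([0, 1])
    only_n = fit([0])
    only_v = fit([1])
    ll_null = float(full.llnull)

    def mcfadden(res):
        return float(1.0 - res.llf / res.llnull)

    return SNRModel(
        beta0=float(full.params[0]),
        beta_ntargets=float(full.params[1]),
        beta_popvar=float(full.params[2]),
        p_values={"beta_ntargets": float(full.pvalues[1]),
                  "beta_popvar": float(full.pvalues[2])},
        mcfadden_r2=mcfadden(full),
        mcfadden_r2_ntargets_only=mcfadden(only_n),
        mcfadden_r2_popvar_only=mcfadden(only_v),
        ll_model=float(full.llf),
        ll_null=ll_null,
    )


def variance_covariates(state: PopulationState,
                        recent_rewards: Optional[Sequence[float]] = None,
                        other_region: Optional[PopulationState] = None) -> pd.DataFrame:
    """Pearson correlations of z-scored variance with task covariates.

    Covariates: trial index, recent reward count (if given) and the paired
    region's variance (if given, matched on trial_id). Constant covariates
    are flagged with NaN correlation.
    """
    df = state.table.reset_index(drop=True)
    z = df.z_pop_var.to_numpy(dtype=float)
    rows = []

    def corr(name, x, y):
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rows.append({"covariate": name, "r": np.nan, "p": np.nan, "flag": "degenerate"})
            return
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"covariate": name, "r": r, "p": p, "flag": ""})

    corr("trial_index", np.arange(len(df), dtype=float), z)
    if recent_rewards is not None:
        corr("recent_rewards", np.asarray(recent_rewards, dtype=float), z)
    if other_region is not None:
        other = other_region.table.set_index("trial_id").z_pop_var
        matched = df.set_index("trial_id").z_pop_var.to_frame("a").join(other.to_frame("b"), how="inner")
        corr("other_region", matched.a.to_numpy(), matched.b.to_numpy())
    return pd.DataFrame(rows, columns=["covariate", "r", "p", "flag"])
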