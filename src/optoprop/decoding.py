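"""Time-resolved population decoding of trial type.

For every imaging frame within the trial window, an L2-penalized logistic
regression is trained from scratch on the vector of per-cell dF/F values
at that frame, with four-fold cross-validation (3:1 train:test); accuracy
is the fold-averaged held-out fraction correct. Classes are balanced by
random subsampling of the majority class, so chance is 0.5. Models trained
on one pair of trial types (canonically hit vs correct rejection) can be
evaluated on a third type (reward-only, miss): the fraction of those trials
classified as the positive class, per timepoint, shows whether they carry
the trained signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .preprocess import TrialTensor

REGULARIZATION_STRENGTH = 0.001   # lambda; sklearn C = 1 / lambda
N_FOLDS = 4


def _trial_indices(tensor: TrialTensor, label: str) -> list[int]:
    """Trials matching an outcome label or trial-type label."""
    out = [i for i, t in enumerate(tensor.trials) if t.outcome == label]
    if out:
        return out
    return [i for i, t in enumerate(tensor.trials) if t.trial_type == label]


@dataclass
class DecodingProfile:
    labels: tuple[str, str]            # (negative, positive)
    time_axis_s: np.ndarray
    accuracy: np.ndarray               # per timepoint, NaN where skipped
    n_folds: int
    regularization_strength: float
    trial_indices: np.ndarray          # balanced trial set (into tensor.trials)
    fold_assignment: np.ndarray        # fold id per balanced trial
    models: dict = field(default_factory=dict)   # (timepoint, fold) -> fitted model


def train_timepoint_decoders(
    tensor: TrialTensor,
    labels: tuple[str, str],
    seed: int = 0,
    regularization_strength: float = REGULARIZATION_STRENGTH,
    n_folds: int = N_FOLDS,
    timepoints: Optional[Sequence[int]] = None,
) -> DecodingProfile:
    """Train one classifier per timepoint per fold for a pair of trial labels.

    ``labels`` is (negative, positive); each may be an outcome (``"hit"``,
    ``"correct_rejection"``, ...) or a trial type. The majority class is
    subsampled once (with the given seed) to balance classes; timepoints at
    which any selected trial is laser-blanked are skipped (NaN accuracy).
    """
    neg = _trial_indices(tensor, labels[0])
    pos = _trial_indices(tensor, labels[1])
    if min(len(neg), len(pos)) < n_folds:
        raise ValueError(
            f"pair {labels}: classes of size {len(neg)}/{len(pos)}; "
            f"need >= {n_folds} trials per class"
        )
    rng = np.random.default_rng(seed)
    n_per = min(len(neg), len(pos))
    neg = rng.choice(neg, size=n_per, replace=False)
    pos = rng.choice(pos, size=n_per, replace=False)
    idx = np.concatenate([neg, pos])
    y = np.concatenate([np.zeros(n_per, dtype=int), np.ones(n_per, dtype=int)])

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    folds = np.empty(len(idx), dtype=int)
    splits = list(skf.split(np.zeros(len(idx)), y))
    for f, (_, test) in enumerate(splits):
        folds[test] = f

    n_time = tensor.data.shape[2]
    tps = range(n_time) if timepoints is None else timepoints
    acc = np.full(n_time, np.nan)
    models: dict = {}
    data = tensor.data[idx]                       # balanced trials x cells x time
    blank = tensor.blank_mask[idx]
    C = 1.0 / regularization_strength
    for tp in tps:
        if blank[:, tp].any():
            continue
        X = data[:, :, tp]
        correct = 0
        for f, (train, test) in enumerate(splits):
            clf = LogisticRegression(C=C, max_iter=1000)  # default L2 penalty
            clf.fit(X[train], y[train])
            correct += int((clf.predict(X[test]) == y[test]).sum())
            models[(tp, f)] = clf
        acc[tp] = correct / len(idx)
    return DecodingProfile(
        labels=labels, time_axis_s=tensor.time_axis_s.copy(), accuracy=acc,
        n_folds=n_folds, regularization_strength=regularization_strength,
        trial_indices=idx, fold_assignment=folds, models=models,
    )


def cross_condition_evaluate(
    profile: DecodingProfile,
    tensor: TrialTensor,
    eval_label: str,
) -> np.ndarray:
    """Fraction of ``eval_label`` trials classified as the positive class.

    Evaluation trials never entered training (they belong to a different
    label); the fraction is averaged over the per-fold models at each
    timepoint. Returns NaN at skipped timepoints or if the label is absent.
    """
    ev = [i for i in _trial_indices(tensor, eval_label)
          if i not in set(profile.trial_indices)]
    n_time = tensor.data.shape[2]
    frac = np.full(n_time, np.nan)
    if not ev:
        warnings.warn(f"no evaluation trials with label {eval_label!r}")
        return frac
    X_all = tensor.data[ev]
    for tp in range(n_time):
        if not np.isfinite(profile.accuracy[tp]):
            continue
        if tensor.blank_mask[ev][:, tp].any():
            continue
        per_fold = [profile.models[(tp, f)].predict(X_all[:, :, tp]).mean()
                    for f in range(profile.n_folds) if (tp, f) in profile.models]
        if per_fold:
            frac[tp] = float(np.mean(per_fold))
    return frac


def significance_profile(accuracies: np.ndarray, chance: float = 0.5,
                         alpha: float = 0.05) -> np.ndarray:
    """Per-timepoint Wilcoxon signed-rank vs chance, Bonferroni corrected.

    ``accuracies`` is sessions x timepoints. The correction counts only
    timepoints that were actually testable. Timepoints where all sessions
    are identical (zero spread) are undefined and masked False.
    """
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.ndim != 2 or accuracies.shape[0] < 2:
        raise ValueError("need accuracies from at least 2 sessions")
    if accuracies.shape[0] < 6:
        warnings.warn(f"only {accuracies.shape[0]} sessions; low power")
    n_time = accuracies.shape[1]
    pvals = np.full(n_time, np.nan)
    for tp in range(n_time):
        col = accuracies[:, tp]
        col = col[np.isfinite(col)]
        if len(col) < 2 or np.allclose(col, chance):
            continue
        try:
            pvals[tp] = stats.wilcoxon(col - chance, alternative="two-sided").pvalue
        except ValueError:
            continue
    n_tested = int(np.sum(np.isfinite(pvals)))
    if n_tested == 0:
        return np.zeros(n_time, dtype=bool)
    return np.where(np.isfinite(pvals), pvals < alpha / n_tested, False)
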