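"""Trace preprocessing: neuropil subtraction, dF/F, QC, trial segmentation.

The pipeline is: subtract 0.7x the neuropil signal from each soma trace,
compute dF/F against the whole-session mean, discard cells whose maximum
dF/F exceeds 10 (transients that large are unlikely to arise from spikes),
then cut trial-aligned tensors spanning 2 s before to 8 s after onset, with
laser-contaminated frames blanked (stim frames plus two frames either side)
and post-stimulus activity baselined to the 2-s pre-onset mean.

Window lengths are converted to frames by rounding half-up; the number of
blanked stimulation frames is ceil(duration * rate). Blanked frames carry
no numeric meaning and must never enter downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .session import SessionData, TrialRecord
from .synth import stim_frame_count

PRE_WINDOW_S = 2.0
POST_WINDOW_S = 8.0
BLANK_PAD_FRAMES = 2


@dataclass
class DffMatrix:
    dff: np.ndarray                    # kept cells x frames
    kept_cell_ids: list[int]
    session_mean_F: np.ndarray         # per kept cell
    dropped_cell_ids: list[int] = field(default_factory=list)


@dataclass
class TrialTensor:
    """dF/F aligned to trial onsets.

    ``data`` is trials x cells x frames; ``time_axis_s`` spans -2 s to +8 s
    relative to onset; ``blank_mask`` (trials x frames) is True on frames
    excluded for laser artifact.
    """

    data: np.ndarray
    time_axis_s: np.ndarray
    blank_mask: np.ndarray
    trials: list[TrialRecord]
    cell_ids: list[int]
    frame_rate_hz: float
    baselined: bool = False

    @property
    def pre_frames(self) -> int:
        return int(np.sum(self.time_axis_s < 0))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def neuropil_subtract(F_soma: np.ndarray, F_neuropil: np.ndarray,
                      coeff: float = 0.7) -> np.ndarray:
    """F = F_soma - coeff * F_neuropil, elementwise."""
    F_soma = np.asarray(F_soma, dtype=float)
    F_neuropil = np.asarray(F_neuropil, dtype=float)
    if F_soma.shape != F_neuropil.shape:
        raise ValueError(f"shape mismatch: {F_soma.shape} vs {F_neuropil.shape}")
    return F_soma - coeff * F_neuropil


def compute_dff(F: np.ndarray, cell_ids: Sequence[int] | None = None) -> DffMatrix:
    """dF/F = (F - Fbar) / Fbar with Fbar the whole-session mean per cell.

    Neuropil subtraction can leave non-positive session means, for which
    the ratio is meaningless; such cells are dropped and reported. The
    positivity threshold is 1e-6 times the 95th percentile of all session
    means.
    """
    F = np.asarray(F, dtype=float)
    if cell_ids is None:
        cell_ids = list(range(F.shape[0]))
    mean_F = F.mean(axis=1)
    thresh = 1e-6 * np.percentile(mean_F, 95)
    keep = mean_F > max(thresh, 0.0)
    if not np.any(keep):
        raise ValueError("all cells dropped: no positive session-mean fluorescence")
    dropped = [int(cid) for cid, k in zip(cell_ids, keep) if not k]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} cells with non-positive mean F")
    kept_F = F[keep]
    kept_mean = mean_F[keep]
    dff = (kept_F - kept_mean[:, None]) / kept_mean[:, None]
    return DffMatrix(
        dff=dff,
        kept_cell_ids=[int(cid) for cid, k in zip(cell_ids, keep) if k],
        session_mean_F=kept_mean,
        dropped_cell_ids=dropped,
    )


def qc_filter_cells(dff: DffMatrix, max_dff: float = 10.0) -> DffMatrix:
    """Drop cells whose maximum dF/F exceeds ``max_dff``."""
    keep = dff.dff.max(axis=1) <= max_dff
    dropped = [cid for cid, k in zip(dff.kept_cell_ids, keep) if not k]
    return DffMatrix(
        dff=dff.dff[keep],
        kept_cell_ids=[cid for cid, k in zip(dff.kept_cell_ids, keep) if k],
        session_mean_F=dff.session_mean_F[keep],
        dropped_cell_ids=dff.dropped_cell_ids + dropped,
    )


def segment_trials(dff: DffMatrix, trials: Sequence[TrialRecord],
                   frame_rate_hz: float) -> TrialTensor:
    """Cut a trials x cells x frames tensor aligned at trial onset.

    Onset is the (sham) photostimulation for go/catch and reward delivery
    for reward-only trials. Go-trial frames with the stimulation laser on,
    plus two frames on either side, are blanked. Trials whose window falls
    outside the recording are dropped with a warning.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    pre = _round_half_up(PRE_WINDOW_S * frame_rate_hz)
    post = _round_half_up(POST_WINDOW_S * frame_rate_hz)
    n_frames_total = dff.dff.shape[1]

    kept_trials, slabs, masks = [], [], []
    for t in trials:
        lo, hi = t.onset_frame - pre, t.onset_frame + post
        if lo < 0 or hi > n_frames_total:
            warnings.warn(f"trial {t.trial_id} window [{lo},{hi}) outside recording; dropped")
            continue
        slab = dff.dff[:, lo:hi]
        mask = np.zeros(pre + post, dtype=bool)
        if t.trial_type == "go" and t.stim_duration_ms > 0:
            nstim = stim_frame_count(t.stim_duration_ms, frame_rate_hz)
            a = max(pre - BLANK_PAD_FRAMES, 0)
            b = min(pre + nstim + BLANK_PAD_FRAMES, pre + post)
            mask[a:b] = True
        kept_trials.append(t)
        slabs.append(slab)
        masks.append(mask)
    if not kept_trials:
        raise ValueError("no trials fit within the recording")

    time_axis = (np.arange(pre + post) - pre) / frame_rate_hz
    return TrialTensor(
        data=np.stack(slabs, axis=0),
        time_axis_s=time_axis,
        blank_mask=np.stack(masks, axis=0),
        trials=kept_trials,
        cell_ids=list(dff.kept_cell_ids),
        frame_rate_hz=frame_rate_hz,
    )


def baseline_post_stimulus(tensor: TrialTensor) -> TrialTensor:
    """Subtract each trial/cell's 2-s pre-onset mean from its post-onset trace.

    Pre-onset frames are left unmodified. Applying twice raises.
    """
    if tensor.baselined:
        raise ValueError("tensor is already baselined")
    pre = tensor.pre_frames
    data = tensor.data.copy()
    # blanked pre frames (the 2-frame pad before stimulation on go trials)
    # carry no numeric meaning and are excluded from the baseline
    valid = (~tensor.blank_mask[:, :pre]).astype(float)[:, None, :]
    base = (data[:, :, :pre] * valid).sum(axis=2, keepdims=True) \
        / np.maximum(valid.sum(axis=2, keepdims=True), 1.0)
    data[:, :, pre:] = data[:, :, pre:] - base
    return replace(tensor, data=data, baselined=True)


def sort_cells_for_raster(tensor: TrialTensor,
                          trial_types: Sequence[str] = ("hit", "miss", "reward_only"),
                          ) -> list[int]:
    """Display ordering from strongly inhibited to strongly excited.

    Cells are ranked by the sum over the given trial types of their
    trial-averaged post-stimulus response (unblanked frames only). Ties
    break stably by cell_id; the ordering is invariant to permuting the
    input cells.
    """
    if not tensor.baselined:
        raise ValueError("sort requires a baselined tensor")
    pre = tensor.pre_frames
    outcome_map = {"hit": "hit", "miss": "miss"}
    scores = np.zeros(len(tensor.cell_ids))
    for label in trial_types:
        if label == "reward_only":
            idx = [i for i, t in enumerate(tensor.trials) if t.trial_type == "reward_only"]
        else:
            idx = [i for i, t in enumerate(tensor.trials) if t.outcome == outcome_map.get(label, label)]
        if not idx:
            continue
        sub = tensor.data[idx][:, :, pre:]
        mask = ~tensor.blank_mask[idx][:, pre:]
        # trial-average over unblanked post frames, then sum over time
        w = mask[:, None, :].astype(float)
        avg = (sub * w).sum(axis=0) / np.maximum(w.sum(axis=0), 1.0)
        scores += avg.sum(axis=1)
    order = sorted(range(len(tensor.cell_ids)),
                   key=lambda i: (scores[i], tensor.cell_ids[i]))
    return [tensor.cell_ids[i] for i in order]


def preprocess_session(session: SessionData, neuropil_coeff: float = 0.7,
                       max_dff: float = 10.0) -> TrialTensor:
    """Full preprocessing chain from a raw session to a baselined tensor."""
    F = neuropil_subtract(session.F_soma, session.F_neuropil, neuropil_coeff)
    dff = qc_filter_cells(compute_dff(F, session.cell_ids()), max_dff)
    tensor = segment_trials(dff, session.trials, session.frame_rate_hz)
    return baseline_post_stimulus(tensor)


def write_tensor(tensor: TrialTensor, path) -> str:
    """Persist a trial tensor (datasets: dff_tensor, time_axis_s, blank_mask,
    kept_cell_ids, plus the trial table) to one HDF5 file."""
    import h5py
    from .session import trials_to_frame
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate_hz"] = tensor.frame_rate_hz
        f.attrs["baselined"] = tensor.baselined
        f.create_dataset("dff_tensor", data=tensor.data)
        f.create_dataset("time_axis_s", data=tensor.time_axis_s)
        f.create_dataset("blank_mask", data=tensor.blank_mask)
        f.create_dataset("kept_cell_ids", data=np.asarray(tensor.cell_ids, dtype=np.int64))
        df = trials_to_frame(tensor.trials)
        tg = f.create_group("trials")
        for col in df.columns:
            vals = df[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            tg.create_dataset(col, data=vals)
    return str(path)


def read_tensor(path) -> TrialTensor:
    import h5py
    import pandas as pd
    from .session import frame_to_trials, TRIAL_CSV_COLUMNS
    with h5py.File(path, "r") as f:
        cols = {}
        for col in TRIAL_CSV_COLUMNS:
            v = f["trials"][col][()]
            if v.dtype.kind == "S":
                v = np.array([x.decode() for x in v])
            cols[col] = v
        trials = frame_to_trials(pd.DataFrame(cols))
        return TrialTensor(
            data=f["dff_tensor"][()],
            time_axis_s=f["time_axis_s"][()],
            blank_mask=f["blank_mask"][()].astype(bool),
            trials=trials,
            cell_ids=[int(i) for i in f["kept_cell_ids"][()]],
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            baselined=bool(f.attrs["baselined"]),
        )
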