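"""Session data model and HDF5/CSV persistence.

A *session* is one behavioral recording: raw soma and neuropil fluorescence
traces (cells x frames, nominally 30 Hz), per-cell metadata (region label,
position, distance to the nearest photostimulation beam center), and a trial
table (onsets, trial types, targeted cells, licks, rewards, outcomes).

On disk a session is a single HDF5 file with groups::

    /traces/soma        float64 (n_cells, n_frames)
    /traces/neuropil    float64 (n_cells, n_frames)
    /cells/<column>     one dataset per CellMeta field
    /trials/<column>    one dataset per TrialRecord field

Frame indices are 0-based; all trial-table times are milliseconds relative
to trial onset. Missing licks/rewards are stored as NaN and surfaced as
``None`` in :class:`TrialRecord`, never as sentinel numbers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

REGIONS = ("S1", "S2")
TRIAL_TYPES = ("go", "catch", "reward_only")
OUTCOMES = ("hit", "miss", "false_positive", "correct_rejection", "too_soon", "unscored")
#: allowed target counts: 0 for catch/reward-only, the variable-count set, and 150
TARGET_COUNTS = (0, 5, 10, 20, 30, 40, 50, 150)

TRIAL_CSV_COLUMNS = [
    "trial_id", "onset_frame", "trial_type", "n_targets", "targeted_cell_ids",
    "first_lick_ms", "reward_time_ms", "outcome", "stim_duration_ms",
]


@dataclass
class CellMeta:
    """Metadata for one imaged cell.

    ``min_target_distance_um`` is the distance to the nearest photostimulation
    beam center across groups; cells within 15 um of a beam center count as
    direct targets.
    """

    cell_id: int
    region: str
    x_um: float = 0.0
    y_um: float = 0.0
    min_target_distance_um: float = math.inf
    is_target_candidate: bool = False


@dataclass
class TrialRecord:
    """One behavioral trial.

    ``stim_duration_ms`` is 250 for 5-50 targets, 760 for 150 targets
    (three 50-cell groups) and 0 on catch / reward-only trials.
    """

    trial_id: int
    onset_frame: int
    trial_type: str
    n_targets: int = 0
    targeted_cell_ids: list[int] = field(default_factory=list)
    first_lick_ms: Optional[float] = None
    reward_time_ms: Optional[float] = None
    outcome: str = "unscored"
    stim_duration_ms: float = 0.0


@dataclass
class SessionData:
    """Container tying traces, cell metadata and the trial table together."""

    F_soma: np.ndarray
    F_neuropil: np.ndarray
    cells: list[CellMeta]
    trials: list[TrialRecord]
    frame_rate_hz: float = 30.0
    session_id: str = "session"

    @property
    def n_cells(self) -> int:
        return self.F_soma.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F_soma.shape[1]

    def cell_ids(self) -> np.ndarray:
        return np.array([c.cell_id for c in self.cells], dtype=int)


class SessionFormatError(ValueError):
    """Raised when an on-disk container is missing groups or malformed."""


def validate_session(session: SessionData) -> list[str]:
    """Check all session invariants; return a list of violation messages.

    Violations are reported, never raised; an empty list means the session
    is valid. The function is pure: repeated calls give identical reports.
    """
    report: list[str] = []
    if session.F_soma.shape != session.F_neuropil.shape:
        report.append(
            f"F_soma shape {session.F_soma.shape} != F_neuropil shape "
            f"{session.F_neuropil.shape}"
        )
    if session.frame_rate_hz <= 0:
        report.append(f"frame_rate_hz must be positive, got {session.frame_rate_hz}")
    if session.F_soma.shape[0] != len(session.cells):
        report.append(
            f"{session.F_soma.shape[0]} trace rows but {len(session.cells)} cells"
        )

    ids = [c.cell_id for c in session.cells]
    if len(set(ids)) != len(ids):
        report.append("cell_id values are not unique")
    known = set(ids)
    for c in session.cells:
        if c.region not in REGIONS:
            report.append(f"cell {c.cell_id}: unknown region {c.region!r}")
        if c.min_target_distance_um < 0:
            report.append(f"cell {c.cell_id}: negative target distance")

    prev_onset = None
    for t in session.trials:
        tag = f"trial {t.trial_id}"
        if t.trial_type not in TRIAL_TYPES:
            report.append(f"{tag}: unknown trial_type {t.trial_type!r}")
        if t.outcome not in OUTCOMES:
            report.append(f"{tag}: unknown outcome {t.outcome!r}")
        if t.trial_type == "go" and t.n_targets <= 0:
            report.append(f"{tag}: go trial with n_targets={t.n_targets}")
        if t.trial_type in ("catch", "reward_only") and t.n_targets != 0:
            report.append(f"{tag}: {t.trial_type} trial with n_targets={t.n_targets}")
        if t.n_targets not in TARGET_COUNTS:
            report.append(f"{tag}: n_targets={t.n_targets} outside {TARGET_COUNTS}")
        if len(t.targeted_cell_ids) != t.n_targets:
            report.append(
                f"{tag}: {len(t.targeted_cell_ids)} targeted ids for "
                f"n_targets={t.n_targets}"
            )
        unknown = [i for i in t.targeted_cell_ids if i not in known]
        if unknown:
            report.append(f"{tag}: targeted cell ids not in session: {unknown}")
        if t.first_lick_ms is not None and t.first_lick_ms < 0:
            report.append(f"{tag}: negative first_lick_ms")
        if prev_onset is not None and t.onset_frame <= prev_onset:
            report.append(f"{tag}: onset_frame {t.onset_frame} not increasing")
        prev_onset = t.onset_frame
    return report


# ---------------------------------------------------------------------------
# trial table <-> DataFrame

def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial records as a DataFrame with the documented CSV columns."""
    rows = []
    for t in trials:
        rows.append({
            "trial_id": t.trial_id,
            "onset_frame": t.onset_frame,
            "trial_type": t.trial_type,
            "n_targets": t.n_targets,
            "targeted_cell_ids": ";".join(str(i) for i in t.targeted_cell_ids),
            "first_lick_ms": np.nan if t.first_lick_ms is None else t.first_lick_ms,
            "reward_time_ms": np.nan if t.reward_time_ms is None else t.reward_time_ms,
            "outcome": t.outcome,
            "stim_duration_ms": t.stim_duration_ms,
        })
    return pd.DataFrame(rows, columns=TRIAL_CSV_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SessionFormatError(f"trial table missing columns: {missing}")
    trials = []
    for _, row in df.iterrows():
        raw = row["targeted_cell_ids"]
        if isinstance(raw, float) and math.isnan(raw):
            raw = ""
        ids = [int(x) for x in str(raw).split(";") if x != ""]
        lick = row["first_lick_ms"]
        rew = row["reward_time_ms"]
        trials.append(TrialRecord(
            trial_id=int(row["trial_id"]),
            onset_frame=int(row["onset_frame"]),
            trial_type=str(row["trial_type"]),
            n_targets=int(row["n_targets"]),
            targeted_cell_ids=ids,
            first_lick_ms=None if pd.isna(lick) else float(lick),
            reward_time_ms=None if pd.isna(rew) else float(rew),
            outcome=str(row["outcome"]),
            stim_duration_ms=float(row["stim_duration_ms"]),
        ))
    return trials


def write_trial_csv(trials: Sequence[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trial_csv(path) -> list[TrialRecord]:
    return frame_to_trials(pd.read_csv(path))


# ---------------------------------------------------------------------------
# HDF5 container

def write_session(session: SessionData, path) -> str:
    """Write a session to one HDF5 file; raises on an invalid session."""
    report = validate_session(session)
    if report:
        raise ValueError("invalid session:\n" + "\n".join(report))
    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = session.session_id
        f.attrs["frame_rate_hz"] = float(session.frame_rate_hz)
        g = f.create_group("traces")
        g.create_dataset("soma", data=np.asarray(session.F_soma, dtype=np.float64))
        g.create_dataset("neuropil", data=np.asarray(session.F_neuropil, dtype=np.float64))

        cg = f.create_group("cells")
        cg.create_dataset("cell_id", data=np.array([c.cell_id for c in session.cells], dtype=np.int64))
        cg.create_dataset("region", data=np.array([c.region for c in session.cells], dtype="S8"))
        cg.create_dataset("x_um", data=np.array([c.x_um for c in session.cells], dtype=np.float64))
        cg.create_dataset("y_um", data=np.array([c.y_um for c in session.cells], dtype=np.float64))
        cg.create_dataset(
            "min_target_distance_um",
            data=np.array([c.min_target_distance_um for c in session.cells], dtype=np.float64),
        )
        cg.create_dataset(
            "is_target_candidate",
            data=np.array([c.is_target_candidate for c in session.cells], dtype=bool),
        )

        tg = f.create_group("trials")
        tr = session.trials
        tg.create_dataset("trial_id", data=np.array([t.trial_id for t in tr], dtype=np.int64))
        tg.create_dataset("onset_frame", data=np.array([t.onset_frame for t in tr], dtype=np.int64))
        tg.create_dataset("trial_type", data=np.array([t.trial_type for t in tr], dtype="S16"))
        tg.create_dataset("n_targets", data=np.array([t.n_targets for t in tr], dtype=np.int64))
        tg.create_dataset(
            "targeted_cell_ids",
            data=np.array([";".join(str(i) for i in t.targeted_cell_ids) for t in tr], dtype="S2048"),
        )
        tg.create_dataset(
            "first_lick_ms",
            data=np.array([np.nan if t.first_lick_ms is None else t.first_lick_ms for t in tr], dtype=np.float64),
        )
        tg.create_dataset(
            "reward_time_ms",
            data=np.array([np.nan if t.reward_time_ms is None else t.reward_time_ms for t in tr], dtype=np.float64),
        )
        tg.create_dataset("outcome", data=np.array([t.outcome for t in tr], dtype="S24"))
        tg.create_dataset(
            "stim_duration_ms",
            data=np.array([t.stim_duration_ms for t in tr], dtype=np.float64),
        )
    return str(path)


def read_session(path) -> SessionData:
    """Read a session container written by :func:`write_session`.

    Raises :class:`SessionFormatError` naming any missing group/field, and
    ``ValueError`` if the read-back session violates its invariants.
    """
    with h5py.File(path, "r") as f:
        for group in ("traces", "cells", "trials"):
            if group not in f:
                raise SessionFormatError(f"missing group /{group}")
        for ds in ("soma", "neuropil"):
            if ds not in f["traces"]:
                raise SessionFormatError(f"missing dataset /traces/{ds}")
        soma = f["traces/soma"][()]
        neuropil = f["traces/neuropil"][()]

        cg = f["cells"]
        for col in ("cell_id", "region"):
            if col not in cg:
                raise SessionFormatError(f"missing dataset /cells/{col}")
        n = cg["cell_id"].shape[0]

        def _cell_col(name, default):
            return cg[name][()] if name in cg else np.full(n, default)

        cells = [
            CellMeta(
                cell_id=int(cid),
                region=reg.decode() if isinstance(reg, bytes) else str(reg),
                x_um=float(x),
                y_um=float(y),
                min_target_distance_um=float(d),
                is_target_candidate=bool(tc),
            )
            for cid, reg, x, y, d, tc in zip(
                cg["cell_id"][()],
                cg["region"][()],
                _cell_col("x_um", 0.0),
                _cell_col("y_um", 0.0),
                _cell_col("min_target_distance_um", np.inf),
                _cell_col("is_target_candidate", False),
            )
        ]

        tg = f["trials"]
        for col in ("trial_id", "onset_frame", "trial_type", "n_targets"):
            if col not in tg:
                raise SessionFormatError(f"missing dataset /trials/{col}")
        cols = {name: tg[name][()] for name in tg}
        trials = []
        for i in range(len(cols["trial_id"])):
            ids_raw = cols["targeted_cell_ids"][i].decode()
            lick = float(cols["first_lick_ms"][i])
            rew = float(cols["reward_time_ms"][i])
            trials.append(TrialRecord(
                trial_id=int(cols["trial_id"][i]),
                onset_frame=int(cols["onset_frame"][i]),
                trial_type=cols["trial_type"][i].decode(),
                n_targets=int(cols["n_targets"][i]),
                targeted_cell_ids=[int(x) for x in ids_raw.split(";") if x != ""],
                first_lick_ms=None if math.isnan(lick) else lick,
                reward_time_ms=None if math.isnan(rew) else rew,
                outcome=cols["outcome"][i].decode(),
                stim_duration_ms=float(cols["stim_duration_ms"][i]),
            ))

        session = SessionData(
            F_soma=soma,
            F_neuropil=neuropil,
            cells=cells,
            trials=trials,
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            session_id=str(f.attrs["session_id"]),
        )
    report = validate_session(session)
    if report:
        raise ValueError("invalid session on disk:\n" + "\n".join(report))
    return session


def sessions_equal(a: SessionData, b: SessionData, rtol: float = 1e-9) -> bool:
    """Round-trip equality: exact for integers/enums, rtol for floats."""
    if a.session_id != b.session_id or not math.isclose(a.frame_rate_hz, b.frame_rate_hz, rel_tol=rtol):
        return False
    if not (np.allclose(a.F_soma, b.F_soma, rtol=rtol) and np.allclose(a.F_neuropil, b.F_neuropil, rtol=rtol)):
        return False
    if len(a.cells) != len(b.cells) or len(a.trials) != len(b.trials):
        return False
    for ca, cb in zip(a.cells, b.cells):
        da, db = dataclasses.asdict(ca), dataclasses.asdict(cb)
        for k in da:
            va, vb = da[k], db[k]
            if isinstance(va, float):
                if not (math.isclose(va, vb, rel_tol=rtol) or (math.isinf(va) and math.isinf(vb))):
                    return False
            elif va != vb:
                return False
    for ta, tb in zip(a.trials, b.trials):
        da, db = dataclasses.asdict(ta), dataclasses.asdict(tb)
        for k in da:
            va, vb = da[k], db[k]
            if isinstance(va, float) and isinstance(vb, float):
                if not math.isclose(va, vb, rel_tol=rtol):
                    return False
            elif va != vb:
                return False
    return True
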