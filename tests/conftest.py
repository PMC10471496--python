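import numpy as np
import pandas as pd
import pytest

from optoprop import synth
from optoprop.metrics import PopulationState
from optoprop.preprocess import TrialTensor, preprocess_session
from optoprop.session import CellMeta, SessionData, TrialRecord


SMALL_CONFIG = synth.SessionConfig(
    network=synth.NetworkConfig(N_cells=220, R_true=0.9, n_latent=2,
                                shared_gain=0.7),
    n_trials=60,
    frac_s1=0.75,
    n_target_candidates=150,
)


@pytest.fixture(scope="session")
def small_session():
    """One scaled-down synthetic session reused across test modules."""
    return synth.synthesize_session(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def small_tensor(small_session):
    return preprocess_session(small_session)


@pytest.fixture()
def tiny_session():
    """Hand-built 6-cell, 2-trial session for I/O and validation tests."""
    rng = np.random.default_rng(0)
    cells = [
        CellMeta(cell_id=i, region="S1" if i < 5 else "S2",
                 x_um=10.0 * i, y_um=20.0,
                 min_target_distance_um=3.0 if i < 5 else 200.0,
                 is_target_candidate=i < 5)
        for i in range(6)
    ]
    trials = [
        TrialRecord(trial_id=0, onset_frame=100, trial_type="go", n_targets=5,
                    targeted_cell_ids=[0, 1, 2, 3, 4], first_lick_ms=432.1,
                    outcome="hit", stim_duration_ms=250.0, reward_time_ms=432.1),
        TrialRecord(trial_id=1, onset_frame=500, trial_type="catch",
                    outcome="correct_rejection"),
    ]
    F = 50.0 + rng.standard_normal((6, 900))
    return SessionData(F_soma=F, F_neuropil=0.5 * F, cells=cells, trials=trials,
                       frame_rate_hz=30.0, session_id="tiny")


def make_population_state(trials, prestim, zscored=True):
    """PopulationState table straight from scored trials + known covariate."""
    tbl = pd.DataFrame({
        "trial_id": [t.trial_id for t in trials],
        "trial_type": [t.trial_type for t in trials],
        "outcome": [t.outcome for t in trials],
        "n_targets": [t.n_targets for t in trials],
        "pop_mean": 0.01 * np.arange(len(trials)),   # nonzero spread

        "pop_var": np.exp([prestim.get(t.trial_id, np.nan) for t in trials]),
        "pop_var_log": [prestim.get(t.trial_id, np.nan) for t in trials],
        "z_pop_var": [prestim.get(t.trial_id, np.nan) for t in trials],
        "z_pop_mean": 0.0,
    })
    return PopulationState(table=tbl, transform="log", zscored=zscored)


def simple_tensor(data, trials, frame_rate_hz=30.0, pre_frames=None,
                  blank_mask=None, baselined=True):
    """Wrap raw arrays into a TrialTensor for unit tests."""
    n_trials, _, n_frames = data.shape
    if pre_frames is None:
        pre_frames = n_frames // 5
    if blank_mask is None:
        blank_mask = np.zeros((n_trials, n_frames), dtype=bool)
    time_axis = (np.arange(n_frames) - pre_frames) / frame_rate_hz
    return TrialTensor(data=data, time_axis_s=time_axis, blank_mask=blank_mask,
                       trials=trials, cell_ids=list(range(data.shape[1])),
                       frame_rate_hz=frame_rate_hz, baselined=baselined)
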