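import numpy as np
import pandas as pd
import pytest

from ripplepipe.io import LaminarRecording, validate_trials
from ripplepipe.preprocess import RereferencedRecording


def make_recording(data, fs=1017.0, area="V1", spacing=150.0, t0=0.0):
    return LaminarRecording(
        session_id="test", area=area, data=np.asarray(data, float),
        fs=fs, contact_spacing=spacing, t0=t0,
    )


def make_reref(data, fs=1017.0, area="V1", t0=0.0):
    data = np.atleast_2d(np.asarray(data, float))
    return RereferencedRecording(
        session_id="test", area=area, data=data, fs=fs,
        contact_spacing=150.0, t0=t0,
    )


def make_trials(n=10, t_start=1.0, seed=0, iti=0.6):
    """Small canonical trial table with balanced factors."""
    rng = np.random.default_rng(seed)
    cells = [
        (c, f, s)
        for c in ("RF", "away")
        for f in ("narrow", "wide")
        for s in ("small", "large")
    ]
    rows, t = [], t_start
    for i in range(n):
        cue, focus, size = cells[i % 8]
        t_fix = t
        t_cue_on = t_fix + 0.3
        t_cue_off = t_cue_on + 0.25
        t_stim_on = t_cue_off + 1.0
        t_dim = t_stim_on + rng.uniform(0.75, 1.25)
        rows.append(
            dict(trial_id=i, cue_location=cue, focus=focus, stim_size=size,
                 t_fix=t_fix, t_cue_on=t_cue_on, t_cue_off=t_cue_off,
                 t_stim_on=t_stim_on, t_dim=t_dim,
                 t_release=t_dim + 0.31, outcome="hit", rt=np.nan)
        )
        t = t_dim + 0.31 + iti
    return validate_trials(pd.DataFrame(rows))


@pytest.fixture
def trials10():
    return make_trials(10)


@pytest.fixture
def pink_reref():
    """Seeded 3-channel rereferenced-style pink-noise recording, 30 s."""
    from ripplepipe.synth import SyntheticConfig, generate_background
    from ripplepipe.preprocess import bipolar_rereference

    cfg = SyntheticConfig(n_channels=5)
    raw = generate_background(cfg, seed=7, duration=30.0)
    return bipolar_rereference(raw)
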