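"""Session data model, on-disk formats, and trial-epoch slicing.

A recording session consists of

* one laminar LFP recording per cortical area (:class:`LaminarRecording`):
  a channels x samples matrix in microvolts with a sampling rate, the
  physical spacing of the probe contacts, and the session-clock time of the
  first sample;
* a trial table: one row per trial with the condition factors of the cued
  spatial-attention task (cue RF/away, narrow/wide attentional focus,
  small/large stimulus), the task event timestamps, outcome and reaction
  time; and
* optional sorted spike trains.

All event times live on a single per-session clock in seconds; trial-relative
times are derived on demand, never stored.

On-disk formats are deliberately plain: raw little-endian float32
(channel-major) plus a JSON sidecar for the LFP, CSV for trials, spikes and
detected events.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "IntegrityError",
    "LaminarRecording",
    "EpochDefinition",
    "CANONICAL_EPOCHS",
    "TRIAL_COLUMNS",
    "CUE_LEVELS",
    "FOCUS_LEVELS",
    "SIZE_LEVELS",
    "OUTCOME_LEVELS",
    "save_recording",
    "load_recording",
    "validate_trials",
    "load_trials",
    "save_trials",
    "load_spikes",
    "save_spikes",
    "read_events",
    "write_events",
    "epoch_windows",
]


class FormatError(Exception):
    """A file is missing or not in the expected on-disk format."""


class IntegrityError(Exception):
    """File contents contradict their own metadata."""


# --------------------------------------------------------------------------
# recordings
# --------------------------------------------------------------------------

AREAS = ("V1", "V4")


@dataclass
class LaminarRecording:
    """Multichannel laminar LFP: ``data[channel, sample]`` in microvolts.

    Parameters
    ----------
    session_id : str
    area : str
        Cortical area label, ``"V1"`` or ``"V4"``.
    data : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    contact_spacing : float
        Distance between adjacent probe contacts in micrometers.
    contact_ids : sequence of int
        One id per row of ``data``, ordered along the probe.
    t0 : float
        Session-clock time (s) of sample 0.
    """

    session_id: str
    area: str
    data: np.ndarray
    fs: float
    contact_spacing: float
    contact_ids: tuple = ()
    t0: float = 0.0

    _min_channels = 3

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise FormatError("data must be 2-D (channels x samples)")
        if self.area not in AREAS:
            raise FormatError(f"unknown area {self.area!r}; expected one of {AREAS}")
        if not self.fs > 0:
            raise FormatError("sampling rate must be positive")
        if not self.contact_spacing > 0:
            raise FormatError("contact spacing must be positive")
        if self.data.shape[0] < self._min_channels:
            raise FormatError(
                f"need at least {self._min_channels} channels, got {self.data.shape[0]}"
            )
        if not np.isfinite(self.data).all():
            raise IntegrityError("data contains non-finite values")
        if not self.contact_ids:
            self.contact_ids = tuple(range(self.data.shape[0]))
        self.contact_ids = tuple(int(c) for c in self.contact_ids)
        if len(self.contact_ids) != self.data.shape[0]:
            raise IntegrityError("contact_ids length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Session-clock time of every sample."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def index_at(self, t: float) -> int:
        """Sample index nearest to session time ``t`` (clipped to range)."""
        i = int(round((t - self.t0) * self.fs))
        return min(max(i, 0), self.n_samples - 1)

    def copy_with(self, **kw) -> "LaminarRecording":
        return replace(self, **kw)


def save_recording(rec: LaminarRecording, base: str | Path) -> Path:
    """Write ``<base>.lfp.f32`` (little-endian float32, channel-major) and
    ``<base>.json`` sidecar. Returns the sidecar path."""
    base = Path(base)
    datafile = Path(str(base) + ".lfp.f32")
    sidecar = Path(str(base) + ".json")
    rec.data.astype("<f4").tofile(datafile)
    meta = {
        "session_id": rec.session_id,
        "area": rec.area,
        "fs": rec.fs,
        "contact_spacing_um": rec.contact_spacing,
        "contact_ids": list(rec.contact_ids),
        "t0": rec.t0,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def load_recording(base: str | Path) -> LaminarRecording:
    """Load a recording written by :func:`save_recording`.

    ``base`` is the path stem, i.e. ``<base>.lfp.f32`` + ``<base>.json``
    must both exist.
    """
    datafile = Path(str(base) + ".lfp.f32")
    sidecar = Path(str(base) + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    if not datafile.exists():
        raise FormatError(f"missing data file {datafile}")
    meta = json.loads(sidecar.read_text())
    raw = np.fromfile(datafile, dtype="<f4")
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    if raw.size != n_ch * n_s:
        raise IntegrityError(
            f"{datafile}: {raw.size} samples on disk, sidecar says {n_ch}x{n_s}"
        )
    return LaminarRecording(
        session_id=meta["session_id"],
        area=meta["area"],
        data=raw.reshape(n_ch, n_s),
        fs=float(meta["fs"]),
        contact_spacing=float(meta["contact_spacing_um"]),
        contact_ids=tuple(meta["contact_ids"]),
        t0=float(meta.get("t0", 0.0)),
    )


# --------------------------------------------------------------------------
# trials
# --------------------------------------------------------------------------

CUE_LEVELS = ("RF", "away")
FOCUS_LEVELS = ("narrow", "wide")
SIZE_LEVELS = ("small", "large")
OUTCOME_LEVELS = ("hit", "miss", "false_alarm", "fixation_break", "blank")

TIME_COLUMNS = ("t_fix", "t_cue_on", "t_cue_off", "t_stim_on", "t_dim", "t_release")

TRIAL_COLUMNS = (
    "trial_id",
    "cue_location",
    "focus",
    "stim_size",
    *TIME_COLUMNS,
    "outcome",
    "rt",
)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and annotate a trial table.

    Checks factor levels and timestamp ordering, recomputes/validates RT
    (``rt = (t_release - t_dim) * 1000`` ms), and adds

    * ``rt_valid`` — False where RT is negative or missing,
    * ``excluded`` — True for fixation-break trials (kept, but flagged).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "rt"]
    if missing:
        raise FormatError(f"trial table missing columns: {missing}")
    df = df.copy()
    for col, levels in [
        ("cue_location", CUE_LEVELS),
        ("focus", FOCUS_LEVELS),
        ("stim_size", SIZE_LEVELS),
        ("outcome", OUTCOME_LEVELS),
    ]:
        bad = set(df[col].dropna().unique()) - set(levels)
        if bad:
            raise FormatError(f"unknown {col} level(s): {sorted(bad)}")

    order = df[["t_cue_on", "t_cue_off", "t_stim_on"]].to_numpy(float)
    full = np.isfinite(order).all(axis=1)
    ok = (order[full, 0] < order[full, 1]) & (order[full, 1] < order[full, 2])
    if not ok.all():
        raise IntegrityError("trial timestamps out of order (cue_on < cue_off < stim_on)")

    both = df["t_release"].notna() & df["t_dim"].notna()
    rt = (df.loc[both, "t_release"] - df.loc[both, "t_dim"]) * 1000.0
    if "rt" not in df.columns:
        df["rt"] = np.nan
    df.loc[both & df["rt"].isna(), "rt"] = rt
    df["rt_valid"] = df["rt"].notna() & (df["rt"] > 0)
    n_neg = int((df["rt"] < 0).sum())
    if n_neg:
        logger.warning("%d trial(s) with negative RT flagged invalid", n_neg)
    df["excluded"] = df["outcome"] == "fixation_break"
    return df


def load_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate ``trials.csv``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing trial table {path}")
    return validate_trials(pd.read_csv(path))


def save_trials(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# spikes and detected events
# --------------------------------------------------------------------------

def load_spikes(path: str | Path) -> pd.DataFrame:
    """Read ``spikes.csv`` (unit_id, channel, t); times must be sorted per unit."""
    df = pd.read_csv(path)
    need = {"unit_id", "channel", "t"}
    if not need <= set(df.columns):
        raise FormatError(f"spike table needs columns {sorted(need)}")
    for uid, g in df.groupby("unit_id"):
        if not np.all(np.diff(g["t"].to_numpy()) >= 0):
            raise IntegrityError(f"spike times of unit {uid} not sorted")
    return df


def save_spikes(df: pd.DataFrame, path: str | Path) -> None:
    df.sort_values(["unit_id", "t"]).to_csv(path, index=False)


EVENT_COLUMNS = (
    "session",
    "area",
    "channel",
    "t_start",
    "t_end",
    "t_center",
    "duration_ms",
    "peak_z",
    "peak_freq_hz",
)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event table missing columns: {missing}")
    return df


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# epochs
# --------------------------------------------------------------------------

_ANCHOR_COLUMN = {
    "fixation": "t_fix",
    "cue_off": "t_cue_off",
    "stim_on": "t_stim_on",
    "trial_gap": "t_release",
}


@dataclass(frozen=True)
class EpochDefinition:
    """A task epoch: a window ``[offset_start, offset_end)`` (s) relative to a
    per-trial anchor event."""

    name: str
    anchor: str
    offset_start: float
    offset_end: float

    def __post_init__(self):
        if self.anchor not in _ANCHOR_COLUMN:
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if not self.offset_end > self.offset_start:
            raise ValueError("offset_end must exceed offset_start")

    @property
    def duration(self) -> float:
        return self.offset_end - self.offset_start


#: The three epochs analysed throughout: a 200-ms precue window after
#: fixation onset, an 800-ms window after cue offset, and the sustained
#: stimulus response 300-750 ms after stimulus onset.
CANONICAL_EPOCHS = {
    "precue": EpochDefinition("precue", "fixation", 0.0, 0.200),
    "postcue": EpochDefinition("postcue", "cue_off", 0.0, 0.800),
    "sustained": EpochDefinition("sustained", "stim_on", 0.300, 0.750),
}


def epoch_windows(trials: pd.DataFrame, epoch: EpochDefinition) -> pd.DataFrame:
    """Per-trial session-time windows for ``epoch``.

    Trials lacking the anchor timestamp are skipped (logged). Windows are
    clipped so they never extend past the next trial's first anchor
    (``t_fix``); clipped-to-empty windows are dropped.

    Returns a DataFrame with columns ``trial_id, t_start, t_end``.
    """
    col = _ANCHOR_COLUMN[epoch.anchor]
    anchors = trials[col]
    skipped = int(anchors.isna().sum())
    if skipped:
        logger.info("epoch %s: skipping %d trial(s) without %s", epoch.name, skipped, col)
    ok = trials[anchors.notna()].copy()
    out = pd.DataFrame(
        {
            "trial_id": ok["trial_id"].to_numpy(),
            "t_start": ok[col].to_numpy(float) + epoch.offset_start,
            "t_end": ok[col].to_numpy(float) + epoch.offset_end,
        }
    )
    # clip at the following trial's start
    if "t_fix" in trials.columns and len(out):
        starts = np.sort(trials["t_fix"].dropna().to_numpy(float))
        if len(starts):
            nxt = np.searchsorted(starts, out["t_start"].to_numpy(), side="right")
            limit = np.where(
                nxt < len(starts), starts[np.minimum(nxt, len(starts) - 1)], np.inf
            )
            out["t_end"] = np.minimum(out["t_end"].to_numpy(), limit)
            out = out[out["t_end"] > out["t_start"]]
    return out.reset_index(drop=True)
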