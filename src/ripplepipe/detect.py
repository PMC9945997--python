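"""Ripple event detection on bipolar-rereferenced LFP channels.

A ripple is a brief (tens of ms) high-frequency (~100-180 Hz) oscillatory
LFP event. Detection per channel proceeds in the order:

1. band-pass the channel in the ripple band (default 80-250 Hz, zero-phase
   linear-phase FIR), square, and z-score using mean/SD computed over the
   entire recording of that channel;
2. candidate events = maximal runs above the candidate threshold (3.5 SD);
3. runs separated by gaps shorter than 5 ms are merged (the squared trace
   of even a strong burst dips below threshold twice per oscillation
   cycle, so merging is what turns cycles into one event);
4. merged runs outside 30-100 ms duration are excluded;
5. candidates whose within-event maximum does not exceed the confirmation
   threshold (5 SD) are discarded;
6. spectral validation: the peak frequency of a 200-ms Hanning-tapered,
   baseline-normalized power spectrum centered on the event must lie in
   80-200 Hz, which rejects line-noise transients and high-frequency
   artifacts that trip the envelope.

Event boundaries are the candidate-threshold crossings; the confirmation
threshold applies to the within-event maximum only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .io import LaminarRecording, EpochDefinition, epoch_windows

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "RippleEvent",
    "DegenerateSignalError",
    "ripple_envelope",
    "detect_candidates",
    "baseline_spectrum",
    "validate_peak_frequency",
    "detect_ripples",
    "label_events_by_epoch",
    "summarize_events",
]


class DegenerateSignalError(Exception):
    """A channel has zero variance and cannot be z-scored."""


@dataclass(frozen=True)
class DetectionConfig:
    """Detector parameters (defaults are the standard dual-threshold values).

    ``z_candidate``/``z_confirm`` are in SD units of the squared, z-scored
    ripple-band trace. ``pf_search_hz`` bounds the argmax search of the
    validation spectrum; events whose peak frequency falls outside
    ``[pf_min_hz, pf_max_hz]`` are rejected as false detections.
    ``smooth_ms`` is an optional boxcar applied to the squared trace before
    z-scoring; it defaults to off.
    """

    band: tuple[float, float] = (80.0, 250.0)
    z_candidate: float = 3.5
    z_confirm: float = 5.0
    merge_gap_ms: float = 5.0
    dur_min_ms: float = 30.0
    dur_max_ms: float = 100.0
    pf_min_hz: float = 80.0
    pf_max_hz: float = 200.0
    pf_window_ms: float = 200.0
    pf_search_hz: tuple[float, float] = (30.0, 300.0)
    smooth_ms: float = 0.0

    def __post_init__(self):
        if self.z_confirm < self.z_candidate:
            raise ValueError("z_confirm must be >= z_candidate")
        if not self.dur_min_ms < self.dur_max_ms:
            raise ValueError("dur_min_ms must be < dur_max_ms")
        if not self.pf_min_hz < self.pf_max_hz:
            raise ValueError("pf_min_hz must be < pf_max_hz")


@dataclass(frozen=True)
class RippleEvent:
    """One detected ripple, in session time."""

    session: str
    area: str
    channel: int
    t_start: float
    t_end: float
    t_center: float
    duration_ms: float
    peak_z: float
    peak_freq_hz: float


def ripple_envelope(rec: LaminarRecording, cfg: DetectionConfig = DetectionConfig()) -> np.ndarray:
    """Normalized ripple-band power trace, one row per channel (z units).

    Band-pass (zero-phase FIR), square, optionally boxcar-smooth, then
    z-score each channel with statistics over its whole duration.
    """
    if rec.fs < 2 * cfg.band[1]:
        raise ValueError("sampling rate below twice the band upper edge")
    taps = signal.firwin(int(0.2 * rec.fs) | 1, list(cfg.band), pass_zero=False, fs=rec.fs)
    bp = signal.filtfilt(taps, [1.0], rec.data, axis=-1)
    env = bp**2
    if cfg.smooth_ms > 0:
        w = max(int(round(cfg.smooth_ms * 1e-3 * rec.fs)), 1)
        kernel = np.ones(w) / w
        env = np.apply_along_axis(lambda x: np.convolve(x, kernel, mode="same"), -1, env)
    sd = env.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        bad = [rec.contact_ids[i] for i in np.where(sd[:, 0] == 0)[0]]
        raise DegenerateSignalError(f"zero-variance channel(s): {bad}")
    return (env - env.mean(axis=-1, keepdims=True)) / sd


def _runs_above(mask: np.ndarray) -> np.ndarray:
    """Half-open [start, end) index pairs of maximal True runs."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return np.column_stack([starts, ends])


def detect_candidates(
    env: np.ndarray, fs: float, cfg: DetectionConfig = DetectionConfig()
) -> list[tuple[int, int, float]]:
    """Provisional events on one normalized power trace.

    Returns ``(start, end, peak_z)`` tuples with half-open sample indices:
    supra-candidate runs, gap-merged, duration-gated, then confirmed
    against the within-event maximum.
    """
    env = np.asarray(env, float)
    if not np.isfinite(env).all():
        raise ValueError("envelope contains non-finite values")
    runs = _runs_above(env > cfg.z_candidate)
    if len(runs) == 0:
        return []
    gap = cfg.merge_gap_ms * 1e-3 * fs
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    out = []
    for s, e in merged:
        dur_ms = (e - s) / fs * 1e3
        if not cfg.dur_min_ms <= dur_ms <= cfg.dur_max_ms:
            continue
        peak = float(env[s:e].max())
        if peak > cfg.z_confirm:
            out.append((int(s), int(e), peak))
    return out


def baseline_spectrum(x: np.ndarray, fs: float, window_ms: float = 200.0) -> tuple[np.ndarray, np.ndarray]:
    """Median Hanning-tapered power spectrum over non-overlapping windows.

    Serves as the per-channel 1/f baseline that peak-frequency validation
    divides out; the median is robust to the (rare) windows that contain
    ripples. Returns ``(freqs, spectrum)``.
    """
    n = int(round(window_ms * 1e-3 * fs))
    n_win = len(x) // n
    if n_win < 1:
        raise ValueError("signal shorter than one spectral window")
    segs = x[: n_win * n].reshape(n_win, n)
    w = np.hanning(n)
    segs = (segs - segs.mean(axis=1, keepdims=True)) * w
    pxx = np.abs(np.fft.rfft(segs, axis=1)) ** 2
    freqs = np.fft.rfftfreq(n, 1 / fs)
    return freqs, np.median(pxx, axis=0)


def validate_peak_frequency(
    center_idx: int,
    lfp: np.ndarray,
    fs: float,
    cfg: DetectionConfig = DetectionConfig(),
    baseline: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[bool, float]:
    """Spectral validation of one event on its rereferenced LFP channel.

    A ``pf_window_ms`` window centered on the event is Hanning-tapered,
    its power spectrum divided by the channel baseline spectrum (if given),
    and the argmax taken over ``pf_search_hz``. Windows that do not fit are
    shrunk symmetrically (logged). Returns ``(keep, peak_freq_hz)``.
    """
    half = int(round(cfg.pf_window_ms * 1e-3 * fs / 2))
    half_eff = min(half, center_idx, len(lfp) - 1 - center_idx)
    if half_eff < half:
        logger.info("peak-frequency window shrunk to +-%d samples at edge", half_eff)
    if half_eff < 4:
        return False, np.nan
    seg = lfp[center_idx - half_eff : center_idx + half_eff]
    w = np.hanning(len(seg))
    pxx = np.abs(np.fft.rfft((seg - seg.mean()) * w)) ** 2
    freqs = np.fft.rfftfreq(len(seg), 1 / fs)
    if baseline is not None:
        bf, bs = baseline
        ref = np.interp(freqs, bf, bs)
        pxx = pxx / np.maximum(ref, np.finfo(float).tiny)
    lo, hi = cfg.pf_search_hz
    sel = (freqs >= lo) & (freqs <= hi)
    pf = float(freqs[sel][np.argmax(pxx[sel])])
    return cfg.pf_min_hz <= pf <= cfg.pf_max_hz, pf


def detect_ripples(
    rec: LaminarRecording, cfg: DetectionConfig = DetectionConfig()
) -> pd.DataFrame:
    """Run the full detector on every channel of a rereferenced recording.

    Returns a tidy event table with columns
    ``session, area, channel, t_start, t_end, t_center, duration_ms,
    peak_z, peak_freq_hz`` (times on the session clock, channel = contact
    id of the rereferenced row).
    """
    env = ripple_envelope(rec, cfg)
    rows = []
    for ch in range(rec.n_channels):
        cands = detect_candidates(env[ch], rec.fs, cfg)
        if not cands:
            continue
        base = baseline_spectrum(rec.data[ch], rec.fs, cfg.pf_window_ms)
        for s, e, peak in cands:
            center = (s + e) // 2
            keep, pf = validate_peak_frequency(center, rec.data[ch], rec.fs, cfg, base)
            if not keep:
                continue
            rows.append(
                {
                    "session": rec.session_id,
                    "area": rec.area,
                    "channel": rec.contact_ids[ch],
                    "t_start": rec.t0 + s / rec.fs,
                    "t_end": rec.t0 + e / rec.fs,
                    "t_center": rec.t0 + (s + e) / 2 / rec.fs,
                    "duration_ms": (e - s) / rec.fs * 1e3,
                    "peak_z": peak,
                    "peak_freq_hz": pf,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "session",
            "area",
            "channel",
            "t_start",
            "t_end",
            "t_center",
            "duration_ms",
            "peak_z",
            "peak_freq_hz",
        ],
    )


def label_events_by_epoch(
    events: pd.DataFrame,
    trials: pd.DataFrame,
    epochs: dict[str, EpochDefinition],
) -> pd.DataFrame:
    """Attach ``epoch`` and ``trial_id`` to events by their center time.

    Events outside every epoch window get ``epoch = NaN``. Epoch windows of
    the canonical task are disjoint within a trial, so the assignment is
    unambiguous.
    """
    events = events.copy()
    events["epoch"] = pd.NA
    events["trial_id"] = pd.NA
    t = events["t_center"].to_numpy(float)
    for name, ep in epochs.items():
        win = epoch_windows(trials, ep)
        for _, w in win.iterrows():
            inside = (t >= w["t_start"]) & (t < w["t_end"])
            events.loc[inside, "epoch"] = name
            events.loc[inside, "trial_id"] = w["trial_id"]
    return events


def summarize_events(events: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-epoch duration and peak-frequency summaries plus Kruskal-Wallis
    tests across epochs.

    ``events`` must carry an ``epoch`` column. Epochs with zero events are
    excluded from the test (logged). Returns ``(summary, tests)`` where
    ``tests`` maps 'duration_ms'/'peak_freq_hz' to ``(H, p)``; tests are
    skipped (None) when fewer than two epochs have events.
    """
    ev = events.dropna(subset=["epoch"])
    summary = (
        ev.groupby("epoch")[["duration_ms", "peak_freq_hz"]]
        .agg(["mean", "sem", "count"])
        .sort_index()
    )
    tests: dict[str, tuple | None] = {}
    groups = [g for _, g in ev.groupby("epoch") if len(g)]
    if len(groups) < 2:
        logger.info("fewer than two epochs with events; KW test skipped")
        tests["duration_ms"] = tests["peak_freq_hz"] = None
        return summary, tests
    for col in ("duration_ms", "peak_freq_hz"):
        samples = [g[col].to_numpy(float) for g in groups]
        if np.ptp(np.concatenate(samples)) == 0:
            # identical values everywhere: no evidence of any epoch difference
            tests[col] = (0.0, 1.0)
            continue
        h, p = stats.kruskal(*samples)
        tests[col] = (float(h), float(p))
    return summary, tests
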