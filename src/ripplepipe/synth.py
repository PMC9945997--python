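"""Synthetic laminar sessions with known ground truth.

Emulates the phenomenology of laminar V1/V4 recordings during a cued
spatial-attention task so that every pipeline stage is testable without
recorded data:

* 1/f background LFP at 1,017 Hz on 16 contacts per area, with a
  depth-weighted common component (so bipolar rereferencing has real
  common-mode signal to reject);
* trial structure: fixation -> 250-ms cue -> 1,000-ms delay -> stimulus ->
  dimming target, with the three condition factors (cue RF/away,
  narrow/wide focus, small/large stimulus) balanced across trials;
* ripple events drawn as Poisson processes within epoch windows at
  condition-dependent rates, each realized as a Gaussian-enveloped
  sinusoid (100-180 Hz, 30-60 ms) scaled in multiples of the channel's
  ripple-band RMS;
* V4 partner events for a fraction of V1 ripples at a ~22-ms lag;
* spikes as inhomogeneous Poisson trains with a ripple-locked rate bump;
* reaction times from a linear model with session random intercepts and a
  ripple-trial reduction.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seeds give identical sessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io import (
    CANONICAL_EPOCHS,
    CUE_LEVELS,
    FOCUS_LEVELS,
    SIZE_LEVELS,
    EpochDefinition,
    LaminarRecording,
    epoch_windows,
    validate_trials,
)
from .preprocess import RereferencedRecording, bipolar_rereference

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Session",
    "default_sustained_rates",
    "generate_background",
    "generate_trials",
    "draw_poisson_events",
    "inject_burst",
    "inject_ripples",
    "inject_evoked_response",
    "generate_trials_spikes_rts",
    "generate_session",
    "simulate_rt_table",
    "simulate_rate_table",
    "detection_performance",
]

_CELLS = [(c, f, s) for c in CUE_LEVELS for f in FOCUS_LEVELS for s in SIZE_LEVELS]


def default_sustained_rates() -> dict:
    """Condition-cell ripple rates (events/s/contact) for the sustained epoch.

    Built multiplicatively from a stimulus-size base of 0.09 (small) vs
    0.04 (large) events/s, a cue-location multiplier of 1.45 (RF) vs 0.65
    (away), and an attentional-focus multiplier of 1.25 (wide) vs 0.75
    (narrow) — small stimuli, cued attention, and wide focus all raise the
    rate, the focus effect being the weakest.
    """
    size_base = {"small": 0.09, "large": 0.04}
    cue_mult = {"RF": 1.45, "away": 0.65}
    focus_mult = {"wide": 1.25, "narrow": 0.75}
    return {
        (c, f, s): size_base[s] * cue_mult[c] * focus_mult[f] for c, f, s in _CELLS
    }


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the study conditions."""

    # probe / signal
    n_channels: int = 16
    fs: float = 1017.0
    contact_spacing: float = 150.0  # um
    n_trials: int = 120
    # 1/f background
    background_alpha: float = 1.0
    background_rms: float = 40.0  # uV
    common_frac: float = 0.6
    # ripple bursts
    ripple_freq_range: tuple[float, float] = (100.0, 180.0)
    ripple_dur_range_ms: tuple[float, float] = (30.0, 60.0)
    ripple_amplitude_mult: float = 6.0  # x ripple-band RMS
    # per-epoch rates: scalar, or per condition cell for the sustained epoch
    rates: dict = field(
        default_factory=lambda: {
            "precue": 0.01,
            "postcue": 0.01,
            "sustained": default_sustained_rates(),
        }
    )
    # cross-area structure
    lag_mean_ms: float = 22.0
    lag_sd_ms: float = 5.0
    co_occurrence: float = 0.1
    # evoked response / laminar ground truth
    evoked_center_contact: int = 8
    evoked_depth_width: float = 1.2  # contacts
    evoked_amp: float = 120.0  # uV
    latency_base_ms: float = 40.0
    latency_slope_ms: float = 3.0  # per contact away from input center
    evoked_tau_ms: float = 4.0
    # spiking
    spike_baseline_hz: float = 22.0
    spike_ripple_gain_hz: float = 8.0
    spike_ripple_sd_ms: float = 25.0
    # reaction times (ms); base chosen so the no-ripple mean (base plus the
    # average condition effect) sits near 311 ms
    rt_base_ms: float = 312.0
    rt_effect_cue_rf: float = -1.5
    rt_effect_small: float = -1.5
    rt_effect_wide: float = 0.5
    rt_effect_ripple: float = -3.0
    rt_session_sd: float = 10.0
    rt_noise_sd: float = 30.0
    # trial timing (s)
    fix_to_cue: float = 0.300
    cue_duration: float = 0.250
    delay: float = 1.000
    stim_to_dim: tuple[float, float] = (0.75, 1.25)
    post_dim: float = 0.5
    intertrial: float = 0.5

    def __post_init__(self):
        for name, r in self.rates.items():
            vals = r.values() if isinstance(r, dict) else [r]
            if any(v < 0 for v in vals):
                raise ValueError(f"negative rate in epoch {name}")

    def cell_rate(self, epoch: str, cue: str, focus: str, size: str) -> float:
        r = self.rates.get(epoch, 0.0)
        return r[(cue, focus, size)] if isinstance(r, dict) else float(r)


@dataclass
class GroundTruth:
    """Injected-event list plus, when applicable, the true layer labels and
    the true trial-model coefficients."""

    events: pd.DataFrame  # area, channel, t_center, freq_hz, duration_ms, amplitude, epoch, trial_id
    layer_labels: dict | None = None
    model_coefficients: dict | None = None


@dataclass
class Session:
    """One fully generated session (both areas, rereferenced)."""

    recordings: dict  # area -> RereferencedRecording
    raw: dict  # area -> LaminarRecording
    trials: pd.DataFrame
    spikes: dict  # area -> spike DataFrame (unit_id, channel, t)
    truth: GroundTruth


_GT_COLUMNS = [
    "area",
    "channel",
    "t_center",
    "freq_hz",
    "duration_ms",
    "amplitude",
    "epoch",
    "trial_id",
]


# --------------------------------------------------------------------------
# background and trials
# --------------------------------------------------------------------------

def _pink(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise via spectral shaping of white noise."""
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2)
    y = np.fft.irfft(X * shape, n)
    return y / y.std()


def generate_background(
    cfg: SyntheticConfig, seed: int, area: str = "V1", duration: float = 60.0,
    session_id: str = "synth", t0: float = 0.0,
) -> LaminarRecording:
    """1/f^alpha background LFP with a depth-weighted common component.

    Each channel mixes a shared trace (weight varying smoothly with depth,
    fraction ``common_frac``) with independent noise, and is scaled to
    ``background_rms`` microvolts.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * cfg.fs))
    common = _pink(rng, n, cfg.fs, cfg.background_alpha)
    depth = np.arange(cfg.n_channels)
    weights = 1.0 + 0.25 * np.cos(2 * np.pi * depth / cfg.n_channels)
    data = np.empty((cfg.n_channels, n))
    a = cfg.common_frac
    b = np.sqrt(max(1.0 - a**2, 0.0))
    for ch in range(cfg.n_channels):
        ind = _pink(rng, n, cfg.fs, cfg.background_alpha)
        x = a * weights[ch] * common + b * ind
        data[ch] = x / x.std() * cfg.background_rms
    return LaminarRecording(
        session_id=session_id,
        area=area,
        data=data,
        fs=cfg.fs,
        contact_spacing=cfg.contact_spacing,
        t0=t0,
    )


def generate_trials(cfg: SyntheticConfig, seed: int, t_start: float = 1.0) -> pd.DataFrame:
    """Balanced factorial trial table with the canonical task timing.

    Fixation -> cue (250 ms) -> delay (1 s) -> stimulus -> dimming target
    after 0.75-1.25 s. RT and release time are left NaN until
    :func:`generate_trials_spikes_rts` assigns them.
    """
    rng = np.random.default_rng(seed)
    cells = (_CELLS * (cfg.n_trials // len(_CELLS) + 1))[: cfg.n_trials]
    order = rng.permutation(cfg.n_trials)
    rows = []
    t = t_start
    for i in range(cfg.n_trials):
        cue, focus, size = cells[order[i]]
        t_fix = t
        t_cue_on = t_fix + cfg.fix_to_cue
        t_cue_off = t_cue_on + cfg.cue_duration
        t_stim_on = t_cue_off + cfg.delay
        t_dim = t_stim_on + rng.uniform(*cfg.stim_to_dim)
        rows.append(
            {
                "trial_id": i,
                "cue_location": cue,
                "focus": focus,
                "stim_size": size,
                "t_fix": t_fix,
                "t_cue_on": t_cue_on,
                "t_cue_off": t_cue_off,
                "t_stim_on": t_stim_on,
                "t_dim": t_dim,
                "t_release": np.nan,
                "outcome": "hit",
                "rt": np.nan,
            }
        )
        t = t_dim + cfg.post_dim + cfg.intertrial
    return validate_trials(pd.DataFrame(rows))


def session_duration(trials: pd.DataFrame, margin: float = 1.0) -> float:
    return float(trials["t_dim"].max()) + margin


# --------------------------------------------------------------------------
# ripple injection
# --------------------------------------------------------------------------

def draw_poisson_events(
    rng: np.random.Generator, windows: pd.DataFrame, rate: float
) -> list[tuple[float, object]]:
    """Homogeneous Poisson event times within per-trial windows.

    Returns ``(time, trial_id)`` tuples; the count in each window is
    Poisson(rate * duration) and times are uniform within the window.
    """
    out = []
    for tid, s, e in windows[["trial_id", "t_start", "t_end"]].itertuples(index=False):
        k = rng.poisson(rate * (e - s))
        out.extend((float(t), tid) for t in rng.uniform(s, e, size=k))
    return out


def _burst(fs: float, freq: float, duration_ms: float, amplitude: float,
           phase: float = 0.0) -> np.ndarray:
    """Gaussian-enveloped sinusoid.

    The envelope SD is duration/2.2, chosen so the width of the burst that
    a 3.5-SD threshold on the squared ripple-band trace sees (at the
    default 6x band-RMS amplitude) approximately equals the nominal
    duration.
    """
    sigma = duration_ms * 1e-3 / 2.2
    half = int(round(4 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    return amplitude * np.exp(-0.5 * (t / sigma) ** 2) * np.sin(2 * np.pi * freq * t + phase)


def ripple_band_rms(rec: LaminarRecording, band: tuple[float, float] = (80.0, 250.0)) -> np.ndarray:
    """Per-channel RMS of the ripple-band component; the amplitude unit for
    injected bursts. Computed spectrally (Parseval over the band)."""
    n = rec.n_samples
    X = np.fft.rfft(rec.data, axis=-1)
    f = np.fft.rfftfreq(n, 1 / rec.fs)
    sel = (f >= band[0]) & (f <= band[1])
    power = 2.0 * np.sum(np.abs(X[:, sel]) ** 2, axis=-1) / n**2
    return np.sqrt(power)


def inject_burst(
    rec: LaminarRecording, channel_row: int, t_center: float, freq: float,
    duration_ms: float, amplitude: float, rng: np.random.Generator | None = None,
) -> None:
    """Add one burst in place on ``data[channel_row]``; silently clipped at
    the recording edges."""
    phase = rng.uniform(0, 2 * np.pi) if rng is not None else 0.0
    w = _burst(rec.fs, freq, duration_ms, amplitude, phase)
    c = rec.index_at(t_center)
    half = len(w) // 2
    lo, hi = c - half, c + half + 1
    wlo = max(0, -lo)
    whi = len(w) - max(0, hi - rec.n_samples)
    rec.data[channel_row, max(lo, 0) : min(hi, rec.n_samples)] += w[wlo:whi]


def inject_ripples(
    rec: LaminarRecording,
    cfg: SyntheticConfig,
    trials: pd.DataFrame | None,
    seed: int,
    uniform_rate: float | None = None,
    epochs: dict[str, EpochDefinition] | None = None,
) -> tuple[LaminarRecording, GroundTruth]:
    """Inject Poisson ripple bursts into a copy of ``rec``.

    Rates are events/s *per contact* (the unit of the study's rate tables):
    with a trial table, events are drawn within each epoch window at
    ``n_channels x`` the condition cell's rate from ``cfg.rates`` and land
    on a random channel. With ``uniform_rate`` (and ``trials=None``),
    events are drawn uniformly over the recording — the detector-benchmark
    mode. Amplitudes are
    ``cfg.ripple_amplitude_mult x`` the channel's ripple-band RMS measured
    before injection; frequency and duration are uniform in the configured
    ranges. Events land on a random channel (row) of ``rec``.
    """
    rng = np.random.default_rng(seed)
    out = rec.copy_with(data=rec.data.copy())
    band_rms = ripple_band_rms(rec)
    epochs = epochs or CANONICAL_EPOCHS

    drawn: list[tuple[float, object, str]] = []
    if uniform_rate is not None:
        margin = 0.5
        win = pd.DataFrame(
            {"trial_id": [pd.NA], "t_start": [rec.t0 + margin],
             "t_end": [rec.t0 + rec.duration - margin]}
        )
        drawn += [
            (t, tid, "uniform")
            for t, tid in draw_poisson_events(rng, win, uniform_rate * out.n_channels)
        ]
    if trials is not None:
        for name, ep in epochs.items():
            for keys, cell in trials.groupby(list(("cue_location", "focus", "stim_size")), observed=True):
                rate = cfg.cell_rate(name, *keys)
                if rate <= 0:
                    continue
                win = epoch_windows(cell, ep)
                drawn += [
                    (t, tid, name)
                    for t, tid in draw_poisson_events(rng, win, rate * out.n_channels)
                ]

    rows = []
    for t_center, trial_id, epoch in sorted(drawn, key=lambda x: x[0]):
        ch = int(rng.integers(out.n_channels))
        freq = rng.uniform(*cfg.ripple_freq_range)
        dur = rng.uniform(*cfg.ripple_dur_range_ms)
        amp = cfg.ripple_amplitude_mult * band_rms[ch]
        inject_burst(out, ch, t_center, freq, dur, amp, rng)
        rows.append(
            {
                "area": rec.area,
                "channel": out.contact_ids[ch],
                "t_center": t_center,
                "freq_hz": freq,
                "duration_ms": dur,
                "amplitude": amp,
                "epoch": epoch,
                "trial_id": trial_id,
            }
        )
    events = pd.DataFrame(rows, columns=_GT_COLUMNS)
    return out, GroundTruth(events=events)


def inject_evoked_response(
    rec: LaminarRecording, trials: pd.DataFrame, cfg: SyntheticConfig
) -> tuple[LaminarRecording, dict]:
    """Add a stimulus-evoked transient with a laminar dipole profile.

    Each contact receives a negative alpha-function transient
    ``-A_ch (t/tau) exp(1 - t/tau)`` starting ``latency_ch`` after stimulus
    onset, with amplitude Gaussian in depth around the input-layer center
    (the CSD sink) and latency increasing with distance from it (the
    latency gradient). Returns the modified copy and the true layer labels
    for the interior contacts.
    """
    out = rec.copy_with(data=rec.data.copy())
    fs = rec.fs
    tau = cfg.evoked_tau_ms * 1e-3
    t = np.arange(0, int(0.08 * fs)) / fs
    kernel = (t / tau) * np.exp(1 - t / tau)
    center = cfg.evoked_center_contact
    for ch in range(rec.n_channels):
        dist = abs(ch - center)
        # sharp dipole component (localizes the CSD sink) on top of a broad
        # volume-conducted floor (keeps latency measurable at every depth)
        amp = cfg.evoked_amp * (
            0.3 + 0.7 * np.exp(-0.5 * (dist / cfg.evoked_depth_width) ** 2)
        )
        lat = (cfg.latency_base_ms + cfg.latency_slope_ms * dist) * 1e-3
        w = -amp * kernel
        for a in trials["t_stim_on"].dropna():
            i = rec.index_at(a + lat)
            hi = min(i + len(w), rec.n_samples)
            out.data[ch, i:hi] += w[: hi - i]
    labels = {}
    for c in rec.contact_ids[1:-1]:
        if abs(c - center) <= 1:
            labels[c] = "input"
        elif c < center:
            labels[c] = "superficial"
        else:
            labels[c] = "deep"
    return out, labels


# --------------------------------------------------------------------------
# spikes and reaction times
# --------------------------------------------------------------------------

def _ripple_trials(truth: GroundTruth, trials: pd.DataFrame,
                   epoch: EpochDefinition = CANONICAL_EPOCHS["sustained"]) -> set:
    win = epoch_windows(trials, epoch)
    t = truth.events["t_center"].to_numpy(float)
    hit = set()
    for tid, s, e in win[["trial_id", "t_start", "t_end"]].itertuples(index=False):
        if np.any((t >= s) & (t < e)):
            hit.add(tid)
    return hit


def generate_trials_spikes_rts(
    cfg: SyntheticConfig,
    truth: GroundTruth,
    seed: int,
    trials: pd.DataFrame | None = None,
    channels: list | None = None,
    duration: float | None = None,
    session_intercept: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill in RTs and generate spike trains consistent with ground truth.

    RTs follow ``base + condition effects + ripple effect + session
    intercept + noise`` where the ripple indicator marks trials with an
    injected event in the sustained window. Spikes are inhomogeneous
    Poisson (1-ms resolution): per-contact baseline rate plus a Gaussian
    rate bump of ``spike_ripple_gain_hz`` (SD ``spike_ripple_sd_ms``) at
    each injected event on that contact.
    """
    rng = np.random.default_rng(seed)
    if trials is None:
        trials = generate_trials(cfg, seed=int(rng.integers(2**31)))
    trials = trials.copy()
    if duration is None:
        duration = session_duration(trials)
    if channels is None:
        channels = sorted(truth.events["channel"].unique()) or list(range(1, cfg.n_channels - 1))
    if session_intercept is None:
        session_intercept = rng.normal(0, cfg.rt_session_sd)

    rippled = _ripple_trials(truth, trials)
    rt = (
        cfg.rt_base_ms
        + np.where(trials["cue_location"] == "RF", cfg.rt_effect_cue_rf, 0.0)
        + np.where(trials["stim_size"] == "small", cfg.rt_effect_small, 0.0)
        + np.where(trials["focus"] == "wide", cfg.rt_effect_wide, 0.0)
        + np.where(trials["trial_id"].isin(rippled), cfg.rt_effect_ripple, 0.0)
        + session_intercept
        + rng.normal(0, cfg.rt_noise_sd, len(trials))
    )
    trials["rt"] = np.maximum(rt, 100.0)
    trials["t_release"] = trials["t_dim"] + trials["rt"] / 1000.0
    trials["rt_valid"] = True

    dt = 1e-3
    n_bins = int(round(duration / dt))
    tgrid = (np.arange(n_bins) + 0.5) * dt
    sd = cfg.spike_ripple_sd_ms * 1e-3
    rows = []
    for ch in channels:
        lam = np.full(n_bins, cfg.spike_baseline_hz)
        for tc in truth.events.loc[truth.events["channel"] == ch, "t_center"]:
            lo = max(int((tc - 4 * sd) / dt), 0)
            hi = min(int((tc + 4 * sd) / dt) + 1, n_bins)
            lam[lo:hi] += cfg.spike_ripple_gain_hz * np.exp(
                -0.5 * ((tgrid[lo:hi] - tc) / sd) ** 2
            )
        fire = rng.random(n_bins) < lam * dt
        times = tgrid[fire] + rng.uniform(-dt / 2, dt / 2, fire.sum())
        rows.append(pd.DataFrame({"unit_id": f"u{ch}", "channel": ch, "t": np.sort(times)}))
    spikes = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["unit_id", "channel", "t"]
    )
    return trials, spikes


# --------------------------------------------------------------------------
# full sessions
# --------------------------------------------------------------------------

def generate_session(
    cfg: SyntheticConfig = SyntheticConfig(),
    seed: int = 0,
    areas: tuple[str, ...] = ("V1", "V4"),
    session_id: str | None = None,
    with_spikes: bool = True,
) -> Session:
    """Generate one complete synthetic session.

    Background is generated per area on the raw 16-contact probe and
    bipolar-rereferenced; ripple bursts are injected into the rereferenced
    channels (one ground-truth event maps to exactly one detectable event
    on one channel). V4 partner events are added for a ``co_occurrence``
    fraction of V1 events at a normally distributed lag.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(10)

    def child(i):
        return int(seeds[i].generate_state(1)[0] % 2**31)

    session_id = session_id or f"synth{seed}"
    trials = generate_trials(cfg, child(0))
    dur = session_duration(trials)

    recs, raws, spikes = {}, {}, {}
    truths = []
    for k, area in enumerate(areas):
        raw = generate_background(cfg, child(1 + k), area, dur, session_id)
        raws[area] = raw
        rec, gt = inject_ripples(bipolar_rereference(raw), cfg, trials, child(3 + k))
        recs[area] = rec
        truths.append(gt.events)

    # cross-area partners: a fraction of V1 events recur in V4 at a lag
    rng = np.random.default_rng(child(5))
    if "V1" in areas and "V4" in areas and len(truths[areas.index("V1")]):
        v1 = truths[areas.index("V1")]
        v4rec = recs["V4"]
        band_rms = ripple_band_rms(v4rec)
        partner_rows = []
        for _, ev in v1.iterrows():
            if rng.random() >= cfg.co_occurrence:
                continue
            lag = rng.normal(cfg.lag_mean_ms, cfg.lag_sd_ms) * 1e-3
            ch = int(rng.integers(v4rec.n_channels))
            freq = rng.uniform(*cfg.ripple_freq_range)
            durms = rng.uniform(*cfg.ripple_dur_range_ms)
            amp = cfg.ripple_amplitude_mult * band_rms[ch]
            tc = float(ev["t_center"]) + lag
            inject_burst(v4rec, ch, tc, freq, durms, amp, rng)
            partner_rows.append(
                {
                    "area": "V4",
                    "channel": v4rec.contact_ids[ch],
                    "t_center": tc,
                    "freq_hz": freq,
                    "duration_ms": durms,
                    "amplitude": amp,
                    "epoch": ev["epoch"],
                    "trial_id": ev["trial_id"],
                }
            )
        if partner_rows:
            truths.append(pd.DataFrame(partner_rows, columns=_GT_COLUMNS))

    events = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(columns=_GT_COLUMNS)
    truth = GroundTruth(
        events=events,
        model_coefficients={
            "rt_base_ms": cfg.rt_base_ms,
            "cue_rf": cfg.rt_effect_cue_rf,
            "small": cfg.rt_effect_small,
            "wide": cfg.rt_effect_wide,
            "ripple": cfg.rt_effect_ripple,
        },
    )
    # RTs once (depend on ripple occupancy of both areas), spikes per area
    trials, _ = generate_trials_spikes_rts(
        cfg, truth, child(6), trials=trials, duration=1.0, channels=[]
    )
    empty_spikes = pd.DataFrame(columns=["unit_id", "channel", "t"])
    for k, area in enumerate(areas):
        if not with_spikes:
            spikes[area] = empty_spikes
            continue
        area_truth = GroundTruth(events=events[events["area"] == area])
        _, spikes[area] = generate_trials_spikes_rts(
            cfg, area_truth, child(7 + k), trials=trials, duration=dur,
            channels=list(recs[area].contact_ids),
        )
    return Session(recordings=recs, raw=raws, trials=trials, spikes=spikes, truth=truth)


# --------------------------------------------------------------------------
# table-level simulators (for statistical calibration studies)
# --------------------------------------------------------------------------

def simulate_rate_table(
    cell_means,
    n_sessions: int,
    session_sd: float,
    noise_sd: float,
    seed: int,
    epoch: str = "sustained",
) -> pd.DataFrame:
    """Session x condition-cell rate table drawn from a Gaussian model.

    ``cell_means`` is a scalar (null: no condition effects) or a dict over
    ``(cue, focus, size)`` cells. Each session gets a random offset
    (``session_sd``) and each cell independent noise (``noise_sd``); rates
    are floored at 0.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sessions):
        off = rng.normal(0, session_sd)
        for c, f, sz in _CELLS:
            mu = cell_means[(c, f, sz)] if isinstance(cell_means, dict) else float(cell_means)
            rows.append(
                {
                    "session": f"s{s}",
                    "epoch": epoch,
                    "cue_location": c,
                    "focus": f,
                    "stim_size": sz,
                    "rate": max(mu + off + rng.normal(0, noise_sd), 0.0),
                }
            )
    return pd.DataFrame(rows)


def simulate_rt_table(
    cfg: SyntheticConfig,
    n_sessions: int,
    n_trials_per_session: int,
    seed: int,
    ripple_prob: float = 0.3,
) -> pd.DataFrame:
    """Trial-level RT table from the generator's linear model (no signal
    synthesis); for mixed-model calibration and parameter recovery."""
    rng = np.random.default_rng(seed)
    n = n_sessions * n_trials_per_session
    cue = rng.choice(CUE_LEVELS, n)
    focus = rng.choice(FOCUS_LEVELS, n)
    size = rng.choice(SIZE_LEVELS, n)
    ripple = rng.random(n) < ripple_prob
    session = np.repeat([f"s{i}" for i in range(n_sessions)], n_trials_per_session)
    intercepts = rng.normal(0, cfg.rt_session_sd, n_sessions)
    rt = (
        cfg.rt_base_ms
        + np.where(cue == "RF", cfg.rt_effect_cue_rf, 0.0)
        + np.where(size == "small", cfg.rt_effect_small, 0.0)
        + np.where(focus == "wide", cfg.rt_effect_wide, 0.0)
        + np.where(ripple, cfg.rt_effect_ripple, 0.0)
        + np.repeat(intercepts, n_trials_per_session)
        + rng.normal(0, cfg.rt_noise_sd, n)
    )
    return pd.DataFrame(
        {
            "session": session,
            "cue_location": cue,
            "focus": focus,
            "stim_size": size,
            "ripple": ripple,
            "rt_ms": rt,
        }
    )


# --------------------------------------------------------------------------
# evaluation against ground truth
# --------------------------------------------------------------------------

def detection_performance(
    truth_events: pd.DataFrame,
    detected: pd.DataFrame,
    duration: float,
    n_channels: int,
    tol_ms: float = 30.0,
) -> dict:
    """Recall and false-positive rate of a detection run.

    A truth event is recovered if a detected event on the same channel has
    its center within ``tol_ms``; detections matching no truth event count
    as false positives, normalized per channel-second.
    """
    tol = tol_ms * 1e-3
    matched_det: set[int] = set()
    n_hit = 0
    for _, ev in truth_events.iterrows():
        cand = detected[
            (detected["channel"] == ev["channel"])
            & (np.abs(detected["t_center"] - ev["t_center"]) <= tol)
        ]
        cand = cand[~cand.index.isin(matched_det)]
        if len(cand):
            n_hit += 1
            matched_det.add(cand.index[0])
    n_truth = len(truth_events)
    n_fp = len(detected) - len(matched_det)
    return {
        "recall": n_hit / n_truth if n_truth else float("nan"),
        "n_truth": n_truth,
        "n_detected": len(detected),
        "false_positive_rate": n_fp / (duration * n_channels),
    }
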