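"""Time-frequency decomposition and ripple-triggered power-power coupling.

Two decompositions are provided: a Hanning-tapered short-time Fourier
spectrogram (200-ms windows, 5-ms steps) and a complex Morlet wavelet
transform with center frequencies logarithmically spaced from 3 to 250 Hz
(40 steps, 7 cycles per frequency). The Morlet transform is computed by
frequency-domain convolution: the FFT of the signal is multiplied with the
(analytic) Gaussian spectrum of each wavelet and inverse-transformed.

The comodulogram asks whether spectral power at one frequency in a *trigger*
signal covaries with power at another frequency in a *target* signal around
ripple events: for each event, wavelet power is averaged over a 200-ms
window centered on the event in both signals, and the Pearson correlation
across events is computed for every frequency pair. Correlations are
Fisher-z transformed. Significance is assessed against a control
comodulogram built from condition- and time-matched ripple-free windows:
the events are split into disjoint blocks, a correlation matrix is computed
per block, and block-wise z values of ripple vs control are t-tested per
cell with Benjamini-Hochberg correction over all frequency pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import LaminarRecording

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrogram",
    "Comodulogram",
    "InsufficientDataError",
    "wavelet_freqs",
    "stft_spectrogram",
    "wavelet_spectrogram",
    "event_mean_power",
    "ripple_triggered_comodulogram",
    "correct_and_test",
]


class InsufficientDataError(Exception):
    """Too few events for a well-defined correlation."""


@dataclass
class Spectrogram:
    times: np.ndarray  # s, window centers
    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # [n_freq, n_time]
    scale: str = "linear"

    def __post_init__(self):
        if not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be strictly increasing")
        if self.scale == "linear" and np.any(self.power < 0):
            raise ValueError("linear power must be non-negative")


@dataclass
class Comodulogram:
    """Trigger x target frequency power-correlation matrix.

    ``r[i, j]`` is the Pearson correlation, across events, between
    window-mean power at ``trigger_freqs[i]`` in the trigger signal and at
    ``target_freqs[j]`` in the target signal; ``z = atanh(r)``.
    ``z_samples`` (optional) holds block-wise z matrices used for testing.
    """

    trigger_freqs: np.ndarray
    target_freqs: np.ndarray
    r: np.ndarray
    z: np.ndarray
    n_events: int
    z_samples: np.ndarray | None = None  # [n_blocks, n_trig, n_targ]
    p: np.ndarray | None = None
    sig_mask: np.ndarray | None = None


def wavelet_freqs(f_lo: float = 3.0, f_hi: float = 250.0, n_freq: int = 40) -> np.ndarray:
    """Logarithmically spaced Morlet center frequencies,
    ``f_k = f_lo * (f_hi/f_lo)**(k/(n_freq-1))``."""
    if n_freq < 2:
        raise ValueError("n_freq must be at least 2")
    return np.geomspace(f_lo, f_hi, n_freq)


# --------------------------------------------------------------------------
# spectrograms
# --------------------------------------------------------------------------

def stft_spectrogram(
    x: np.ndarray,
    fs: float,
    window_ms: float = 200.0,
    step_ms: float = 5.0,
    baseline: tuple[float, float] | None = None,
    t0: float = 0.0,
) -> Spectrogram:
    """Hanning-tapered sliding-window power spectrogram.

    Each window is mean-subtracted and tapered before the FFT. Power is
    normalized so that the sum over frequency bins equals the tapered
    window's mean square (Parseval within taper normalization). If
    ``baseline`` is an interval (s, relative to ``t0``), every spectrum is
    divided by the mean spectrum of windows falling inside it (1/f
    correction).
    """
    x = np.asarray(x, float)
    n = int(round(window_ms * 1e-3 * fs))
    step = max(int(round(step_ms * 1e-3 * fs)), 1)
    if len(x) < n:
        raise ValueError("signal shorter than one window")
    starts = np.arange(0, len(x) - n + 1, step)
    idx = starts[:, None] + np.arange(n)[None, :]
    segs = x[idx]
    w = np.hanning(n)
    segs = (segs - segs.mean(axis=1, keepdims=True)) * w
    spec = np.abs(np.fft.rfft(segs, axis=1)) ** 2
    # one-sided Parseval scaling: sum over bins == mean square of the
    # tapered window normalized by the taper energy
    scale = np.ones(spec.shape[1])
    scale[1:] = 2.0
    if n % 2 == 0:
        scale[-1] = 1.0
    spec = spec * scale / (n * (w**2).sum())
    freqs = np.fft.rfftfreq(n, 1 / fs)
    times = t0 + (starts + n / 2) / fs
    power = spec.T  # [n_freq, n_time]
    if baseline is not None:
        b_lo, b_hi = baseline
        inside = (times - t0 >= b_lo) & (times - t0 <= b_hi)
        if not inside.any():
            raise ValueError("baseline interval contains no spectrogram windows")
        ref = power[:, inside].mean(axis=1, keepdims=True)
        power = power / np.maximum(ref, np.finfo(float).tiny)
    return Spectrogram(times=times, freqs=freqs[1:], power=power[1:], scale="linear")


def _morlet_kernels(n: int, fs: float, freqs: np.ndarray, n_cycles: float) -> np.ndarray:
    """Analytic Morlet transfer functions on the FFT grid, one row per
    center frequency.

    Wavelets are unit-energy normalized (each row scaled by the square
    root of its spectral width), which keeps ridge localization unbiased
    across the constant-Q grid; per-frequency scaling cancels in the
    power-power correlations downstream.
    """
    f = np.fft.fftfreq(n, 1 / fs)
    sigma_f = freqs / n_cycles  # spectral width of each wavelet
    h = 2.0 * np.exp(-0.5 * ((f[None, :] - freqs[:, None]) / sigma_f[:, None]) ** 2)
    h[:, f < 0] = 0.0
    h[:, 0] *= 0.5
    h *= np.sqrt(sigma_f[0] / sigma_f)[:, None]
    return h


def wavelet_spectrogram(
    x: np.ndarray,
    fs: float,
    f_lo: float = 3.0,
    f_hi: float = 250.0,
    n_freq: int = 40,
    n_cycles: float = 7.0,
    t0: float = 0.0,
) -> Spectrogram:
    """Complex Morlet power via frequency-domain convolution.

    Power is the squared magnitude of the analytic wavelet coefficient; a
    pure tone of amplitude A yields power ~A^2 at the nearest center
    frequency.
    """
    if f_hi >= fs / 2:
        raise ValueError("f_hi must be below Nyquist")
    x = np.asarray(x, float)
    freqs = wavelet_freqs(f_lo, f_hi, n_freq)
    X = np.fft.fft(x)
    h = _morlet_kernels(len(x), fs, freqs, n_cycles)
    power = np.abs(np.fft.ifft(X[None, :] * h, axis=1)) ** 2
    times = t0 + np.arange(len(x)) / fs
    return Spectrogram(times=times, freqs=freqs, power=power, scale="linear")


def event_mean_power(
    rec: LaminarRecording,
    centers: np.ndarray,
    channels: np.ndarray | None,
    freqs: np.ndarray,
    window_ms: float = 200.0,
    n_cycles: float = 7.0,
) -> np.ndarray:
    """Window-mean Morlet power per event and frequency.

    For each event center time (session clock) the wavelet power of the
    event's channel (or the channel average when ``channels`` is None) is
    averaged over a centered window. Events whose window does not fit in
    the recording yield NaN rows. Returns ``[n_events, n_freq]``.

    Wavelet transforms are computed once per channel and frequency over the
    full recording, so cost scales with channels used, not with events.
    """
    centers = np.asarray(centers, float)
    half = int(round(window_ms * 1e-3 * rec.fs / 2))
    n = rec.n_samples
    out = np.full((len(centers), len(freqs)), np.nan)
    ci = np.round((centers - rec.t0) * rec.fs).astype(int)
    valid = (ci - half >= 0) & (ci + half <= n)
    if channels is None:
        ch_groups = {None: np.where(valid)[0]}
    else:
        channels = np.asarray(channels)
        ch_groups = {
            ch: np.where(valid & (channels == ch))[0] for ch in np.unique(channels[valid])
        }
    id_to_row = {cid: i for i, cid in enumerate(rec.contact_ids)}
    for ch, ev_idx in ch_groups.items():
        if len(ev_idx) == 0:
            continue
        if ch is None:
            sig = rec.data
        else:
            sig = rec.data[id_to_row[int(ch)]][None, :]
        X = np.fft.fft(sig, axis=-1)
        for k, fc in enumerate(freqs):
            h = _morlet_kernels(n, rec.fs, np.array([fc]), n_cycles)[0]
            p = (np.abs(np.fft.ifft(X * h[None, :], axis=-1)) ** 2).mean(axis=0)
            for j in ev_idx:
                out[j, k] = p[ci[j] - half : ci[j] + half].mean()
    return out


# --------------------------------------------------------------------------
# comodulogram
# --------------------------------------------------------------------------

def _corr_matrix(ptrig: np.ndarray, ptarg: np.ndarray) -> np.ndarray:
    """Pearson correlations between columns of two [n_events, n_freq]
    power matrices -> [n_trig_freq, n_targ_freq]."""
    a = ptrig - ptrig.mean(axis=0)
    b = ptarg - ptarg.mean(axis=0)
    sa = np.sqrt((a**2).sum(axis=0))
    sb = np.sqrt((b**2).sum(axis=0))
    r = a.T @ b / np.outer(np.maximum(sa, np.finfo(float).tiny), np.maximum(sb, np.finfo(float).tiny))
    return np.clip(r, -1.0, 1.0)


def ripple_triggered_comodulogram(
    trigger_events: pd.DataFrame,
    trigger_rec: LaminarRecording,
    target_rec: LaminarRecording,
    window_ms: float = 200.0,
    freqs: np.ndarray | None = None,
    n_cycles: float = 7.0,
    target_channel: int | None = None,
    n_blocks: int = 8,
    min_events: int = 10,
) -> Comodulogram:
    """Event-triggered power-power coupling between two recordings.

    For every event (row with ``t_center`` and ``channel``) wavelet power
    is window-averaged in the trigger recording (event's own channel) and
    in the target recording (``target_channel``, or the channel average),
    giving one power-by-frequency sample per event in each area. ``r`` is
    the across-event Pearson correlation for each frequency pair and
    ``z = atanh(r)`` its Fisher transform. Events are additionally split
    into ``n_blocks`` disjoint blocks whose per-block z matrices feed
    :func:`correct_and_test`.
    """
    if freqs is None:
        freqs = wavelet_freqs()
    centers = trigger_events["t_center"].to_numpy(float)
    chans = trigger_events["channel"].to_numpy() if "channel" in trigger_events else None
    ptrig = event_mean_power(trigger_rec, centers, chans, freqs, window_ms, n_cycles)
    tchan = None if target_channel is None else np.full(len(centers), target_channel)
    ptarg = event_mean_power(target_rec, centers, tchan, freqs, window_ms, n_cycles)
    ok = np.isfinite(ptrig).all(axis=1) & np.isfinite(ptarg).all(axis=1)
    n = int(ok.sum())
    if n < min_events:
        raise InsufficientDataError(f"only {n} events with valid windows (need {min_events})")
    ptrig, ptarg = ptrig[ok], ptarg[ok]
    with np.errstate(divide="ignore"):
        r = _corr_matrix(ptrig, ptarg)
        z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        z_samples = None
        if n_blocks and n >= 2 * n_blocks:
            blocks = np.array_split(np.arange(n), n_blocks)
            z_samples = np.stack(
                [
                    np.arctanh(
                        np.clip(_corr_matrix(ptrig[b], ptarg[b]), -1 + 1e-12, 1 - 1e-12)
                    )
                    for b in blocks
                ]
            )
    return Comodulogram(
        trigger_freqs=freqs,
        target_freqs=freqs,
        r=r,
        z=z,
        n_events=n,
        z_samples=z_samples,
    )


def correct_and_test(
    comod: Comodulogram, control: Comodulogram, alpha: float = 0.05
) -> Comodulogram:
    """Test each frequency pair of a comodulogram against a matched control.

    ``control`` must come from condition- and time-matched ripple-free
    windows with the same frequency grid and block structure. Block-wise z
    values are compared per cell with a two-sample t-test, and the p-value
    matrix is Benjamini-Hochberg corrected across all frequency pairs.
    Returns a new :class:`Comodulogram` with ``p`` and ``sig_mask`` set.
    """
    if comod.z.shape != control.z.shape:
        raise ValueError("comodulogram and control have different shapes")
    if comod.z_samples is None or control.z_samples is None:
        raise ValueError("block-wise z samples required; rerun with n_blocks >= 2")
    a, b = comod.z_samples, control.z_samples
    t, p = stats.ttest_ind(a, b, axis=0)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical cells: no evidence
    if alpha <= 0:
        sig = np.zeros_like(p, bool)
        p_adj = np.ones_like(p)
    else:
        rej, p_adj, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
        sig = rej.reshape(p.shape)
        p_adj = p_adj.reshape(p.shape)
    return Comodulogram(
        trigger_freqs=comod.trigger_freqs,
        target_freqs=comod.target_freqs,
        r=comod.r,
        z=comod.z,
        n_events=comod.n_events,
        z_samples=comod.z_samples,
        p=p_adj,
        sig_mask=sig,
    )
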