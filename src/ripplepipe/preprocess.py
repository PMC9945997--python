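"""Broadband conditioning and bipolar rereferencing of laminar LFPs.

The analysis-ready signal is obtained in two steps:

1. zero-phase band-pass filtering (default 0.5-300 Hz) followed by
   anti-aliased polyphase resampling to the working rate (1,017 Hz), and
2. bipolar rereferencing, ``y_i[n] = x_{i+1}[n] - x_{i-1}[n]``, which
   cancels signal common to neighboring contacts and localizes the LFP.
   The first and last contacts have no flanking neighbors and are dropped.

Zero phase matters here: event times extracted downstream (ripple onsets,
centers) must not be shifted by filter group delay, so all FIR filters are
applied forward-backward (``filtfilt``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .io import FormatError, LaminarRecording

logger = logging.getLogger(__name__)

__all__ = [
    "RereferencedRecording",
    "bandpass_zero_phase",
    "bandlimit_resample",
    "bipolar_rereference",
]


@dataclass
class RereferencedRecording(LaminarRecording):
    """Bipolar-rereferenced recording.

    Row ``i`` of ``data`` is the difference of parent contacts ``i+1`` and
    ``i-1`` (0-based); ``contact_ids`` are the parent ids of the *center*
    contacts, and ``parent_contact_ids`` preserves the full original list.
    """

    parent_contact_ids: tuple = ()

    _min_channels = 1


def _bandpass_taps(fs: float, f_lo: float, f_hi: float, transition_hz: float = 10.0) -> np.ndarray:
    """Linear-phase FIR band-pass taps (Hamming window design).

    The transition band is ``min(transition_hz, f_lo)`` so the low edge stays
    meaningful for sub-Hz cutoffs.
    """
    trans = min(transition_hz, max(f_lo, 0.1))
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1  # odd
    return signal.firwin(numtaps, [f_lo, f_hi], pass_zero=False, fs=fs)


def bandpass_zero_phase(
    data: np.ndarray, fs: float, f_lo: float, f_hi: float, transition_hz: float = 10.0
) -> np.ndarray:
    """Forward-backward FIR band-pass along the last axis (no group delay)."""
    if not 0 <= f_lo < f_hi:
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi >= fs / 2:
        raise ValueError(f"f_hi={f_hi} at or above Nyquist ({fs / 2})")
    taps = _bandpass_taps(fs, f_lo, f_hi, transition_hz)
    if data.shape[-1] <= 3 * len(taps):
        # short signals: shrink the filter rather than fail on padding
        numtaps = max(int(data.shape[-1] / 3.5) | 1, 11)
        taps = signal.firwin(numtaps, [f_lo, f_hi], pass_zero=False, fs=fs)
    return signal.filtfilt(taps, [1.0], data, axis=-1)


def bandlimit_resample(
    raw: LaminarRecording,
    band: tuple[float, float] = (0.5, 300.0),
    fs_out: float = 1017.0,
    transition_hz: float = 10.0,
) -> LaminarRecording:
    """Zero-phase band-pass, then polyphase decimation to ``fs_out``.

    Filtering precedes decimation so the anti-aliasing margin is set by the
    band's upper edge, which must lie below the output Nyquist rate. The
    resampling ratio may be non-integer (e.g. 32,756 -> 1,017 Hz).
    """
    f_lo, f_hi = band
    if fs_out > raw.fs:
        raise ValueError("fs_out must not exceed the input rate")
    if f_hi >= fs_out / 2:
        raise ValueError(f"band upper edge {f_hi} Hz >= output Nyquist {fs_out / 2} Hz")
    data = bandpass_zero_phase(raw.data, raw.fs, f_lo, f_hi, transition_hz)
    if fs_out != raw.fs:
        ratio = Fraction(fs_out / raw.fs).limit_denominator(10**6)
        data = signal.resample_poly(data, ratio.numerator, ratio.denominator, axis=-1)
    return raw.copy_with(data=data, fs=fs_out)


def bipolar_rereference(rec: LaminarRecording) -> RereferencedRecording:
    """Bipolar rereference: output row i = parent row i+2 minus parent row i.

    With parents indexed 0..n-1, output channel j sits at parent contact
    j+1 and equals ``x[j+2] - x[j]``; the edge contacts are excluded.
    """
    if rec.n_channels < 3:
        raise FormatError("bipolar rereferencing needs at least 3 channels")
    y = rec.data[2:, :] - rec.data[:-2, :]
    return RereferencedRecording(
        session_id=rec.session_id,
        area=rec.area,
        data=y,
        fs=rec.fs,
        contact_spacing=rec.contact_spacing,
        contact_ids=rec.contact_ids[1:-1],
        t0=rec.t0,
        parent_contact_ids=rec.contact_ids,
    )
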