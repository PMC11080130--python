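"""Filtering, stationary-segment selection, and overlapping analysis windows.

Raw trials are demeaned, notch-filtered at every 50 Hz harmonic inside the
analysis band, and bandpassed 10-500 Hz with a 3rd-order Butterworth filter.
All filtering is applied forward-backward (zero-phase), because several
downstream features (WL, SSC) are waveform-shape sensitive and phase
distortion would bias them.

The study selected a 3-s stationary segment of each contraction by visual
inspection; here the selection is automated and therefore testable: the
contiguous 3-s slice minimizing the variance of the 250-ms moving-RMS
envelope, summed over channels, is chosen (earliest slice on ties). Windows
are then cut at 200 ms length with a 50 ms step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import signal as sig

from .simulate import RawRecording

WINDOW_S = 0.200
STEP_S = 0.050
SEGMENT_S = 3.0
ENVELOPE_S = 0.250


@dataclass(frozen=True)
class FilterSpec:
    """Notch + bandpass filter parameters."""

    notch_base_hz: float = 50.0
    notch_q: float = 30.0
    band_low_hz: float = 10.0
    band_high_hz: float = 500.0
    band_order: int = 3

    def validate(self, fs: float) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz < fs / 2:
            raise ValueError("need 0 < low < high < fs/2")
        if self.band_order < 1:
            raise ValueError("bandpass order must be >= 1")

    def notch_harmonics(self) -> list[float]:
        """All multiples of the base frequency strictly inside the passband."""
        out, f = [], self.notch_base_hz
        while f < self.band_high_hz:
            out.append(f)
            f += self.notch_base_hz
        return out


@dataclass
class WindowMatrix:
    """Fixed-length overlapping windows of one channel of one trial."""

    trial_id: str
    channel: str
    window_len: int
    step: int
    windows: np.ndarray      # (n_windows, window_len)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def apply_filters(rec: RawRecording, spec: FilterSpec | None = None) -> RawRecording:
    """Zero-phase notch (every harmonic in band) + Butterworth bandpass."""
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    x = np.asarray(rec.samples, dtype=float)
    bad = ~np.isfinite(x)
    if bad.any():
        ch = rec.channel_labels[int(np.flatnonzero(bad.any(axis=1))[0])]
        raise ValueError(f"non-finite samples in channel {ch}")
    y = x - x.mean(axis=1, keepdims=True)
    for f0 in spec.notch_harmonics():
        b, a = sig.iirnotch(f0, spec.notch_q, fs=rec.fs)
        # pad by ~3 notch time constants (2Q/omega0) to absorb ring-down
        pad = min(y.shape[1] - 1, int(3 * spec.notch_q * rec.fs / (np.pi * f0)))
        y = sig.filtfilt(b, a, y, axis=1, padlen=pad)
    sos = sig.butter(spec.band_order, [spec.band_low_hz, spec.band_high_hz],
                     btype="bandpass", fs=rec.fs, output="sos")
    y = sig.sosfiltfilt(sos, y, axis=1)
    return _dc_replace(rec, samples=y)


def _moving_rms(x: np.ndarray, width: int) -> np.ndarray:
    """Per-channel moving RMS over ``width`` samples ('valid' alignment)."""
    sq = x**2
    csum = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(sq, axis=1)], axis=1)
    window_sums = csum[:, width:] - csum[:, :-width]
    return np.sqrt(np.maximum(window_sums / width, 0.0))


def select_segment(rec: RawRecording, duration: float = SEGMENT_S
                   ) -> tuple[RawRecording, tuple[int, int]]:
    """Pick the most stationary contiguous ``duration``-second slice.

    The criterion is the variance of the 250-ms moving-RMS envelope summed
    over channels, minimized over all candidate start samples; the earliest
    start wins ties. Returns the sliced recording and its (start, stop)
    sample boundaries in the original trial.
    """
    seg_len = int(round(duration * rec.fs))
    n = rec.samples.shape[1]
    if n < seg_len:
        raise ValueError(f"trial shorter than {duration} s")
    if n == seg_len:
        return _dc_replace(rec, samples=rec.samples.copy()), (0, seg_len)

    env_w = int(round(ENVELOPE_S * rec.fs))
    env = _moving_rms(rec.samples, env_w)          # (C, n - env_w + 1)
    sub_len = seg_len - env_w + 1                  # envelope samples per slice
    m = env.shape[1]
    csum = np.concatenate([np.zeros((env.shape[0], 1)), np.cumsum(env, axis=1)], axis=1)
    csum2 = np.concatenate([np.zeros((env.shape[0], 1)), np.cumsum(env**2, axis=1)],
                           axis=1)
    n_starts = m - sub_len + 1
    s = np.arange(n_starts)
    seg_sum = csum[:, s + sub_len] - csum[:, s]
    seg_sum2 = csum2[:, s + sub_len] - csum2[:, s]
    var = seg_sum2 / sub_len - (seg_sum / sub_len) ** 2
    crit = var.sum(axis=0)
    start = int(np.argmin(np.round(crit, 12)))     # earliest minimum wins
    sl = rec.samples[:, start : start + seg_len].copy()
    return _dc_replace(rec, samples=sl), (start, start + seg_len)


def make_windows(segment: RawRecording) -> list[WindowMatrix]:
    """Cut 200-ms windows with a 50-ms step; one WindowMatrix per channel."""
    wlen = int(round(WINDOW_S * segment.fs))
    step = int(round(STEP_S * segment.fs))
    n = segment.samples.shape[1]
    if n < wlen:
        raise ValueError("segment shorter than one analysis window")
    n_win = (n - wlen) // step + 1
    starts = np.arange(n_win) * step
    out = []
    for c, label in enumerate(segment.channel_labels):
        wins = np.stack([segment.samples[c, s : s + wlen] for s in starts])
        out.append(WindowMatrix(segment.trial_id, label, wlen, step, wins))
    return out
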