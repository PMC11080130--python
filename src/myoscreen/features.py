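"""The nine window-level sEMG features, MVC normalization, and aggregation.

Six Hudgins time-domain features are computed per 200-ms window: root mean
square (RMS), mean absolute value (MAV), integrated EMG (iEMG), waveform
length (WL), zero crossings (ZC) and slope sign changes (SSC), the last two
with a configurable amplitude deadband.

Three time-frequency features come from the continuous wavelet transform with
a Morlet mother wavelet psi(t) = exp(i*w0*t) exp(-t^2/2):

    C(a, b) = a^{-1/2} * sum_k x[k] psi*((k - b)/a)

evaluated at the scale set {3.6, 4.6, ..., 62.6} (in samples; pseudo-frequency
f = w0 * fs / (2 pi a), spanning roughly 25-440 Hz at fs = 2000 and w0 = 5):

* CWT_power  — per-scale mean of |C|^2, averaged over scales;
* WE         — Shannon entropy (natural log) of the normalized per-scale
               power distribution;
* CWT_kurtosis — unbiased excess kurtosis of the m = 100 kernel-density
               estimates of the PDF of pooled coefficient moduli.

Features of sub-maximal trials are normalized channel-specifically by the
mean feature value over the subject's three MVC trials, then averaged to
trial- and subject-level tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import fft as sfft

MORLET_W0 = 5.0
DEFAULT_SCALES = tuple(np.arange(3.6, 62.6 + 0.5, 1.0))   # 60 scales
KDE_GRID_POINTS = 100
KDE_BINS = 512            # linear-binning resolution for the KDE evaluation
KERNEL_HALFWIDTH = 6.0    # Morlet support truncation, in units of the scale

FEATURE_NAMES = ("RMS", "MAV", "iEMG", "WL", "ZC", "SSC",
                 "CWT_power", "WE", "CWT_kurtosis")
AMPLITUDE_FEATURES = ("RMS", "MAV", "iEMG", "WL", "CWT_power")


@dataclass
class CWTCoefficients:
    """Morlet CWT of one window: (n_scales, n_samples) complex matrix."""

    scales: np.ndarray
    coefficients: np.ndarray
    w0: float = MORLET_W0

    def __post_init__(self) -> None:
        s = np.asarray(self.scales, dtype=float)
        if np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("scales must be positive and strictly increasing")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite CWT coefficients")


def morlet(t: np.ndarray, w0: float = MORLET_W0) -> np.ndarray:
    return np.exp(1j * w0 * t) * np.exp(-0.5 * t**2)


# ---------------------------------------------------------------------------
# time-domain features


def td_features(window: np.ndarray, zc_ssc_threshold: float = 0.0) -> dict[str, float]:
    """RMS, MAV, iEMG, WL, ZC, SSC of one window.

    ZC counts sign changes whose flanking amplitudes both exceed the
    threshold; SSC counts interior turning points whose two adjacent slopes
    both exceed it in magnitude.
    """
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    out = {
        "RMS": float(np.sqrt(np.mean(x**2))),
        "MAV": float(np.mean(np.abs(x))),
        "iEMG": float(np.sum(np.abs(x))),
        "WL": float(np.sum(np.abs(np.diff(x)))) if x.size > 1 else 0.0,
    }
    thr = zc_ssc_threshold
    if x.size > 1:
        a, b = x[:-1], x[1:]
        zc = (a * b < 0) & (np.abs(a) >= thr) & (np.abs(b) >= thr)
        out["ZC"] = int(np.count_nonzero(zc))
    else:
        out["ZC"] = 0
    if x.size > 2:
        d1 = x[1:-1] - x[:-2]
        d2 = x[1:-1] - x[2:]
        ssc = (d1 * d2 > 0) & (np.abs(d1) >= thr) & (np.abs(d2) >= thr)
        out["SSC"] = int(np.count_nonzero(ssc))
    else:
        out["SSC"] = 0
    return out


# ---------------------------------------------------------------------------
# continuous wavelet transform


@lru_cache(maxsize=8)
def _kernel_ffts(scales: tuple[float, ...], n_samples: int, w0: float
                 ) -> tuple[np.ndarray, int, int]:
    """Precompute FFTs of the conjugate-reflected Morlet kernels.

    For scale a the correlation C[b] = sum_k x[k] psi*((k-b)/a) / sqrt(a) is a
    convolution with h[m] = psi*(-m/a) / sqrt(a) truncated at |m/a| <=
    KERNEL_HALFWIDTH, where the Gaussian envelope has fallen to
    exp(-18) ~ 1.5e-8 of its peak. Returns (stacked kernel FFTs, fft length,
    max half-width M)."""
    m_max = int(np.ceil(KERNEL_HALFWIDTH * max(scales)))
    n_fft = sfft.next_fast_len(n_samples + 2 * m_max, real=False)
    kf = np.empty((len(scales), n_fft), dtype=complex)
    for i, a in enumerate(scales):
        m = np.arange(-m_max, m_max + 1)
        h = np.conj(morlet(-m / a, w0)) / np.sqrt(a)
        h[np.abs(m) > KERNEL_HALFWIDTH * a] = 0.0
        # place h centered at 0 with wraparound so ifft aligns lags directly
        buf = np.zeros(n_fft, dtype=complex)
        buf[: m_max + 1] = h[m_max:]
        buf[-m_max:] = h[:m_max]
        kf[i] = sfft.fft(buf)
    return kf, n_fft, m_max


def cwt(window: np.ndarray, scales=DEFAULT_SCALES, w0: float = MORLET_W0,
        fs: float | None = None) -> CWTCoefficients:
    """Morlet CWT of one window at the given scale set (scales in samples).

    ``fs`` is accepted for provenance only; the transform itself operates in
    sample units, matching the study's dimensionless scale set.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    scales_t = tuple(float(a) for a in scales)
    if any(a <= 0 for a in scales_t):
        raise ValueError("scales must be positive")
    coeffs = _cwt_batch(x[None, :], scales_t, w0)[:, 0, :]
    return CWTCoefficients(np.asarray(scales_t), coeffs, w0)


def _cwt_batch(windows: np.ndarray, scales: tuple[float, ...],
               w0: float = MORLET_W0) -> np.ndarray:
    """CWT of many equal-length windows at once: (n_scales, n_windows, n)."""
    n = windows.shape[1]
    kf, n_fft, _ = _kernel_ffts(scales, n, w0)
    xf = sfft.fft(windows, n_fft, axis=1)
    prod = kf[:, None, :] * xf[None, :, :]
    full = sfft.ifft(prod, axis=2)
    return full[:, :, :n]


def cwt_power(c: CWTCoefficients) -> float:
    """Mean over scales of the per-scale average |C|^2."""
    return float(np.mean(np.abs(c.coefficients) ** 2))


def per_scale_power(c: CWTCoefficients) -> np.ndarray:
    return np.mean(np.abs(c.coefficients) ** 2, axis=1)


def wavelet_entropy(c: CWTCoefficients) -> float:
    """Shannon entropy (natural log) of the normalized per-scale power."""
    return _entropy_from_power(per_scale_power(c))


def _entropy_from_power(power: np.ndarray) -> float:
    total = power.sum()
    if total <= 0:
        raise ValueError("all-zero power: wavelet entropy undefined")
    h = power / total
    nz = h[h > 0]
    return float(-np.sum(nz * np.log(nz)))


def kurtosis_formula(x: np.ndarray) -> float:
    """Unbiased sample excess kurtosis.

    G2 = [m(m+1)/((m-1)(m-2)(m-3)) * sum(((x - mean)/s)^4)] - 3(m-1)^2/((m-2)(m-3))
    with s the ddof-1 standard deviation. Raises on zero spread.
    """
    x = np.asarray(x, dtype=float)
    m = x.size
    if m < 4:
        raise ValueError("kurtosis needs at least 4 points")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("degenerate input: zero spread (S = 0)")
    z4 = np.sum(((x - x.mean()) / s) ** 4)
    return float(m * (m + 1) / ((m - 1) * (m - 2) * (m - 3)) * z4
                 - 3 * (m - 1) ** 2 / ((m - 2) * (m - 3)))


def _scott_bandwidth(values: np.ndarray) -> float:
    """Scott's rule for a univariate Gaussian kernel: sd * n^(-1/5)."""
    sd = values.std(ddof=1)
    return float(sd * values.size ** (-1 / 5)) if sd > 0 else 0.0


def kde_pdf(values: np.ndarray, m: int = KDE_GRID_POINTS,
            n_bins: int = KDE_BINS) -> np.ndarray:
    """Gaussian-kernel density of ``values`` on ``m`` grid points spanning
    their range, Scott's-rule bandwidth, evaluated through linear binning."""
    v = np.asarray(values, dtype=float)
    if m < 5:
        raise ValueError("need at least 5 grid points")
    bw = _scott_bandwidth(v)
    if bw == 0:
        raise ValueError("degenerate input: zero spread")
    lo, hi = float(v.min()), float(v.max())
    grid = np.linspace(lo, hi, m)
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(v, bins=edges)
    diff = grid[:, None] - centers[None, :]
    kern = np.exp(-0.5 * (diff / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    return kern @ counts / v.size


def cwt_kurtosis(c: CWTCoefficients, m: int = KDE_GRID_POINTS) -> float:
    """Excess kurtosis of the kernel-estimated PDF of pooled |C| values.

    The coefficient moduli over all scales and times are pooled, their
    empirical density is estimated on ``m`` equally spaced points spanning the
    pooled range, and the unbiased excess-kurtosis formula is applied to the
    m density values."""
    pooled = np.abs(c.coefficients).ravel()
    pdf = kde_pdf(pooled, m=m)
    return kurtosis_formula(pdf)


# ---------------------------------------------------------------------------
# pipeline-level extraction and tables


def window_features(windows: np.ndarray, zc_ssc_rel_threshold: float = 0.01,
                    scales=DEFAULT_SCALES) -> pd.DataFrame:
    """All nine features for a (n_windows, window_len) matrix of one channel.

    The ZC/SSC deadband is ``zc_ssc_rel_threshold`` times each window's RMS,
    which keeps both counts invariant to channel gain."""
    scales_t = tuple(float(a) for a in scales)
    coeffs = _cwt_batch(windows, scales_t)          # (n_scales, n_win, n)
    power = np.mean(np.abs(coeffs) ** 2, axis=2)    # (n_scales, n_win)
    rows = []
    for w in range(windows.shape[0]):
        x = windows[w]
        rms = float(np.sqrt(np.mean(x**2)))
        feats = td_features(x, zc_ssc_threshold=zc_ssc_rel_threshold * rms)
        feats["CWT_power"] = float(power[:, w].mean())
        feats["WE"] = _entropy_from_power(power[:, w])
        feats["CWT_kurtosis"] = kurtosis_formula(
            kde_pdf(np.abs(coeffs[:, w, :]).ravel()))
        feats["window"] = w
        rows.append(feats)
    return pd.DataFrame(rows)


def mvc_normalize(table: pd.DataFrame, mvc_table: pd.DataFrame) -> pd.DataFrame:
    """Divide each raw feature value by the subject/channel-specific mean over
    the MVC trials of the same feature.

    Both tables are long-form with columns (subject, channel, trial, feature,
    raw). Returns ``table`` with a ``normalized`` column added."""
    trial_means = (mvc_table.groupby(["subject", "channel", "feature", "trial"])
                   ["raw"].mean().reset_index())
    ref = (trial_means.groupby(["subject", "channel", "feature"])["raw"]
           .mean().rename("mvc_ref").reset_index())
    merged = table.merge(ref, on=["subject", "channel", "feature"], how="left")
    missing = merged["mvc_ref"].isna() | (merged["mvc_ref"] == 0)
    if missing.any():
        row = merged.loc[missing].iloc[0]
        raise ValueError(
            "missing or zero MVC reference for subject "
            f"{row['subject']}, channel {row['channel']}, feature {row['feature']}")
    merged["normalized"] = merged["raw"] / merged["mvc_ref"]
    return merged.drop(columns="mvc_ref")


def aggregate(table: pd.DataFrame, channel_set=None, mode: str = "stats",
              value_col: str = "normalized") -> pd.DataFrame:
    """Collapse a window-level table to one record per (subject, level, feature).

    ``stats`` mode averages over all windows, trials, and channels in
    ``channel_set`` jointly (the study's statistical-analysis averaging);
    ``classify`` mode first averages within each channel, then across the
    channel set, matching the classifier-input construction."""
    if mode not in ("stats", "classify"):
        raise ValueError("mode must be 'stats' or 'classify'")
    if channel_set is not None:
        channel_set = list(channel_set)
        if not channel_set:
            raise ValueError("empty channel_set")
        table = table[table["channel"].isin(channel_set)]
        if table.empty:
            raise ValueError("channel_set matches no rows")
    keys = ["subject", "level", "feature"]
    extra = [c for c in ("group", "sex") if c in table.columns]
    if mode == "stats":
        agg = table.groupby(keys + extra, observed=True)[value_col].mean()
    else:
        per_channel = table.groupby(keys + extra + ["channel"], observed=True)[
            value_col].mean()
        agg = per_channel.groupby(keys + extra, observed=True).mean()
    return agg.rename("value").reset_index()
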