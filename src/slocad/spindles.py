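"""Sleep spindle detection with per-epoch median + MAD power thresholds.

A single channel (Cz by convention) is band-passed to 10-16 Hz, squared,
and smoothed with a 100 ms sliding window to give a power time series.
Within every 30-s epoch two thresholds are set from the epoch's power
distribution: high = median + 4 MAD and low = median + 2 MAD (MAD taken
raw, without the normal-consistency factor).  Candidates are runs of
power strictly above the high threshold, extended outward to the low-
threshold crossings, merged when they share a span, and kept when they
last 0.3-3 s.  A specificity filter retains only events whose mean periodogram power per
frequency bin in 10-16 Hz exceeds three times that in the flanking 8-10
and 16-18 Hz bands; a flat (broadband) spectrum scores about 1 and is
rejected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator

from .io import SPINDLE_COLUMNS, EegRecording

SIGMA_BAND = (10.0, 16.0)
FLANK_LOW = (8.0, 10.0)
FLANK_HIGH = (16.0, 18.0)


def sigma_filter(x: np.ndarray, sfreq: float,
                 band: tuple[float, float] = SIGMA_BAND) -> np.ndarray:
    """Zero-phase FIR band-pass (Hamming window) of a single-channel series."""
    if sfreq <= 2 * band[1]:
        raise ValueError(f"sampling rate {sfreq} Hz too low for a "
                         f"{band[1]} Hz band edge")
    x = np.asarray(x, dtype=float)
    numtaps = int(round(sfreq)) // 2 * 2 + 1  # ~1 s of taps, odd
    numtaps = min(numtaps, max(3, (len(x) - 1) // 3 // 2 * 2 + 1))
    b = signal.firwin(numtaps, band, pass_zero=False, fs=sfreq,
                      window="hamming")
    return signal.filtfilt(b, 1.0, x)


def power_timeseries(x_filtered: np.ndarray, sfreq: float,
                     window: float = 0.1) -> np.ndarray:
    """Pointwise square followed by a centered moving average (uV^2)."""
    w = max(1, int(round(window * sfreq)))
    return uniform_filter1d(np.asarray(x_filtered, dtype=float) ** 2,
                            size=w, mode="nearest")


def epoch_thresholds(power: np.ndarray, sfreq: float,
                     epoch_length: float = 30.0,
                     high_mult: float = 4.0,
                     low_mult: float = 2.0) -> pd.DataFrame:
    """Per-epoch (high, low) detection thresholds from median + k*MAD."""
    power = np.asarray(power, dtype=float)
    if np.any(power < 0):
        raise ValueError("power must be non-negative")
    n_per = int(round(epoch_length * sfreq))
    n_epochs = int(np.ceil(len(power) / n_per))
    rows = []
    for e in range(n_epochs):
        seg = power[e * n_per:(e + 1) * n_per]
        if len(seg) < 2:
            raise ValueError(f"epoch {e} has fewer than 2 samples")
        med = float(np.median(seg))
        mad = float(np.median(np.abs(seg - med)))
        rows.append({"epoch": e, "high": med + high_mult * mad,
                     "low": med + low_mult * mad})
    return pd.DataFrame(rows).set_index("epoch")


def band_power_ratio(segment: np.ndarray, sfreq: float,
                     min_length: float = 0.5) -> float:
    """Mean periodogram power per bin in 10-16 Hz over the pooled flanking
    8-10 and 16-18 Hz bands; short segments are zero-padded to 0.5 s."""
    seg = np.asarray(segment, dtype=float)
    n_min = int(round(min_length * sfreq))
    if len(seg) < n_min:
        seg = np.pad(seg, (0, n_min - len(seg)))
    f, pxx = signal.periodogram(seg, fs=sfreq, window="boxcar")
    sigma = (f >= SIGMA_BAND[0]) & (f <= SIGMA_BAND[1])
    flank = (((f >= FLANK_LOW[0]) & (f < FLANK_LOW[1]))
             | ((f > FLANK_HIGH[0]) & (f <= FLANK_HIGH[1])))
    in_band = pxx[sigma].mean()
    flank_power = pxx[flank].mean()
    if flank_power == 0:
        return np.inf if in_band > 0 else 0.0
    return float(in_band / flank_power)


def detect_spindles(rec: EegRecording, channel: str | int = "Cz",
                    band: tuple[float, float] = SIGMA_BAND,
                    smooth_window: float = 0.1,
                    epoch_length: float = 30.0,
                    high_mult: float = 4.0, low_mult: float = 2.0,
                    min_duration: float = 0.3, max_duration: float = 3.0,
                    ratio_threshold: float = 3.0) -> pd.DataFrame:
    """Detect spindles on one channel; returns an onset-sorted event table.

    Boundary extension uses the low threshold of the epoch containing the
    high-threshold exceedance onset and may cross epoch boundaries.
    """
    if isinstance(channel, str):
        if channel not in rec.ch_names:
            raise ValueError(f"channel {channel!r} not in recording "
                             f"({rec.ch_names})")
        ch = rec.ch_names.index(channel)
        ch_name = channel
    else:
        ch = int(channel)
        if not 0 <= ch < rec.n_channels:
            raise ValueError(f"channel index {ch} out of range")
        ch_name = rec.ch_names[ch]

    x = rec.data[ch]
    xf = sigma_filter(x, rec.sfreq, band=band)
    power = power_timeseries(xf, rec.sfreq, window=smooth_window)
    thr = epoch_thresholds(power, rec.sfreq, epoch_length=epoch_length,
                           high_mult=high_mult, low_mult=low_mult)
    n_per = int(round(epoch_length * rec.sfreq))
    high_per_sample = thr["high"].to_numpy()[
        np.minimum(np.arange(len(power)) // n_per, len(thr) - 1)]

    above = power > high_per_sample  # strict exceedance
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[above[edges + 1]] + 1)
    if above[0]:
        starts.insert(0, 0)

    spans: list[tuple[int, int]] = []  # [start, stop) above the low threshold
    for i0 in starts:
        low = float(thr["low"].iloc[min(i0 // n_per, len(thr) - 1)])
        a = i0
        while a > 0 and power[a - 1] > low:
            a -= 1
        b = i0
        while b < len(power) - 1 and power[b + 1] > low:
            b += 1
        spans.append((a, b + 1))
    # merge candidates sharing (or overlapping) a low-threshold span
    spans.sort()
    merged: list[list[int]] = []
    for a, b in spans:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    rows = []
    for a, b in merged:
        onset = a / rec.sfreq
        duration = (b - a) / rec.sfreq
        if not (min_duration <= duration <= max_duration):
            continue
        ratio = band_power_ratio(x[a:b], rec.sfreq)
        if ratio <= ratio_threshold:
            continue
        k = a + int(np.argmax(power[a:b]))
        rows.append({"onset": onset, "duration": duration,
                     "peak_power_time": k / rec.sfreq,
                     "peak_power": float(power[k]),
                     "power_ratio": ratio, "channel": ch_name})
    table = pd.DataFrame(rows, columns=SPINDLE_COLUMNS)
    return table.sort_values("onset", ignore_index=True)


class SpindleDetector(BaseEstimator):
    """Estimator-style spindle detector (see :func:`detect_spindles`)."""

    def __init__(self, channel: str | int = "Cz",
                 band: tuple[float, float] = SIGMA_BAND,
                 smooth_window: float = 0.1, epoch_length: float = 30.0,
                 high_mult: float = 4.0, low_mult: float = 2.0,
                 min_duration: float = 0.3, max_duration: float = 3.0,
                 ratio_threshold: float = 3.0):
        self.channel = channel
        self.band = band
        self.smooth_window = smooth_window
        self.epoch_length = epoch_length
        self.high_mult = high_mult
        self.low_mult = low_mult
        self.min_duration = min_duration
        self.max_duration = max_duration
        self.ratio_threshold = ratio_threshold

    def fit(self, rec: EegRecording, y=None):
        self.events_ = self.transform(rec)
        return self

    def transform(self, rec: EegRecording) -> pd.DataFrame:
        return detect_spindles(
            rec, channel=self.channel, band=self.band,
            smooth_window=self.smooth_window, epoch_length=self.epoch_length,
            high_mult=self.high_mult, low_mult=self.low_mult,
            min_duration=self.min_duration, max_duration=self.max_duration,
            ratio_threshold=self.ratio_threshold)
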