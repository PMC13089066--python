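"""Slow wave event (SWE) detection on the multichannel negative envelope.

The detection reference signal is the negative envelope: at each sample the
four most negative channel values are selected, the single most negative is
discarded, and the remaining three are averaged; the resulting series is
zero-mean centered over the recording.  Negative half-waves of the envelope
(between a positive-to-negative zero crossing and the next negative-to-
positive crossing) lasting 0.25-1 s with a trough at or below -5 uV are
classified as SWEs.

Each event carries four features:

* negative slope — |trough amplitude| / (trough time - onset), uV/s
* positive slope — |trough amplitude| / (offset - trough time), uV/s
* relative scalp involvement — percentage of channels whose 0.5-4 Hz
  signal averages below -5 uV within a 40 ms window centered on the trough
* synchronization score (SyncS) —
  ``involvement x (positive slope + negative slope) / 2 x 1/1000``,
  indexing how widely and steeply the wave recruits the scalp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator

from .io import SWE_COLUMNS, EegRecording, Hypnogram


@dataclass
class EnvelopeSeries:
    """Zero-mean centered negative-envelope series."""

    values: np.ndarray
    sfreq: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if abs(self.values.mean()) > 1e-6:
            raise ValueError("envelope must be zero-mean centered")


class HalfWave(NamedTuple):
    onset: float
    neg_peak_time: float
    offset: float
    neg_peak_amp: float


def bandpass_slow(rec: EegRecording, low: float = 0.5, high: float = 4.0,
                  order: int = 4) -> EegRecording:
    """Zero-phase Butterworth band-pass of every channel (default 0.5-4 Hz)."""
    if rec.sfreq <= 2 * high:
        raise ValueError(f"sampling rate {rec.sfreq} Hz too low for a "
                         f"{high} Hz band edge")
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=rec.sfreq, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return EegRecording(data=filtered, sfreq=rec.sfreq,
                        ch_names=list(rec.ch_names))


def negative_envelope(rec_filtered: EegRecording) -> EnvelopeSeries:
    """Drop the single most negative channel value per sample, average the
    next three most negative, then center the series to zero mean."""
    if rec_filtered.n_channels < 4:
        raise ValueError("negative envelope requires at least 4 channels")
    ordered = np.sort(rec_filtered.data, axis=0)  # ascending: most negative first
    env = ordered[1:4].mean(axis=0)
    return EnvelopeSeries(values=env - env.mean(), sfreq=rec_filtered.sfreq)


def detect_half_waves(env: EnvelopeSeries, min_dur: float = 0.25,
                      max_dur: float = 1.0,
                      amp_thresh: float = -5.0) -> list[HalfWave]:
    """Negative half-waves of the centered envelope meeting the duration
    and amplitude criteria (bounds inclusive).

    Onset/offset are the samples at the flanking zero crossings on the
    sample grid (onset = last non-negative sample before the negative run).
    Runs touching the recording edge lack a flanking crossing and are
    discarded.
    """
    x = env.values
    sf = env.sfreq
    neg = x < 0
    # run boundaries of the negative-sample mask
    edges = np.flatnonzero(np.diff(neg.astype(np.int8)))
    starts = edges[neg[edges + 1]] + 1
    stops = edges[~neg[edges + 1]] + 1  # exclusive stop of a negative run
    events: list[HalfWave] = []
    for i0 in starts:
        j = stops[stops > i0]
        if len(j) == 0:
            continue  # run reaches the end of the recording
        i1 = j[0]  # first non-negative sample after the run
        onset = (i0 - 1) / sf
        offset = i1 / sf
        dur = offset - onset
        if not (min_dur <= dur <= max_dur):
            continue
        seg = x[i0:i1]
        k = int(np.argmin(seg))
        if seg[k] > amp_thresh:
            continue
        events.append(HalfWave(onset=onset, neg_peak_time=(i0 + k) / sf,
                               offset=offset, neg_peak_amp=float(seg[k])))
    return events


def compute_slopes(onset: float, neg_peak_time: float, offset: float,
                   neg_peak_amp: float) -> tuple[float, float]:
    """Slope magnitudes (uV/s) of the descending and ascending limbs."""
    if not onset < neg_peak_time < offset:
        raise ValueError("zero-length half-wave limb")
    neg_slope = abs(neg_peak_amp) / (neg_peak_time - onset)
    pos_slope = abs(neg_peak_amp) / (offset - neg_peak_time)
    return neg_slope, pos_slope


def compute_involvement(neg_peak_time: float, rec_filtered: EegRecording,
                        window: float = 0.040,
                        thresh: float = -5.0) -> float:
    """Percent of channels whose band-passed signal averages below
    ``thresh`` within a ``window``-long interval centered on the trough."""
    sf = rec_filtered.sfreq
    i0 = int(round((neg_peak_time - window / 2) * sf))
    i1 = int(round((neg_peak_time + window / 2) * sf)) + 1
    if i0 < 0 or i1 > rec_filtered.n_samples:
        warnings.warn("involvement window truncated at the recording edge",
                      stacklevel=2)
        i0, i1 = max(i0, 0), min(i1, rec_filtered.n_samples)
    means = rec_filtered.data[:, i0:i1].mean(axis=1)
    return 100.0 * float(np.mean(means < thresh))


def synchronization_score(involvement: float, neg_slope: float,
                          pos_slope: float) -> float:
    """SyncS = involvement x mean(|slopes|) / 1000 (dimensionless)."""
    if min(involvement, neg_slope, pos_slope) < 0:
        raise ValueError("involvement and slopes must be non-negative")
    return involvement * (pos_slope + neg_slope) / 2.0 / 1000.0


def detect_swes(rec: EegRecording, hypnogram: Hypnogram | None = None,
                low: float = 0.5, high: float = 4.0,
                min_duration: float = 0.25, max_duration: float = 1.0,
                amp_threshold: float = -5.0,
                involvement_window: float = 0.040,
                involvement_threshold: float = -5.0) -> pd.DataFrame:
    """Full SWE detection: band-pass, negative envelope, half-wave
    classification, and per-event feature extraction.

    Returns an onset-sorted event table (columns per :data:`io.SWE_COLUMNS`);
    ``stage`` is the hypnogram epoch containing the trough when a hypnogram
    is supplied, otherwise missing.
    """
    filtered = bandpass_slow(rec, low=low, high=high)
    env = negative_envelope(filtered)
    half_waves = detect_half_waves(env, min_dur=min_duration,
                                   max_dur=max_duration,
                                   amp_thresh=amp_threshold)
    rows = []
    for hw in half_waves:
        neg_slope, pos_slope = compute_slopes(hw.onset, hw.neg_peak_time,
                                              hw.offset, hw.neg_peak_amp)
        involvement = compute_involvement(hw.neg_peak_time, filtered,
                                          window=involvement_window,
                                          thresh=involvement_threshold)
        rows.append({
            "onset": hw.onset,
            "duration": hw.offset - hw.onset,
            "neg_peak_time": hw.neg_peak_time,
            "neg_peak_amp": hw.neg_peak_amp,
            "neg_slope": neg_slope,
            "pos_slope": pos_slope,
            "involvement": involvement,
            "sync_score": synchronization_score(involvement, neg_slope,
                                                pos_slope),
            "stage": (hypnogram.stage_at(hw.neg_peak_time)
                      if hypnogram is not None else None),
        })
    table = pd.DataFrame(rows, columns=SWE_COLUMNS)
    return table.sort_values("onset", ignore_index=True)


class SweDetector(BaseEstimator):
    """Estimator-style slow wave detector.

    ``fit`` runs detection on a recording and stores the event table in
    ``events_`` (with the centered envelope in ``envelope_``); ``transform``
    applies the same parameters to a new recording and returns its events.
    """

    def __init__(self, low: float = 0.5, high: float = 4.0,
                 min_duration: float = 0.25, max_duration: float = 1.0,
                 amp_threshold: float = -5.0,
                 involvement_window: float = 0.040,
                 involvement_threshold: float = -5.0):
        self.low = low
        self.high = high
        self.min_duration = min_duration
        self.max_duration = max_duration
        self.amp_threshold = amp_threshold
        self.involvement_window = involvement_window
        self.involvement_threshold = involvement_threshold

    def fit(self, rec: EegRecording, hypnogram: Hypnogram | None = None):
        self.envelope_ = negative_envelope(
            bandpass_slow(rec, low=self.low, high=self.high))
        self.events_ = self.transform(rec, hypnogram)
        return self

    def transform(self, rec: EegRecording,
                  hypnogram: Hypnogram | None = None) -> pd.DataFrame:
        return detect_swes(
            rec, hypnogram=hypnogram, low=self.low, high=self.high,
            min_duration=self.min_duration, max_duration=self.max_duration,
            amp_threshold=self.amp_threshold,
            involvement_window=self.involvement_window,
            involvement_threshold=self.involvement_threshold)
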