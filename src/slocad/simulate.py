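"""Synthetic EEG, hypnogram, BOLD, confound and atlas generators.

Every generator is seeded and deterministic, and returns the ground truth
alongside the data, so detector sensitivity, GLM coefficient recovery and
end-to-end deviation metrics can be scored against known answers without
any external recordings.

What is emulated
----------------
* EEG: per-channel 1/f ("pink") background noise; slow wave events as
  negative half-period sinusoid deflections (0.5-4 Hz morphology) added to
  an involved-channel subset; spindles as Gaussian-windowed 10-16 Hz
  bursts.
* Hypnograms: contiguous stage blocks rendered on the 30-s epoch grid.
* BOLD: baseline + polynomial drift + beta x HRF-convolved event response
  in active ROIs (optionally a parametric-modulation response) + leakage
  of motion/CSF confound signals + white Gaussian noise.
* Confounds: motion as slow random walks, CSF voxel series as mixtures of
  low-frequency sinusoids.
* Atlas: a seeded Voronoi partition of the grid into contiguous labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import HrfSpec, build_event_regressor, build_parametric_modulator
from .io import SLEEP_STAGES, BoldRun, EegRecording, Hypnogram


@dataclass(frozen=True)
class SweTruth:
    """One implanted slow wave: negative half-sine of ``duration`` seconds
    with trough ``peak_amp`` (< 0 uV) at the event midpoint, added to
    ``channels`` (None = all channels)."""

    onset: float
    duration: float
    peak_amp: float
    channels: tuple[int, ...] | None = None


@dataclass(frozen=True)
class SpindleTruth:
    """One implanted spindle: Gaussian-windowed sinusoid burst."""

    onset: float
    duration: float
    freq: float
    amp: float
    channels: tuple[int, ...] | None = None


@dataclass
class EegSimConfig:
    n_channels: int
    duration: float
    sfreq: float = 200.0
    swe_truth: list[SweTruth] = field(default_factory=list)
    spindle_truth: list[SpindleTruth] = field(default_factory=list)
    noise_sd: float = 1.0
    noise_color: str = "pink"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.duration <= 0 or self.sfreq <= 0:
            raise ValueError("duration and sfreq must be positive")
        for ev in self.swe_truth:
            if not (0 <= ev.onset and ev.onset + ev.duration <= self.duration):
                raise ValueError(f"SWE truth event at {ev.onset}s outside run")
            if ev.peak_amp >= 0:
                raise ValueError("SWE peak amplitudes must be negative")
            self._check_channels(ev.channels)
        for ev in self.spindle_truth:
            if not (0 <= ev.onset and ev.onset + ev.duration <= self.duration):
                raise ValueError(f"spindle truth event at {ev.onset}s outside run")
            if not 10.0 <= ev.freq <= 16.0:
                raise ValueError("spindle frequency must lie in 10-16 Hz")
            self._check_channels(ev.channels)

    def _check_channels(self, channels: tuple[int, ...] | None) -> None:
        if channels is not None and not set(channels) <= set(range(self.n_channels)):
            raise ValueError("involved-channel set outside channel indices")


@dataclass(frozen=True)
class Roi:
    """Active region: boolean voxel mask, response amplitude, condition name."""

    mask: np.ndarray
    beta: float
    condition: str = "swe"


@dataclass
class BoldSimConfig:
    grid_shape: tuple[int, int, int]
    n_volumes: int
    tr: float = 2.0
    active_rois: list[Roi] = field(default_factory=list)
    modulator_slope: float = 0.0
    noise_sd: float = 1.0
    baseline: float = 100.0
    drift_order: int = 1
    drift_scale: float = 0.5
    confound_leak: dict[str, float] = field(default_factory=dict)
    n_csf_voxels: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be a nonempty 3-D shape")
        if self.n_volumes < 20:
            raise ValueError("n_volumes must be >= 20")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        for roi in self.active_rois:
            if roi.mask.shape != tuple(self.grid_shape):
                raise ValueError("ROI mask does not match the grid")


@dataclass
class GroundTruth:
    """Known truth accompanying a simulated dataset."""

    swe_events: pd.DataFrame | None = None
    spindle_events: pd.DataFrame | None = None
    beta: dict[str, np.ndarray] | None = None
    modulator_slope: np.ndarray | None = None
    motion: pd.DataFrame | None = None
    csf: np.ndarray | None = None


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-SD 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spectrum * scale, n)
    return shaped / shaped.std()


def _warn_on_overlaps(cfg: EegSimConfig) -> None:
    spans: dict[int, list[tuple[float, float]]] = {}
    events = [(ev.onset, ev.duration, ev.channels)
              for ev in cfg.swe_truth + cfg.spindle_truth]
    for onset, dur, channels in events:
        chans = channels if channels is not None else tuple(range(cfg.n_channels))
        for ch in chans:
            for a, b in spans.setdefault(ch, []):
                if onset < b and a < onset + dur:
                    warnings.warn(
                        "overlapping truth events on one channel; summing "
                        "linearly", stacklevel=3)
                    return
            spans[ch].append((onset, onset + dur))


def generate_eeg(cfg: EegSimConfig) -> tuple[EegRecording, GroundTruth]:
    """Simulate a multichannel recording and return it with its truth tables."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.sfreq))
    data = np.zeros((cfg.n_channels, n))
    if cfg.noise_sd > 0:
        for ch in range(cfg.n_channels):
            base = (_pink_noise(rng, n) if cfg.noise_color == "pink"
                    else rng.standard_normal(n))
            data[ch] = cfg.noise_sd * base
    _warn_on_overlaps(cfg)
    t = np.arange(n) / cfg.sfreq

    for ev in cfg.swe_truth:
        sel = (t >= ev.onset) & (t <= ev.onset + ev.duration)
        # negative half-period sinusoid, trough at the event midpoint
        wave = ev.peak_amp * np.sin(np.pi * (t[sel] - ev.onset) / ev.duration)
        chans = ev.channels if ev.channels is not None else range(cfg.n_channels)
        for ch in chans:
            data[ch, sel] += wave

    for ev in cfg.spindle_truth:
        sel = (t >= ev.onset) & (t <= ev.onset + ev.duration)
        center = ev.onset + ev.duration / 2
        window = np.exp(-0.5 * ((t[sel] - center) / (ev.duration / 6)) ** 2)
        burst = ev.amp * window * np.sin(2 * np.pi * ev.freq * (t[sel] - ev.onset))
        chans = ev.channels if ev.channels is not None else range(cfg.n_channels)
        for ch in chans:
            data[ch, sel] += burst

    swe_tab = pd.DataFrame(
        [{"onset": ev.onset, "duration": ev.duration,
          "neg_peak_time": ev.onset + ev.duration / 2,
          "neg_peak_amp": ev.peak_amp,
          "n_channels": (len(ev.channels) if ev.channels is not None
                         else cfg.n_channels)}
         for ev in cfg.swe_truth]).sort_values("onset", ignore_index=True) \
        if cfg.swe_truth else pd.DataFrame(
            columns=["onset", "duration", "neg_peak_time", "neg_peak_amp",
                     "n_channels"])
    spin_tab = pd.DataFrame(
        [{"onset": ev.onset, "duration": ev.duration, "freq": ev.freq,
          "amp": ev.amp,
          "peak_time": ev.onset + ev.duration / 2}
         for ev in cfg.spindle_truth]).sort_values("onset", ignore_index=True) \
        if cfg.spindle_truth else pd.DataFrame(
            columns=["onset", "duration", "freq", "amp", "peak_time"])

    rec = EegRecording(data=data, sfreq=cfg.sfreq)
    return rec, GroundTruth(swe_events=swe_tab, spindle_events=spin_tab)


def generate_hypnogram(duration: float,
                       block_pattern: list[tuple[str, float]],
                       epoch_length: float = 30.0) -> Hypnogram:
    """Render contiguous (stage, length-seconds) blocks onto the epoch grid.

    Each epoch takes the stage of the block containing its start time; the
    blocks must cover the full duration.
    """
    for stage, length in block_pattern:
        if stage not in SLEEP_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if length <= 0:
            raise ValueError("block lengths must be positive")
    total = sum(length for _, length in block_pattern)
    if total < duration - 1e-9:
        raise ValueError(f"blocks cover {total}s but duration is {duration}s")
    edges = np.cumsum([length for _, length in block_pattern])
    n_epochs = int(np.ceil(duration / epoch_length))
    stages = []
    for i in range(n_epochs):
        start = i * epoch_length
        block = int(np.searchsorted(edges, start, side="right"))
        stages.append(block_pattern[block][0])
    return Hypnogram(stages=stages, epoch_length=epoch_length)


def generate_confounds(n_frames: int, n_csf_voxels: int = 20,
                       tr: float = 2.0, seed: int = 0
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """Motion as slow random walks (frames x 6) and CSF voxel series as
    low-frequency sinusoid mixtures plus noise (frames x voxels)."""
    rng = np.random.default_rng(seed)
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(n_frames, 6)), axis=0)
    from .design import MOTION_BASE  # local to avoid a circular surface
    motion_df = pd.DataFrame(motion, columns=[f"{n}" for n in MOTION_BASE])

    t = np.arange(n_frames) * tr
    n_waves = 3
    periods = rng.uniform(30.0, 120.0, size=n_waves)
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    shared = sum(np.sin(2 * np.pi * t / p + ph) for p, ph in zip(periods, phases))
    weights = rng.uniform(0.5, 1.5, size=n_csf_voxels)
    csf = shared[:, None] * weights[None, :]
    csf = csf + rng.normal(0.0, 0.2, size=csf.shape)
    return motion_df, csf


def generate_bold(cfg: BoldSimConfig, events: pd.DataFrame,
                  modulators: np.ndarray | None = None,
                  hrf: HrfSpec | None = None
                  ) -> tuple[BoldRun, GroundTruth]:
    """Simulate a 4-D BOLD run with known voxelwise response amplitudes.

    Active ROI voxels carry ``beta x`` the HRF-convolved event boxcar plus,
    when ``modulators`` is given, ``modulator_slope x`` the convolved
    mean-centered modulator sticks.  All voxels share polynomial drift,
    confound leakage and white noise.
    """
    rng = np.random.default_rng(cfg.seed)
    run = BoldRun(data=np.zeros(cfg.grid_shape + (cfg.n_volumes,)), tr=cfg.tr)
    frame_times = run.frame_times
    run_end = cfg.n_volumes * cfg.tr
    if len(events) and np.any(np.asarray(events["onset"]) +
                              np.asarray(events["duration"]) > run_end):
        raise ValueError("events extend beyond the run")

    x_event = build_event_regressor(events, frame_times, hrf)
    x_mod = (build_parametric_modulator(events, modulators, frame_times, hrf)
             if modulators is not None else None)

    data = np.full(cfg.grid_shape + (cfg.n_volumes,), float(cfg.baseline))
    # per-voxel polynomial drift (Legendre basis over the run)
    if cfg.drift_order > 0:
        x01 = np.linspace(-1, 1, cfg.n_volumes)
        basis = np.polynomial.legendre.legvander(x01, cfg.drift_order)[:, 1:]
        coeffs = rng.normal(0.0, cfg.drift_scale,
                            size=cfg.grid_shape + (cfg.drift_order,))
        data += coeffs @ basis.T

    motion_df, csf = generate_confounds(cfg.n_volumes, cfg.n_csf_voxels,
                                        cfg.tr, seed=cfg.seed + 1)
    leak_m = cfg.confound_leak.get("motion", 0.0)
    leak_c = cfg.confound_leak.get("csf", 0.0)
    if leak_m or leak_c:
        def _std(v):
            s = v.std()
            return (v - v.mean()) / (s if s > 0 else 1.0)
        leak = (leak_m * _std(motion_df.to_numpy().mean(axis=1))
                + leak_c * _std(csf.mean(axis=1)))
        w = rng.normal(0.0, 1.0, size=cfg.grid_shape)
        data += w[..., None] * leak[None, None, None, :]

    beta_vols: dict[str, np.ndarray] = {}
    slope_vol = np.zeros(cfg.grid_shape)
    for roi in cfg.active_rois:
        vol = beta_vols.setdefault(roi.condition, np.zeros(cfg.grid_shape))
        vol[roi.mask] += roi.beta
        data[roi.mask] += roi.beta * x_event
        if x_mod is not None and cfg.modulator_slope:
            slope_vol[roi.mask] += cfg.modulator_slope
            data[roi.mask] += cfg.modulator_slope * x_mod

    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)

    run.data = data
    truth = GroundTruth(beta=beta_vols, modulator_slope=slope_vol,
                        motion=motion_df, csf=csf)
    return run, truth


def generate_atlas(grid_shape: tuple[int, int, int], n_labels: int,
                   seed: int = 0) -> np.ndarray:
    """Seeded Voronoi partition of the grid into ``n_labels`` contiguous
    integer-labeled regions (labels 1..n; every voxel is assigned)."""
    if n_labels < 1:
        raise ValueError("n_labels must be >= 1")
    n_voxels = int(np.prod(grid_shape))
    if n_labels > n_voxels:
        raise ValueError("more labels than voxels")
    rng = np.random.default_rng(seed)
    centroid_idx = rng.choice(n_voxels, size=n_labels, replace=False)
    centroids = np.column_stack(np.unravel_index(centroid_idx, grid_shape))
    coords = np.indices(grid_shape).reshape(3, -1).T
    d2 = ((coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1) + 1
    return labels.reshape(grid_shape).astype(np.int32)
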