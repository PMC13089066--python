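"""Core data containers and file formats.

EEG is carried as a channels x samples matrix in microvolts, sleep staging
as a 30-s-epoch hypnogram, and volumetric data as numpy arrays paired with
a NIfTI affine.  On disk, EEG fixtures are flat little-endian float32
binaries with a JSON sidecar; event tables are tab-separated (BIDS-events
dialect: ``onset``, ``duration``, ``trial_type``, plus feature columns);
volumes are NIfTI-1 via nibabel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

SLEEP_STAGES = ("W", "N1", "N2", "N3", "REM")

#: column order of the slow-wave event table written/consumed by the pipeline
SWE_COLUMNS = [
    "onset", "duration", "neg_peak_time", "neg_peak_amp",
    "neg_slope", "pos_slope", "involvement", "sync_score", "stage",
]

#: column order of the spindle event table
SPINDLE_COLUMNS = [
    "onset", "duration", "peak_power_time", "peak_power", "power_ratio", "channel",
]


@dataclass
class EegRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    sfreq: float
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if np.isnan(self.data).any():
            raise ValueError("EEG data contains NaNs")
        if not self.ch_names:
            self.ch_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq


@dataclass
class Hypnogram:
    """Sleep-stage labels on a fixed epoch grid (30 s by convention)."""

    stages: list[str]
    epoch_length: float = 30.0

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(SLEEP_STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages: {sorted(bad)}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def stage_at(self, t: float) -> str | None:
        """Stage of the epoch containing time ``t`` (seconds), or None outside."""
        idx = int(t // self.epoch_length)
        if t < 0 or idx >= len(self.stages):
            return None
        return self.stages[idx]


@dataclass
class BoldRun:
    """4-D BOLD data: ``data`` is (x, y, z, frames); frame times reference
    the frame midpoint."""

    data: np.ndarray
    tr: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, frames)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def frame_times(self) -> np.ndarray:
        # frame timestamp at the acquisition midpoint
        return (np.arange(self.n_frames) + 0.5) * self.tr


# ---------------------------------------------------------------------------
# EEG fixture format: flat float32 binary + JSON sidecar
# ---------------------------------------------------------------------------

def write_eeg_fixture(rec: EegRecording, path: str | Path) -> None:
    """Write ``<path>.dat`` (float32, channel-major) and ``<path>.json``."""
    path = Path(path)
    rec.data.astype("<f4").tofile(path.with_suffix(".dat"))
    meta = {
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "sfreq": rec.sfreq,
        "ch_names": rec.ch_names,
        "units": "uV",
        "dtype": "<f4",
        "order": "channel-major",
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_eeg_fixture(path: str | Path) -> EegRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path.with_suffix(".dat"), dtype=meta["dtype"])
    data = data.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return EegRecording(data=data, sfreq=meta["sfreq"], ch_names=meta["ch_names"])


def read_edf(path: str | Path) -> EegRecording:
    """Read an EDF recording via MNE (optional dependency), scaled to uV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EegRecording(
        data=raw.get_data() * 1e6, sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
    )


# ---------------------------------------------------------------------------
# Event tables and hypnograms
# ---------------------------------------------------------------------------

def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("\n".join(hyp.stages) + "\n")


def read_hypnogram(path: str | Path, epoch_length: float = 30.0) -> Hypnogram:
    stages = [s for s in Path(path).read_text().split() if s]
    return Hypnogram(stages=stages, epoch_length=epoch_length)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def save_volume(data: np.ndarray, path: str | Path,
                affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_bold(run: BoldRun, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(run.data.astype(np.float32), run.affine), str(path))


def load_bold(path: str | Path, tr: float) -> BoldRun:
    img = nib.load(str(path))
    return BoldRun(data=np.asarray(img.get_fdata()), tr=tr, affine=img.affine)


def check_same_geometry(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"volume geometry mismatch: {sorted(shapes)}")
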