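import numpy as np
import pytest

from slocad.io import EegRecording
from slocad.simulate import EegSimConfig, SweTruth, generate_eeg


def make_envelope(values, sfreq=200.0):
    """Wrap a raw series as a centered EnvelopeSeries by padding with a
    compensating positive constant so the mean is exactly zero."""
    from slocad.swe import EnvelopeSeries

    values = np.asarray(values, dtype=float)
    n_pad = len(values)
    pad_value = -values.sum() / (2 * n_pad)
    assert pad_value >= 0, "helper expects a net-negative series"
    padded = np.concatenate([np.full(n_pad, pad_value), values,
                             np.full(n_pad, pad_value)])
    return EnvelopeSeries(values=padded, sfreq=sfreq), n_pad / sfreq


@pytest.fixture
def implanted_swe_recording():
    """20 slow waves (-40 uV, 0.6 s, all channels) on pink noise (SD 2)."""
    truth = [SweTruth(onset=5.0 + 10.0 * i, duration=0.6, peak_amp=-40.0)
             for i in range(20)]
    cfg = EegSimConfig(n_channels=8, duration=220.0, swe_truth=truth,
                       noise_sd=2.0, seed=7)
    rec, gt = generate_eeg(cfg)
    return rec, gt


@pytest.fixture
def constant_recording():
    data = np.tile(np.linspace(-1.0, 1.0, 400), (6, 1))
    return EegRecording(data=data, sfreq=200.0)
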