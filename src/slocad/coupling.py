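"""Slow wave - spindle coupling classification.

An SWE counts as spindle-coupled when any spindle power peak falls within
a centered time window (4 s by default, i.e. +/- 2 s, boundary inclusive)
around the SWE's negative peak.  One spindle may couple several SWEs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def classify_coupling(swes: pd.DataFrame, spindles: pd.DataFrame,
                      window: float = 4.0) -> pd.DataFrame:
    """Return a copy of ``swes`` with a boolean ``coupled`` column set."""
    if window <= 0:
        raise ValueError("window must be positive")
    out = swes.copy()
    if len(swes) == 0:
        out["coupled"] = pd.Series(dtype=bool)
        return out
    if len(spindles) == 0:
        out["coupled"] = False
        return out
    swe_peaks = np.asarray(swes["neg_peak_time"], dtype=float)
    spin_peaks = np.asarray(spindles["peak_power_time"], dtype=float)
    dist = np.abs(swe_peaks[:, None] - spin_peaks[None, :])
    out["coupled"] = (dist <= window / 2).any(axis=1)
    return out
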