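"""GLM design construction for event-related BOLD analyses.

Builds the regressor matrix for the four model variants used to map slow
wave events (SWEs) onto BOLD data:

``main``
    SWE events of interest + spindle events of no interest.
``syncs``
    adds a parametric modulator carrying each SWE's synchronization score.
``coupling_syncs``
    two serially orthogonalized modulators — a binary spindle-coupling
    regressor entered first, then the synchronization scores — so coupling
    is given explanatory priority.
``stage``
    separate event regressors for N2 and N3 SWEs.
``stage_syncs``
    N2/N3 event regressors each with its own synchronization-score
    modulator (interaction model).

All variants share the nuisance set: 24 motion parameters (6 base, their
temporal derivatives, and both sets squared), 5 CSF principal components
(aCompCor), and a constant.  Event vectors are duration boxcars convolved
with a canonical double-gamma haemodynamic response function on an
oversampled grid, then sampled at the frame times (frame midpoints).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

VARIANTS = ("main", "syncs", "coupling_syncs", "stage", "stage_syncs")

MOTION_BASE = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class HrfSpec:
    """Canonical double-gamma haemodynamic response function parameters.

    The response is the difference of two gamma probability densities: a
    positive lobe peaking near ``peak_delay`` seconds and an undershoot
    peaking near ``undershoot_delay`` seconds, scaled down by
    ``undershoot_ratio``.  Defaults give the familiar ~5 s peak / ~15 s
    undershoot shape.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0
    length: float = 32.0
    oversampling: int = 16

    def __post_init__(self) -> None:
        if self.length <= self.peak_delay:
            raise ValueError("kernel length must exceed the peak delay")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")
        if min(self.peak_delay, self.undershoot_delay,
               self.peak_dispersion, self.undershoot_dispersion,
               self.undershoot_ratio) <= 0:
            raise ValueError("HRF parameters must be positive")


def canonical_hrf(spec: HrfSpec | None = None, dt: float = 0.1) -> np.ndarray:
    """Sample the canonical HRF on ``[0, spec.length]`` at step ``dt``.

    The kernel is peak-normalized (max = 1) so that a unit-height event
    regressor peaks at the regression coefficient's value.
    """
    spec = spec or HrfSpec()
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, spec.length + dt / 2, dt)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = peak - under / spec.undershoot_ratio
    return h / np.max(h)


def _regressor_from_heights(onsets: np.ndarray, durations: np.ndarray,
                            heights: np.ndarray, frame_times: np.ndarray,
                            spec: HrfSpec) -> np.ndarray:
    """Boxcar-at-height convolution on an oversampled grid, sampled at frames."""
    frame_times = np.asarray(frame_times, dtype=float)
    if len(frame_times) < 2:
        raise ValueError("need at least two frame times")
    frame_dt = np.median(np.diff(frame_times))
    run_end = frame_times[-1] + frame_dt / 2
    if np.any(onsets < 0) or np.any(onsets + durations > run_end):
        raise ValueError("event extends beyond the run")
    dt = frame_dt / spec.oversampling
    grid = np.arange(0.0, run_end + dt, dt)
    box = np.zeros_like(grid)
    for onset, dur, h in zip(onsets, durations, heights):
        i0 = int(np.round(onset / dt))
        i1 = int(np.round((onset + dur) / dt))
        if i1 <= i0:  # zero-duration event -> one-sample impulse
            i1 = i0 + 1
        box[i0:min(i1, len(box))] += h
    kernel = canonical_hrf(spec, dt)
    conv = np.convolve(box, kernel)[: len(grid)]
    return np.interp(frame_times, grid, conv)


def build_event_regressor(events: pd.DataFrame, frame_times: np.ndarray,
                          spec: HrfSpec | None = None) -> np.ndarray:
    """HRF-convolved unit boxcar regressor from an (onset, duration) table."""
    spec = spec or HrfSpec()
    if len(events) == 0:
        return np.zeros(len(frame_times))
    onsets = np.asarray(events["onset"], dtype=float)
    durations = np.asarray(events["duration"], dtype=float)
    return _regressor_from_heights(onsets, durations, np.ones(len(onsets)),
                                   frame_times, spec)


def build_parametric_modulator(events: pd.DataFrame, values: np.ndarray,
                               frame_times: np.ndarray,
                               spec: HrfSpec | None = None) -> np.ndarray:
    """Mean-centered per-event values as boxcar heights, HRF-convolved.

    Centering across events makes the modulator orthogonal in expectation to
    the unit event regressor, so the event column keeps the mean response.
    """
    spec = spec or HrfSpec()
    values = np.asarray(values, dtype=float)
    if len(values) != len(events):
        raise ValueError("one modulator value required per event")
    if len(events) == 0:
        return np.zeros(len(frame_times))
    centered = values - values.mean()
    onsets = np.asarray(events["onset"], dtype=float)
    durations = np.asarray(events["duration"], dtype=float)
    return _regressor_from_heights(onsets, durations, centered, frame_times, spec)


def serial_orthogonalize(columns: np.ndarray) -> np.ndarray:
    """Gram-Schmidt in column order: column k is residualized against all
    earlier columns; earlier columns are left unchanged.

    Zero-norm columns are left as zeros with a warning.
    """
    X = np.array(columns, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D array with at least two columns")
    for k in range(1, X.shape[1]):
        prev = X[:, :k]
        norms = np.linalg.norm(prev, axis=0)
        keep = norms > 1e-12
        if keep.any():
            beta, *_ = np.linalg.lstsq(prev[:, keep], X[:, k], rcond=None)
            X[:, k] = X[:, k] - prev[:, keep] @ beta
        if np.linalg.norm(X[:, k]) <= 1e-10 * max(1.0, norms.max(initial=1.0)):
            warnings.warn(f"column {k} has zero norm after orthogonalization",
                          stacklevel=2)
            X[:, k] = 0.0
    return X


def _residualize(col: np.ndarray, against: np.ndarray) -> np.ndarray:
    stacked = np.column_stack([against, col])
    return serial_orthogonalize(stacked)[:, -1]


def motion_24(six_params: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Expand 6 rigid-body motion traces to the 24-parameter set:
    [R, dR, R^2, dR^2], with backward differences (first row zero)."""
    X = np.asarray(six_params, dtype=float)
    if X.ndim != 2 or X.shape[1] != 6:
        raise ValueError("expected a frames x 6 motion matrix")
    dX = np.vstack([np.zeros((1, 6)), np.diff(X, axis=0)])
    out = np.column_stack([X, dX, X**2, dX**2])
    names = ([f"motion_{n}" for n in MOTION_BASE]
             + [f"motion_{n}_derivative" for n in MOTION_BASE]
             + [f"motion_{n}_sq" for n in MOTION_BASE]
             + [f"motion_{n}_derivative_sq" for n in MOTION_BASE])
    return pd.DataFrame(out, columns=names)


def acompcor(csf_timeseries: np.ndarray, n_components: int = 5) -> pd.DataFrame:
    """Anatomical component correction: top principal components of the
    linearly detrended, per-voxel standardized CSF voxel matrix.

    Returns unit-variance, mutually orthogonal component time courses.
    """
    X = np.asarray(csf_timeseries, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a frames x voxels CSF matrix")
    n_frames, n_voxels = X.shape
    if n_frames < n_components or n_voxels < n_components:
        raise ValueError(f"need at least {n_components} frames and voxels")
    X = signal.detrend(X, axis=0, type="linear")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    rank = np.linalg.matrix_rank(X)
    n_keep = min(n_components, rank)
    if n_keep < n_components:
        warnings.warn(f"CSF matrix rank {rank} < {n_components}; "
                      f"returning {n_keep} components", stacklevel=2)
    comps = PCA(n_components=n_keep, svd_solver="full").fit_transform(X)
    comps = comps / comps.std(axis=0)
    return pd.DataFrame(comps, columns=[f"acompcor_{i + 1:02d}"
                                        for i in range(n_keep)])


def _split_by_stage(swes: pd.DataFrame) -> dict[str, pd.DataFrame]:
    if "stage" not in swes.columns or swes["stage"].isna().all():
        raise ValueError("stage-resolved variants require staged SWEs "
                         "(run detection with a hypnogram)")
    return {st: swes[swes["stage"] == st] for st in ("N2", "N3")}


def assemble_design(variant: str, swes: pd.DataFrame,
                    spindles: pd.DataFrame | None,
                    motion: np.ndarray | pd.DataFrame,
                    csf: np.ndarray,
                    frame_times: np.ndarray,
                    hrf: HrfSpec | None = None,
                    n_cosine: int = 0,
                    drift_order: int = 0) -> pd.DataFrame:
    """Assemble the full frame-times x regressors design matrix.

    Condition columns depend on ``variant`` (see module docstring); the
    spindle no-interest column is included for the main/syncs/coupling
    variants.  Modulators are serially orthogonalized after their event
    column.  Returns a DataFrame indexed by frame time whose
    ``attrs['condition_columns']`` lists the columns of interest.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    hrf = hrf or HrfSpec()
    frame_times = np.asarray(frame_times, dtype=float)
    cols: dict[str, np.ndarray] = {}
    conditions: list[str] = []

    if variant in ("main", "syncs", "coupling_syncs"):
        swe_col = build_event_regressor(swes, frame_times, hrf)
        cols["swe"] = swe_col
        conditions.append("swe")
        if variant in ("syncs", "coupling_syncs"):
            syncs = build_parametric_modulator(
                swes, np.asarray(swes["sync_score"], dtype=float),
                frame_times, hrf)
        if variant == "syncs":
            cols["swe_by_syncs"] = _residualize(syncs, swe_col[:, None])
            conditions.append("swe_by_syncs")
        elif variant == "coupling_syncs":
            if "coupled" not in swes.columns:
                raise ValueError("coupling_syncs variant requires a 'coupled' "
                                 "column (run coupling classification first)")
            coupling = build_parametric_modulator(
                swes, np.asarray(swes["coupled"], dtype=float),
                frame_times, hrf)
            ortho = serial_orthogonalize(
                np.column_stack([swe_col, coupling, syncs]))
            cols["swe_by_coupling"] = ortho[:, 1]
            cols["swe_by_syncs"] = ortho[:, 2]
            conditions += ["swe_by_coupling", "swe_by_syncs"]
        # the spindle no-interest column is dropped when no spindles were
        # detected (an all-zero column would make the design rank deficient)
        if spindles is not None and len(spindles):
            cols["spindle"] = build_event_regressor(spindles, frame_times, hrf)
    else:  # stage-resolved variants
        by_stage = _split_by_stage(swes)
        for st in ("N2", "N3"):
            cols[f"swe_{st.lower()}"] = build_event_regressor(
                by_stage[st], frame_times, hrf)
            conditions.append(f"swe_{st.lower()}")
        if variant == "stage_syncs":
            for st in ("N2", "N3"):
                ev = by_stage[st]
                mod = build_parametric_modulator(
                    ev, np.asarray(ev["sync_score"], dtype=float),
                    frame_times, hrf)
                name = f"swe_{st.lower()}_by_syncs"
                cols[name] = _residualize(mod, cols[f"swe_{st.lower()}"][:, None])
                conditions.append(name)

    nuisance = pd.concat([motion_24(motion), acompcor(csf)], axis=1)
    for name in nuisance.columns:
        cols[name] = nuisance[name].to_numpy()
    for j in range(1, n_cosine + 1):
        t = (frame_times - frame_times[0]) / (frame_times[-1] - frame_times[0])
        cols[f"cosine_{j:02d}"] = np.cos(np.pi * j * t)
    if drift_order > 0:
        x01 = np.linspace(-1, 1, len(frame_times))
        leg = np.polynomial.legendre.legvander(x01, drift_order)[:, 1:]
        for j in range(drift_order):
            cols[f"poly_{j + 1:02d}"] = leg[:, j]
    cols["constant"] = np.ones(len(frame_times))

    X = pd.DataFrame(cols, index=pd.Index(frame_times, name="frame_time"))
    if X.isna().any().any():
        raise ValueError("design matrix contains NaN")
    X.attrs["condition_columns"] = conditions
    X.attrs["variant"] = variant
    return X


class DesignMatrixBuilder(BaseEstimator):
    """Estimator-style wrapper around :func:`assemble_design`.

    Parameters mirror the functional interface; ``build`` produces the
    design for one run.  Exposed as a BaseEstimator so HRF and variant
    choices participate in sklearn-style parameter management.
    """

    def __init__(self, variant: str = "main", hrf: HrfSpec | None = None,
                 n_cosine: int = 0, drift_order: int = 0):
        self.variant = variant
        self.hrf = hrf
        self.n_cosine = n_cosine
        self.drift_order = drift_order

    def build(self, swes: pd.DataFrame, spindles: pd.DataFrame | None,
              motion, csf, frame_times) -> pd.DataFrame:
        return assemble_design(self.variant, swes, spindles, motion, csf,
                               frame_times, hrf=self.hrf,
                               n_cosine=self.n_cosine,
                               drift_order=self.drift_order)
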