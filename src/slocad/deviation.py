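"""SloCAD: slow wave canonical activity deviation.

A subject's binarized slow-wave activation map ``I`` is subtracted from a
cohort reference mask ``R`` of canonically recruited voxels.  The result
is a pair of deviation maps plus three scalar summaries:

* ``missing`` = R and not I — canonical voxels the subject fails to recruit;
  ``missing_fraction`` = |missing| / |R|
* ``extra`` = I and not R — subject activations outside the canon;
  ``extra_fraction`` = |extra| / |I| (0 for an empty subject map)
* ``dice_deviation`` = 1 - 2|I ∩ R| / (|I| + |R|) — the headline symmetric
  deviation scalar.

The directional fractions are reported alongside the symmetric Dice
deviation because a clinical reading needs to know whether a subject
under-recruits the canon or recruits atypical territory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io import check_same_geometry
from .maps import ReferenceMask


@dataclass
class SloCadResult:
    missing: np.ndarray
    extra: np.ndarray
    missing_fraction: float
    extra_fraction: float
    dice_deviation: float
    n_reference: int
    n_individual: int
    n_intersection: int
    mean_t_missing: float | None = None
    mean_t_extra: float | None = None

    def summary(self) -> dict:
        return {
            "missing_fraction": self.missing_fraction,
            "extra_fraction": self.extra_fraction,
            "dice_deviation": self.dice_deviation,
            "n_reference": self.n_reference,
            "n_individual": self.n_individual,
            "n_intersection": self.n_intersection,
        }


def slocad_deviation(individual: np.ndarray,
                     reference: ReferenceMask | np.ndarray,
                     t_map: np.ndarray | None = None,
                     atlas: np.ndarray | None = None,
                     label_weights: dict[int, float] | None = None
                     ) -> SloCadResult:
    """Deviation maps and scalars of one subject map against a reference.

    ``t_map`` optionally adds mean-T summaries within the missing/extra
    sets; ``atlas`` + ``label_weights`` optionally weight voxels by region
    when computing the fractions (uniform by default).
    """
    I = np.asarray(individual, dtype=bool)
    R = np.asarray(reference.mask if isinstance(reference, ReferenceMask)
                   else reference, dtype=bool)
    check_same_geometry(I, R)
    if not R.any():
        raise ValueError("reference mask is empty")

    missing = R & ~I
    extra = I & ~R

    if atlas is not None and label_weights:
        w = np.ones(R.shape, dtype=float)
        for label, weight in label_weights.items():
            w[np.asarray(atlas) == label] = weight
        missing_fraction = float(w[missing].sum() / w[R].sum())
        extra_fraction = (float(w[extra].sum() / w[I].sum())
                          if I.any() else 0.0)
    else:
        missing_fraction = float(missing.sum() / R.sum())
        extra_fraction = float(extra.sum() / I.sum()) if I.any() else 0.0

    inter = int((I & R).sum())
    dice_dev = 1.0 - 2.0 * inter / (int(I.sum()) + int(R.sum()))

    mean_t_missing = mean_t_extra = None
    if t_map is not None:
        t = np.asarray(t_map, dtype=float)
        check_same_geometry(t, R)
        mean_t_missing = float(np.nanmean(t[missing])) if missing.any() else 0.0
        mean_t_extra = float(np.nanmean(t[extra])) if extra.any() else 0.0

    return SloCadResult(missing=missing, extra=extra,
                        missing_fraction=missing_fraction,
                        extra_fraction=extra_fraction,
                        dice_deviation=float(dice_dev),
                        n_reference=int(R.sum()),
                        n_individual=int(I.sum()),
                        n_intersection=inter,
                        mean_t_missing=mean_t_missing,
                        mean_t_extra=mean_t_extra)


class SloCadScorer(BaseEstimator):
    """Estimator-style deviation scorer: ``fit`` a reference mask, then
    ``transform`` subject maps into :class:`SloCadResult` objects."""

    def __init__(self):
        pass

    def fit(self, reference: ReferenceMask | np.ndarray, y=None):
        mask = (reference.mask if isinstance(reference, ReferenceMask)
                else np.asarray(reference, dtype=bool))
        if not mask.any():
            raise ValueError("reference mask is empty")
        self.reference_ = reference
        return self

    def transform(self, individual: np.ndarray,
                  t_map: np.ndarray | None = None) -> SloCadResult:
        return slocad_deviation(individual, self.reference_, t_map=t_map)
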