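"""Probability (penetrance) maps, reference masks, and overlap statistics.

Binarized subject activation maps are averaged voxelwise into a
probability map (values are multiples of 1/N), thresholded at >= 20% to
form a reference mask of canonically recruited voxels, and compared
between cohorts by shared-voxel counts and percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import check_same_geometry


@dataclass
class ProbabilityMap:
    """Voxelwise activation probability across N subjects."""

    values: np.ndarray
    n_subjects: int


@dataclass
class ReferenceMask:
    """Binary mask of canonically recruited voxels."""

    mask: np.ndarray
    threshold: float
    n_subjects: int = 0


def probability_map(binary_maps: list[np.ndarray]) -> ProbabilityMap:
    """Voxelwise mean of {0, 1} subject maps."""
    if len(binary_maps) == 0:
        raise ValueError("need at least one subject map")
    arrays = [np.asarray(m, dtype=bool) for m in binary_maps]
    check_same_geometry(*arrays)
    stacked = np.stack([a.astype(float) for a in arrays])
    return ProbabilityMap(values=stacked.mean(axis=0),
                          n_subjects=len(arrays))


def reference_mask(prob: ProbabilityMap, threshold: float = 0.20,
                   strict: bool = False) -> ReferenceMask:
    """Threshold a probability map into a reference mask.

    Inclusion is ``>= threshold`` by default; ``strict=True`` switches to
    ``>``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    mask = (prob.values > threshold) if strict else (prob.values >= threshold)
    return ReferenceMask(mask=mask, threshold=threshold,
                         n_subjects=prob.n_subjects)


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"),
                                           rounding=ROUND_HALF_UP))


class MaskOverlap(NamedTuple):
    n_a: int
    n_b: int
    n_shared: int
    pct_of_a: float
    pct_of_b: float


def mask_overlap(a: ReferenceMask | np.ndarray,
                 b: ReferenceMask | np.ndarray) -> MaskOverlap:
    """Shared-voxel count and the percentage of each mask it represents
    (reported rounded half-up to one decimal)."""
    ma = np.asarray(a.mask if isinstance(a, ReferenceMask) else a, dtype=bool)
    mb = np.asarray(b.mask if isinstance(b, ReferenceMask) else b, dtype=bool)
    check_same_geometry(ma, mb)
    n_a, n_b = int(ma.sum()), int(mb.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("overlap percentages undefined for an empty mask")
    n_shared = int((ma & mb).sum())
    return MaskOverlap(n_a=n_a, n_b=n_b, n_shared=n_shared,
                       pct_of_a=_round1(100.0 * n_shared / n_a),
                       pct_of_b=_round1(100.0 * n_shared / n_b))


def roi_voxel_counts(binary: np.ndarray, atlas: np.ndarray) -> pd.Series:
    """Activated voxel count per nonzero atlas label."""
    binary = np.asarray(binary, dtype=bool)
    atlas = np.asarray(atlas)
    check_same_geometry(binary, atlas)
    labels = np.unique(atlas)
    labels = labels[labels != 0]
    counts = {int(lbl): int((binary & (atlas == lbl)).sum()) for lbl in labels}
    return pd.Series(counts, name="n_voxels").rename_axis("label")


class ReferenceMapBuilder(BaseEstimator):
    """Estimator-style aggregation of subject maps into a reference mask.

    ``fit`` over a list of binary subject maps sets ``probability_map_``
    and ``mask_``.
    """

    def __init__(self, threshold: float = 0.20, strict: bool = False):
        self.threshold = threshold
        self.strict = strict

    def fit(self, binary_maps: list[np.ndarray], y=None):
        self.probability_map_ = probability_map(binary_maps)
        self.mask_ = reference_mask(self.probability_map_,
                                    threshold=self.threshold,
                                    strict=self.strict)
        return self
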