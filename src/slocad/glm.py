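"""Voxel-wise GLM fitting, T-contrasts, and FDR + cluster-extent thresholding.

Subject-level BOLD runs are modeled voxel by voxel with ordinary least
squares against a shared design matrix.  A T-contrast produces a T map and
one-sided (activation) p values with ``df = frames - rank(X)``.  Subject
maps are thresholded by Benjamini-Hochberg FDR over the analysis mask at
q < 0.05 followed by a cluster extent filter (k >= 10 voxels, 26-neighbor
connectivity by default), matching the conventional event-related fMRI
reporting threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import BoldRun

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class GlmFit:
    """Fitted voxelwise OLS model."""

    beta: np.ndarray          # (n_columns,) + grid
    sigma2: np.ndarray        # grid
    df: int
    columns: list[str]
    xtx_inv: np.ndarray
    mask: np.ndarray          # boolean grid


@dataclass
class StatMap:
    """T statistic map with one-sided p values; NaN outside the mask."""

    t: np.ndarray
    p: np.ndarray
    df: int
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def _design_array(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    X = np.asarray(design, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _check_rank(X: np.ndarray, columns: list[str]) -> int:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True)
        dependent = sorted(columns[i] for i in piv[rank:])
        raise ValueError(f"design is rank deficient; dependent columns: "
                         f"{dependent}")
    return rank


def fit_glm(bold: BoldRun | np.ndarray, design,
            mask: np.ndarray | None = None) -> GlmFit:
    """Ordinary least squares per masked voxel.

    ``bold`` may be a :class:`BoldRun` or a plain 4-D array (x, y, z,
    frames).  The analysis mask defaults to the full grid.
    """
    data = bold.data if isinstance(bold, BoldRun) else np.asarray(bold, float)
    if data.ndim != 4:
        raise ValueError("BOLD data must be 4-D")
    X, columns = _design_array(design)
    n_frames = X.shape[0]
    if data.shape[3] != n_frames:
        raise ValueError(f"frames mismatch: BOLD has {data.shape[3]}, "
                         f"design has {n_frames}")
    grid = data.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask geometry does not match the BOLD grid")

    rank = _check_rank(X, columns)
    df = n_frames - rank
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")

    Y = data[mask].T                       # frames x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = (resid ** 2).sum(axis=0)
    # round-off residuals of an exactly representable series count as zero
    tss = (Y ** 2).sum(axis=0)
    rss[rss <= 1e-12 * np.maximum(tss, np.finfo(float).tiny)] = 0.0

    beta_vol = np.full((X.shape[1],) + grid, np.nan)
    beta_vol[:, mask] = beta
    sigma2_vol = np.full(grid, np.nan)
    sigma2_vol[mask] = rss / df
    return GlmFit(beta=beta_vol, sigma2=sigma2_vol, df=df, columns=columns,
                  xtx_inv=np.linalg.inv(X.T @ X), mask=mask)


def _contrast_vector(fit: GlmFit, contrast) -> np.ndarray:
    if isinstance(contrast, str):
        c = np.zeros(len(fit.columns))
        c[fit.columns.index(contrast)] = 1.0
        return c
    if isinstance(contrast, dict):
        c = np.zeros(len(fit.columns))
        for name, w in contrast.items():
            c[fit.columns.index(name)] = w
        return c
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(fit.columns),):
        raise ValueError("contrast length does not match design columns")
    return c


def t_contrast(fit: GlmFit, contrast) -> StatMap:
    """T map and one-sided (upper-tail) p values for a contrast.

    ``contrast`` is a weight vector, a column name, or a {name: weight}
    dict.  Voxels with zero residual variance get a +/-inf T sentinel (with
    a warning) and p = 0 for positive effects.
    """
    c = _contrast_vector(fit, contrast)
    if not np.any(c):
        raise ValueError("all-zero contrast")
    eff = np.tensordot(c, fit.beta, axes=1)
    var_scale = float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(fit.sigma2 * var_scale)
        t = eff / se
    zero_var = fit.mask & (fit.sigma2 == 0)
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} voxel(s) with zero residual "
                      "variance; T set to an infinite sentinel", stacklevel=2)
        t[zero_var] = np.where(eff[zero_var] >= 0, np.inf, -np.inf)
    p = np.full(t.shape, np.nan)
    finite = fit.mask & np.isfinite(t)
    p[finite] = stats.t.sf(t[finite], fit.df)
    p[fit.mask & np.isposinf(t)] = 0.0
    p[fit.mask & np.isneginf(t)] = 1.0
    t = np.where(fit.mask, t, np.nan)
    return StatMap(t=t, p=p, df=fit.df, mask=fit.mask)


def fdr_threshold(p: np.ndarray, mask: np.ndarray,
                  q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg over the masked voxels; returns a binary map."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    pvals = np.asarray(p, dtype=float)[mask]
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    out = np.zeros(mask.shape, dtype=bool)
    out[mask] = reject
    return out


def cluster_extent_filter(binary: np.ndarray, k: int = 10,
                          connectivity: int = 26) -> np.ndarray:
    """Zero connected components smaller than ``k`` voxels (k inclusive)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be one of 6, 18, 26")
    binary = np.asarray(binary, dtype=bool)
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return binary.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= k
    keep[0] = False
    return keep[labels]


def threshold_statmap(stat: StatMap, q: float = 0.05, k: int = 10,
                      mask: np.ndarray | None = None,
                      connectivity: int = 26
                      ) -> tuple[np.ndarray, np.ndarray]:
    """FDR threshold first, then the cluster extent filter.

    Returns the binary survivor map and the T volume restricted to it
    (zero elsewhere).
    """
    mask = stat.mask if mask is None else np.asarray(mask, dtype=bool)
    survivors = fdr_threshold(stat.p, mask, q=q)
    survivors = cluster_extent_filter(survivors, k=k,
                                      connectivity=connectivity)
    t_thresh = np.where(survivors, stat.t, 0.0)
    return survivors, t_thresh


class VoxelGlm(BaseEstimator):
    """Estimator-style voxelwise GLM.

    ``fit(bold, design)`` stores ``beta_``, ``sigma2_`` and ``df_``;
    ``t_contrast`` and ``threshold`` operate on the fitted model.
    """

    def __init__(self, mask: np.ndarray | None = None):
        self.mask = mask

    def fit(self, bold: BoldRun | np.ndarray, design):
        fit = fit_glm(bold, design, mask=self.mask)
        self.fit_ = fit
        self.beta_ = fit.beta
        self.sigma2_ = fit.sigma2
        self.df_ = fit.df
        self.columns_ = fit.columns
        return self

    def t_contrast(self, contrast) -> StatMap:
        return t_contrast(self.fit_, contrast)

    def threshold(self, contrast, q: float = 0.05, k: int = 10,
                  connectivity: int = 26) -> tuple[np.ndarray, np.ndarray]:
        return threshold_statmap(self.t_contrast(contrast), q=q, k=k,
                                 connectivity=connectivity)
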