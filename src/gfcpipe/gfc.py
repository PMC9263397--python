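"""Voxel-wise global functional connectivity (GFC).

GFC of a voxel is the mean Fisher-z-transformed Pearson correlation between
that voxel's time series and the series of every *other* voxel inside a
gray-matter mask:

    GFC(i) = 1/(N-1) * sum_{j != i} atanh(r_ij)

The transform is applied before averaging, so the computation is genuinely
pairwise; :func:`gfc_map` streams the N x N correlation matrix in blocks of
mask voxels (peak extra memory O(N * chunk_size), never O(N^2)), while
:func:`gfc_map_bruteforce` materializes the full matrix and serves as the
independent oracle for testing.

Negative correlations enter the mean as-is (signed z); |r| is clipped to
1 - 1e-7 before atanh so maps are always finite.  Voxels with zero temporal
variance have no defined correlation: they are excluded from other voxels'
means (both numerator and denominator) and their own GFC is NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Bold4D

#: correlations are clipped to +/- (1 - R_CLIP_EPS) before Fisher z
R_CLIP_EPS = 1e-7


class MaskError(ValueError):
    """Invalid or incompatible gray-matter mask."""


@dataclass
class GrayMatterMask:
    """Boolean gray-matter mask with its grid geometry and origin threshold."""

    mask: np.ndarray
    affine: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.mask.ndim != 3:
            raise MaskError("mask must be a 3D volume")
        if not self.mask.any():
            raise MaskError("gray-matter mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class GFCMap:
    """Per-voxel mean Fisher-z connectivity; NaN outside the mask.

    Voxels inside the mask whose series had zero variance are also NaN and
    counted in `n_undefined`.
    """

    values: np.ndarray
    affine: np.ndarray
    subject_id: str = ""
    n_undefined: int = 0

    def in_mask(self, mask: GrayMatterMask) -> np.ndarray:
        return self.values[mask.mask]


def make_gm_mask(
    prob_volume: np.ndarray,
    affine: np.ndarray,
    threshold: float = 0.2,
) -> GrayMatterMask:
    """Threshold a tissue-probability volume: include voxels with p > threshold.

    The inequality is strict, so a probability exactly equal to the
    threshold is excluded.
    """
    prob = np.asarray(prob_volume, dtype=np.float64)
    if prob.min() < 0 or prob.max() > 1:
        raise MaskError("probability volume must lie in [0, 1]")
    mask = prob > threshold
    if not mask.any():
        raise MaskError(f"no voxels with probability > {threshold}")
    return GrayMatterMask(mask, affine, threshold)


def _masked_series(bold: Bold4D, mask: GrayMatterMask) -> np.ndarray:
    if mask.mask.shape != bold.grid_shape:
        raise MaskError(
            f"mask grid {mask.mask.shape} != image grid {bold.grid_shape}"
        )
    if bold.n_volumes < 3:
        raise MaskError("GFC needs at least 3 time points")
    if mask.n_voxels < 2:
        raise MaskError("GFC needs at least 2 mask voxels")
    return bold.data[mask.mask]  # N x t


def gfc_map(
    bold: Bold4D,
    mask: GrayMatterMask,
    chunk_size: int = 2048,
    subject_id: str = "",
) -> GFCMap:
    """Compute the GFC map by streaming pairwise correlations in chunks.

    The result is independent of `chunk_size` (identical to the brute-force
    oracle within 1e-10).
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be positive")
    x = _masked_series(bold, mask)
    n = x.shape[0]
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    valid = norms > 0
    n_valid = int(valid.sum())
    out = np.full(bold.grid_shape, np.nan)
    vals = np.full(n, np.nan)
    if n_valid >= 2:
        xn = xc[valid] / norms[valid, None]  # unit-norm rows: r = dot product
        sums = np.empty(n_valid)
        for start in range(0, n_valid, chunk_size):
            stop = min(start + chunk_size, n_valid)
            r = xn[start:stop] @ xn.T  # chunk x N_valid
            np.clip(r, -1 + R_CLIP_EPS, 1 - R_CLIP_EPS, out=r)
            z = np.arctanh(r)
            # zero the self-correlation entries before summing the rows
            z[np.arange(stop - start), np.arange(start, stop)] = 0.0
            sums[start:stop] = z.sum(axis=1)
        vals[valid] = sums / (n_valid - 1)
    out[mask.mask] = vals
    return GFCMap(out, mask.affine, subject_id, n_undefined=n - n_valid)


def gfc_map_bruteforce(
    bold: Bold4D,
    mask: GrayMatterMask,
    subject_id: str = "",
) -> GFCMap:
    """Oracle GFC: explicit N x N correlation matrix, Fisher z, row means.

    Only suitable for small masks; used to validate :func:`gfc_map`.
    """
    x = _masked_series(bold, mask)
    n = x.shape[0]
    sd = x.std(axis=1)
    valid = sd > 0
    n_valid = int(valid.sum())
    out = np.full(bold.grid_shape, np.nan)
    vals = np.full(n, np.nan)
    if n_valid >= 2:
        r = np.corrcoef(x[valid])
        r = np.clip(r, -1 + R_CLIP_EPS, 1 - R_CLIP_EPS)
        z = np.arctanh(r)
        np.fill_diagonal(z, 0.0)
        vals[valid] = z.sum(axis=1) / (n_valid - 1)
    out[mask.mask] = vals
    return GFCMap(out, mask.affine, subject_id, n_undefined=n - n_valid)


def extract_cluster_mean_z(gfc: GFCMap, cluster_voxels: np.ndarray) -> float:
    """Mean GFC z over a cluster given as an (m, 3) array of voxel indices."""
    idx = np.atleast_2d(np.asarray(cluster_voxels, dtype=int))
    if idx.size == 0:
        raise ValueError("empty cluster")
    if idx.shape[1] != 3:
        raise ValueError("cluster_voxels must be (m, 3) voxel indices")
    vals = gfc.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    if np.isnan(vals).any():
        raise ValueError("cluster contains voxels outside the defined GFC mask")
    return float(vals.mean())
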