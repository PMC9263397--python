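"""Mass-univariate group inference on GFC maps.

A three-group ANCOVA (F-test for the group factor, adjusting for age,
gender, education years, and mean frame-wise displacement) is fitted
independently at every gray-matter voxel by ordinary least squares model
comparison, followed by covariate-adjusted pairwise post hoc t-tests.
Voxel-level multiple comparisons are handled with the Benjamini-Hochberg
step-up procedure, and surviving voxels are grouped into connected
components (default 26-connectivity) reported with size, peak statistic and
peak world (MNI) coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats


class DesignError(ValueError):
    """Invalid design matrix for voxel-wise inference."""


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Subjects x regressors design with named columns.

    `group_cols` indexes the group-indicator (dummy) columns whose joint
    contribution the ANCOVA F tests.
    """

    matrix: np.ndarray
    labels: list[str]
    group_cols: list[int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise DesignError("design must be 2D")
        if len(self.labels) != self.matrix.shape[1]:
            raise DesignError("one label per column required")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise DesignError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


def build_design(
    table: pd.DataFrame,
    group_col: str = "group",
    covariates: tuple[str, ...] = ("age", "gender", "education_years", "mean_fd"),
    reference_group: str | None = None,
) -> DesignMatrix:
    """Build intercept + group dummies + mean-centered covariates.

    Groups are dummy-coded against `reference_group` (default: last level in
    sorted order).  Covariates are mean-centered for numerical stability,
    which leaves F and t statistics unchanged.
    """
    groups = sorted(table[group_col].astype(str).unique())
    if len(groups) < 2:
        raise DesignError("need at least two groups")
    if reference_group is None:
        reference_group = groups[-1]
    if reference_group not in groups:
        raise DesignError(f"reference group {reference_group!r} not present")
    dummies = [g for g in groups if g != reference_group]
    cols = [np.ones(len(table))]
    labels = ["intercept"]
    for g in dummies:
        cols.append((table[group_col].astype(str) == g).to_numpy(float))
        labels.append(f"group[{g}]")
    group_cols = list(range(1, 1 + len(dummies)))
    for cov in covariates:
        v = table[cov].to_numpy(float)
        if np.isnan(v).any():
            raise DesignError(f"covariate {cov!r} has missing values")
        cols.append(v - v.mean())
        labels.append(cov)
    return DesignMatrix(np.column_stack(cols), labels, group_cols)


# ---------------------------------------------------------------------------
# Statistic maps
# ---------------------------------------------------------------------------

@dataclass
class StatMap:
    """Per-voxel statistic with p-values and an optional FDR rejection mask.

    `stat` and `p` are flat arrays over analysis-mask voxels, in the order
    given by ``mask_3d.nonzero()``.  Voxels where the statistic is undefined
    (zero residual variance) carry NaN.
    """

    stat: np.ndarray
    p: np.ndarray
    df: tuple[float, float] | float
    kind: str                      # "F" or "t"
    mask_3d: np.ndarray
    affine: np.ndarray
    fdr_mask: np.ndarray | None = None
    fdr_q: float | None = None
    fdr_threshold: float = field(default=np.nan)

    def volume(self, which: str = "stat") -> np.ndarray:
        """Embed a flat per-voxel array back into the 3D grid (NaN outside)."""
        src = {"stat": self.stat, "p": self.p}[which]
        out = np.full(self.mask_3d.shape, np.nan)
        out[self.mask_3d] = src
        return out


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sums of squares of Y (n x V) on X (n x k), per column of Y."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return np.einsum("ij,ij->j", resid, resid)


def _stack_maps(maps, mask_3d: np.ndarray) -> np.ndarray:
    y = np.stack([m.values[mask_3d] for m in maps])  # n x V
    if np.isnan(y).any():
        raise DesignError(
            "GFC maps contain undefined voxels inside the analysis mask; "
            "restrict the mask to voxels defined for every subject"
        )
    return y


def analysis_mask(maps, gm_mask_3d: np.ndarray) -> np.ndarray:
    """Voxels of the gray-matter mask with a defined GFC value for every subject."""
    ok = gm_mask_3d.copy()
    for m in maps:
        ok &= ~np.isnan(m.values)
    return ok


def fit_voxel_ancova(maps, design: DesignMatrix, mask_3d: np.ndarray) -> StatMap:
    """Voxel-wise ANCOVA F-test for the group factor.

    At each voxel the full model (intercept + group dummies + covariates)
    is compared with the reduced model without the group dummies:

        F = ((RSS_reduced - RSS_full) / q) / (RSS_full / (n - k))

    with q group dummies, giving df = (q, n - k).  Voxels with (numerically)
    zero full-model residual variance are flagged NaN rather than reported
    as spuriously significant.
    """
    if not design.group_cols:
        raise DesignError("design has no group columns to test")
    x_full = design.matrix
    n, k = x_full.shape
    q = len(design.group_cols)
    if n <= k:
        raise DesignError(f"need more subjects ({n}) than regressors ({k})")
    y = _stack_maps(maps, mask_3d)
    if y.shape[0] != n:
        raise DesignError("number of maps != design rows")
    keep = [j for j in range(k) if j not in design.group_cols]
    rss_full = _rss(x_full, y)
    rss_red = _rss(x_full[:, keep], y)
    df2 = n - k
    scale = float(np.mean(np.einsum("ij,ij->j", y, y))) + 1e-300
    degenerate = rss_full <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / q) / (rss_full / df2)
    f = np.where(degenerate, np.nan, np.maximum(f, 0.0))
    p = np.where(np.isnan(f), np.nan, stats.f.sf(f, q, df2))
    return StatMap(f, p, (float(q), float(df2)), "F", mask_3d,
                   affine=np.asarray(maps[0].affine), fdr_mask=None)


def posthoc_t(maps, design: DesignMatrix, mask_3d: np.ndarray) -> StatMap:
    """Covariate-adjusted two-group t-test per voxel.

    The design must contain exactly one group dummy; the statistic is the
    t-value of its coefficient, df = n - k, two-sided p.  The sign follows
    the dummy coding (positive = coded group above reference).
    """
    if len(design.group_cols) != 1:
        raise DesignError("post hoc t requires exactly one group dummy")
    x = design.matrix
    n, k = x.shape
    if n <= k:
        raise DesignError(f"need more subjects ({n}) than regressors ({k})")
    y = _stack_maps(maps, mask_3d)
    if y.shape[0] != n:
        raise DesignError("number of maps != design rows")
    j = design.group_cols[0]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    df = n - k
    scale = float(np.mean(np.einsum("ij,ij->j", y, y))) + 1e-300
    degenerate = rss <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(xtx_inv[j, j] * rss / df)
        t = beta[j] / se
    t = np.where(degenerate, np.nan, t)
    p = np.where(np.isnan(t), np.nan, 2 * stats.t.sf(np.abs(t), df))
    return StatMap(t, p, float(df), "t", mask_3d,
                   affine=np.asarray(maps[0].affine), fdr_mask=None)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level q.

    Rejects all hypotheses with p <= p_(i*) where
    i* = max{i : p_(i) <= i*q/m}.  NaN p-values are never rejected and do
    not count toward m.  Returns (rejection mask, adaptive p threshold);
    the threshold is NaN when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=np.float64)
    reject = np.zeros(p.shape, dtype=bool)
    finite = ~np.isnan(p)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return reject, float("nan")
    order = np.argsort(pf, kind="stable")
    sorted_p = pf[order]
    crit = (np.arange(1, m + 1) / m) * q
    below = sorted_p <= crit
    if not below.any():
        return reject, float("nan")
    i_star = int(np.max(np.flatnonzero(below)))
    threshold = float(sorted_p[i_star])
    reject[finite] = pf <= threshold
    return reject, threshold


def bh_adjusted_p(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values: p_adj_(i) = min_{j>=i} (m/j) p_(j), capped at 1."""
    p = np.asarray(p_values, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    finite = ~np.isnan(p)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return out
    order = np.argsort(pf, kind="stable")
    ranked = pf[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[finite] = res
    return out


def apply_fdr(stat_map: StatMap, q: float = 0.05) -> StatMap:
    """Attach the BH rejection mask at level q to a statistic map."""
    reject, threshold = fdr_bh(stat_map.p, q)
    stat_map.fdr_mask = reject
    stat_map.fdr_q = q
    stat_map.fdr_threshold = threshold
    return stat_map


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    """Connected component of surviving voxels."""

    voxels: np.ndarray          # (size, 3) voxel indices
    size: int
    peak_voxel: tuple[int, int, int]
    peak_mni: tuple[float, float, float]
    peak_stat: float
    sign: int                   # +1 / -1 for t maps, +1 for F maps


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def voxel_to_world(affine: np.ndarray, ijk) -> tuple[float, float, float]:
    """World (MNI mm) coordinate of a 0-based voxel index via the affine."""
    v = np.asarray(affine, float) @ np.array([ijk[0], ijk[1], ijk[2], 1.0])
    return (float(v[0]), float(v[1]), float(v[2]))


def label_clusters(
    stat_map: StatMap,
    connectivity: int = 26,
    min_extent: int = 1,
) -> list[Cluster]:
    """Connected components of the FDR-surviving voxels.

    t-maps are split by sign before labelling so a positive and a negative
    region touching each other are reported separately.  Each cluster
    reports its size, its peak statistic (maximal |stat|; ties broken by
    lowest linear voxel index) and the peak's world coordinate.  Clusters
    are sorted by size, largest first.
    """
    if stat_map.fdr_mask is None:
        raise DesignError("apply_fdr must be called before label_clusters")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = _STRUCTURES[connectivity]
    surviving = np.zeros(stat_map.mask_3d.shape, dtype=bool)
    surviving[stat_map.mask_3d] = stat_map.fdr_mask
    stat_vol = stat_map.volume("stat")
    clusters: list[Cluster] = []
    if stat_map.kind == "t":
        signed = [(1, surviving & (stat_vol > 0)), (-1, surviving & (stat_vol < 0))]
    else:
        signed = [(1, surviving)]
    for sign, vol in signed:
        labelled, n_comp = ndimage.label(vol, structure=structure)
        for comp in range(1, n_comp + 1):
            member = labelled == comp
            size = int(member.sum())
            if size < min_extent:
                continue
            idx = np.argwhere(member)
            vals = stat_vol[member]
            linear = np.ravel_multi_index(idx.T, vol.shape)
            best = np.lexsort((linear, -np.abs(vals)))[0]
            peak = tuple(int(c) for c in idx[best])
            clusters.append(
                Cluster(
                    voxels=idx,
                    size=size,
                    peak_voxel=peak,
                    peak_mni=voxel_to_world(stat_map.affine, peak),
                    peak_stat=float(vals[best]),
                    sign=sign,
                )
            )
    clusters.sort(key=lambda c: -c.size)
    return clusters


def cluster_table(clusters: list[Cluster]) -> pd.DataFrame:
    """Tabular cluster report: peak x/y/z (mm), voxel count, statistic value."""
    rows = [
        {
            "cluster": i + 1,
            "peak_x": c.peak_mni[0],
            "peak_y": c.peak_mni[1],
            "peak_z": c.peak_mni[2],
            "n_voxels": c.size,
            "stat_value": c.peak_stat,
        }
        for i, c in enumerate(clusters)
    ]
    return pd.DataFrame(rows, columns=["cluster", "peak_x", "peak_y", "peak_z",
                                       "n_voxels", "stat_value"])
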