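"""2-D radiomic features (first-order, GLCM texture, shape) and ANOVA selection.

The feature set is a fixed, named, versioned catalogue of 44 features
computed per tumor ROI on raw HU values: 19 first-order statistics, 15
gray-level co-occurrence matrix (GLCM) features and 10 shape descriptors.
Histogram and GLCM discretization uses a fixed bin width (default 25 HU)
anchored at the ROI minimum.  Feature selection keeps the top-k features by
one-way ANOVA F-value computed on the training split only and is then frozen
for the test split.

Conventions for degenerate ROIs: a constant ROI has variance 0, skewness and
kurtosis 0, entropy 0 and uniformity 1; the GLCM of a constant ROI is a
single cell, so contrast is 0, joint energy 1 and joint entropy 0, and GLCM
correlation is defined as 1 when either marginal variance vanishes (a
constant region is treated as perfectly correlated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

FEATURE_SET_VERSION = "1.0"
DEFAULT_BIN_WIDTH = 25.0
#: the 4 standard 2-D co-occurrence offsets (0, 45, 90, 135 degrees)
DEFAULT_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))
MIN_ROI_PIXELS = 256

FIRST_ORDER_NAMES = [
    "firstorder_mean", "firstorder_median", "firstorder_minimum",
    "firstorder_maximum", "firstorder_range", "firstorder_variance",
    "firstorder_skewness", "firstorder_kurtosis", "firstorder_energy",
    "firstorder_rms", "firstorder_mad", "firstorder_robust_mad",
    "firstorder_p10", "firstorder_p25", "firstorder_p75", "firstorder_p90",
    "firstorder_iqr", "firstorder_entropy", "firstorder_uniformity",
]
GLCM_NAMES = [
    "glcm_contrast", "glcm_dissimilarity", "glcm_homogeneity",
    "glcm_joint_energy", "glcm_joint_entropy", "glcm_correlation",
    "glcm_cluster_shade", "glcm_cluster_prominence", "glcm_max_probability",
    "glcm_sum_average", "glcm_sum_entropy", "glcm_difference_average",
    "glcm_difference_entropy", "glcm_inverse_variance", "glcm_autocorrelation",
]
SHAPE_NAMES = [
    "shape_area", "shape_perimeter", "shape_perimeter_area_ratio",
    "shape_compactness", "shape_elongation", "shape_major_axis",
    "shape_minor_axis", "shape_eccentricity", "shape_max_diameter",
    "shape_extent",
]
FEATURE_NAMES = FIRST_ORDER_NAMES + GLCM_NAMES + SHAPE_NAMES


@dataclass
class FeatureVector:
    names: List[str]
    values: np.ndarray

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass
class SelectionResult:
    selected_names: List[str]
    f_values: Dict[str, float]


def _check_roi(mask: np.ndarray, min_pixels: int):
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty ROI mask")
    if n < min_pixels:
        raise ValueError(f"ROI has {n} pixels (< {min_pixels}); rejected")
    return n


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width discretization anchored at the ROI minimum."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return np.floor((values - values.min()) / bin_width).astype(np.int64)


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def first_order_features(ct: np.ndarray, mask: np.ndarray,
                         bin_width: float = DEFAULT_BIN_WIDTH,
                         min_pixels: int = MIN_ROI_PIXELS) -> FeatureVector:
    """First-order statistics of the masked intensities (population moments)."""
    _check_roi(mask, min_pixels)
    x = np.asarray(ct, dtype=np.float64)[np.asarray(mask, dtype=bool)]
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    sd = np.sqrt(var)
    if var > 0:
        skew = np.mean((x - mean) ** 3) / sd ** 3
        kurt = np.mean((x - mean) ** 4) / var ** 2 - 3.0  # excess kurtosis
    else:
        skew = 0.0
        kurt = 0.0
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    inner = x[(x >= p10) & (x <= p90)]
    robust_mad = np.mean(np.abs(inner - inner.mean())) if inner.size else 0.0
    levels = discretize(x, bin_width)
    p = np.bincount(levels).astype(np.float64)
    p = p[p > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p * p).sum())
    vals = np.array([
        mean, np.median(x), x.min(), x.max(), x.max() - x.min(), var,
        skew, kurt, float((x ** 2).sum()), np.sqrt(np.mean(x ** 2)),
        np.mean(np.abs(x - mean)), robust_mad,
        p10, p25, p75, p90, p75 - p25, entropy, uniformity,
    ])
    return FeatureVector(FIRST_ORDER_NAMES, vals)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(ct: np.ndarray, mask: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH,
                offsets: Sequence[Tuple[int, int]] = DEFAULT_OFFSETS) -> np.ndarray:
    """Symmetric normalized GLCM averaged over the given offsets.

    Co-occurrences are counted only between pixel pairs that both lie inside
    the mask.  Each offset's matrix is symmetrized and normalized to sum 1
    before averaging.
    """
    mask = np.asarray(mask, dtype=bool)
    _check_roi(mask, 1)
    ct = np.asarray(ct, dtype=np.float64)
    vals = ct[mask]
    lvl_img = np.zeros(ct.shape, dtype=np.int64)
    lvl_img[mask] = discretize(vals, bin_width)
    L = int(lvl_img[mask].max()) + 1
    H, W = mask.shape
    mats = []
    for dr, dc in offsets:
        r0a, r0b = max(0, -dr), min(H, H - dr)
        c0a, c0b = max(0, -dc), min(W, W - dc)
        src = np.s_[r0a:r0b, c0a:c0b]
        dst = np.s_[r0a + dr:r0b + dr, c0a + dc:c0b + dc]
        both = mask[src] & mask[dst]
        if not both.any():
            continue
        i = lvl_img[src][both]
        j = lvl_img[dst][both]
        m = np.zeros((L, L), dtype=np.float64)
        np.add.at(m, (i, j), 1.0)
        m = m + m.T  # symmetric
        mats.append(m / m.sum())
    if not mats:
        raise ValueError("no co-occurring pixel pairs inside the mask")
    return np.mean(np.stack(mats), axis=0)


def glcm_features(ct: np.ndarray, mask: np.ndarray,
                  bin_width: float = DEFAULT_BIN_WIDTH,
                  offsets: Sequence[Tuple[int, int]] = DEFAULT_OFFSETS,
                  min_pixels: int = MIN_ROI_PIXELS) -> FeatureVector:
    _check_roi(mask, min_pixels)
    P = glcm_matrix(ct, mask, bin_width, offsets)
    L = P.shape[0]
    i = np.arange(L)[:, None].astype(np.float64)
    j = np.arange(L)[None, :].astype(np.float64)
    px = P.sum(axis=1)
    mu_i = float((i[:, 0] * px).sum())
    var_i = float(((i[:, 0] - mu_i) ** 2 * px).sum())
    # symmetric matrix: both marginals identical
    d = i - j
    s = i + j
    contrast = float((P * d ** 2).sum())
    dissimilarity = float((P * np.abs(d)).sum())
    homogeneity = float((P / (1.0 + d ** 2)).sum())
    joint_energy = float((P ** 2).sum())
    nz = P[P > 0]
    joint_entropy = float(-(nz * np.log2(nz)).sum())
    if var_i > 0:
        correlation = float((P * (i - mu_i) * (j - mu_i)).sum() / var_i)
    else:
        correlation = 1.0  # constant region: perfectly correlated by convention
    cluster_shade = float((P * (s - 2 * mu_i) ** 3).sum())
    cluster_prominence = float((P * (s - 2 * mu_i) ** 4).sum())
    max_probability = float(P.max())
    # sum / difference distributions
    ks = np.arange(2 * L - 1)
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (i + j).astype(int).ravel(), P.ravel())
    kd = np.arange(L)
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(i - j).astype(int).ravel(), P.ravel())
    sum_average = float((ks * p_sum).sum())
    nzs = p_sum[p_sum > 0]
    sum_entropy = float(-(nzs * np.log2(nzs)).sum())
    difference_average = float((kd * p_diff).sum())
    nzd = p_diff[p_diff > 0]
    difference_entropy = float(-(nzd * np.log2(nzd)).sum())
    off_diag = d != 0
    if off_diag.any():
        inverse_variance = float((P[off_diag] / d[off_diag] ** 2).sum())
    else:
        inverse_variance = 0.0
    autocorrelation = float((P * i * j).sum())
    vals = np.array([
        contrast, dissimilarity, homogeneity, joint_energy, joint_entropy,
        correlation, cluster_shade, cluster_prominence, max_probability,
        sum_average, sum_entropy, difference_average, difference_entropy,
        inverse_variance, autocorrelation,
    ])
    return FeatureVector(GLCM_NAMES, vals)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def shape2d_features(mask: np.ndarray, min_pixels: int = 1) -> FeatureVector:
    """2-D shape descriptors of a binary mask (pixel-grid conventions).

    Perimeter is the count of 4-neighborhood boundary edges (including image
    borders); the axis lengths come from the eigenvalues of the inertia
    (coordinate covariance) tensor; maximum diameter is the largest pairwise
    distance between pixel centers.
    """
    mask = np.asarray(mask, dtype=bool)
    n = _check_roi(mask, min_pixels)
    area = float(n)
    padded = np.pad(mask, 1)
    perimeter = 0.0
    for axis in (0, 1):
        perimeter += float(np.count_nonzero(np.diff(padded.astype(np.int8), axis=axis)))
    coords = np.argwhere(mask).astype(np.float64)
    cov = np.cov(coords.T, bias=True) if n > 1 else np.zeros((2, 2))
    cov = np.atleast_2d(cov)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lmax, lmin = max(evals[0], 0.0), max(evals[-1], 0.0)
    if lmax > 0:
        elongation = float(np.sqrt(lmin / lmax))
        eccentricity = float(np.sqrt(1.0 - lmin / lmax))
    else:
        elongation, eccentricity = 1.0, 0.0
    major_axis = float(4.0 * np.sqrt(lmax))
    minor_axis = float(4.0 * np.sqrt(lmin))
    if n == 1:
        max_diameter = 0.0
    elif n <= 3:
        max_diameter = float(pdist(coords).max())
    else:
        try:
            hull = coords[ConvexHull(coords).vertices]
        except Exception:  # collinear points
            hull = coords
        max_diameter = float(pdist(hull).max())
    rmin, rmax = coords[:, 0].min(), coords[:, 0].max()
    cmin, cmax = coords[:, 1].min(), coords[:, 1].max()
    extent = area / ((rmax - rmin + 1) * (cmax - cmin + 1))
    compactness = 4.0 * np.pi * area / perimeter ** 2
    vals = np.array([
        area, perimeter, perimeter / area, compactness, elongation,
        major_axis, minor_axis, eccentricity, max_diameter, extent,
    ])
    return FeatureVector(SHAPE_NAMES, vals)


def extract_features(ct: np.ndarray, mask: np.ndarray,
                     bin_width: float = DEFAULT_BIN_WIDTH,
                     offsets: Sequence[Tuple[int, int]] = DEFAULT_OFFSETS,
                     min_pixels: int = MIN_ROI_PIXELS) -> FeatureVector:
    """The full 44-feature vector for one ROI."""
    fo = first_order_features(ct, mask, bin_width, min_pixels)
    gl = glcm_features(ct, mask, bin_width, offsets, min_pixels)
    sh = shape2d_features(mask)
    return FeatureVector(FEATURE_NAMES,
                         np.concatenate([fo.values, gl.values, sh.values]))


# ---------------------------------------------------------------------------
# ANOVA selection
# ---------------------------------------------------------------------------

def anova_f(feature_values, labels) -> float:
    """One-way ANOVA F = between-group MS / within-group MS.

    For two groups this equals the squared pooled-variance t statistic.
    Returns +inf when the within-group variance is 0 but groups differ
    (ranked first) and NaN when the total variance is 0 (ranked last).
    """
    x = np.asarray(feature_values, dtype=np.float64)
    g = np.asarray(labels)
    groups = [x[g == u] for u in np.unique(g)]
    if len(groups) < 2 or any(len(gr) < 2 for gr in groups):
        raise ValueError("need >=2 groups with >=2 samples each")
    grand = x.mean()
    if np.allclose(x, grand):
        return float("nan")
    ssb = sum(len(gr) * (gr.mean() - grand) ** 2 for gr in groups)
    ssw = sum(((gr - gr.mean()) ** 2).sum() for gr in groups)
    dfb = len(groups) - 1
    dfw = x.size - len(groups)
    if ssw == 0:
        return float("inf")
    return float((ssb / dfb) / (ssw / dfw))


def select_top_k(feature_table, labels, k: int = 32) -> SelectionResult:
    """Top-k features by ANOVA F on the training split, descending.

    ``feature_table`` is a pandas DataFrame (columns = feature names) or a
    (matrix, names) pair.  Ties are broken by lexicographic feature name;
    NaN F-values rank last and are never selected.  If fewer than k features
    have a defined F, all of them are returned with a warning.
    """
    import pandas as pd

    if isinstance(feature_table, tuple):
        X, names = feature_table
        X = np.asarray(X, dtype=np.float64)
    else:
        df = pd.DataFrame(feature_table)
        names = list(df.columns)
        X = df.to_numpy(dtype=np.float64)
    labels = np.asarray(labels)
    f_values = {name: anova_f(X[:, idx], labels) for idx, name in enumerate(names)}

    def sort_key(name):
        f = f_values[name]
        if np.isnan(f):
            return (2, 0.0, name)
        if np.isinf(f):
            return (0, 0.0, name)
        return (1, -f, name)

    ranked = sorted(names, key=sort_key)
    usable = [n for n in ranked if not np.isnan(f_values[n])]
    if len(usable) < k:
        warnings.warn(f"only {len(usable)} features have a defined F-value; "
                      f"selecting all of them (k={k})")
    return SelectionResult(selected_names=usable[:k], f_values=f_values)


# ---------------------------------------------------------------------------
# z-scoring with frozen training statistics
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """z-score transform with mean/SD frozen on the training set."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        sd = X.std(axis=0)
        return cls(mean=X.mean(axis=0), sd=np.where(sd > 0, sd, 1.0))

    def transform(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.sd
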