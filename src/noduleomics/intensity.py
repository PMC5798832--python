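"""First-order intensity statistics, intensity-volume histogram and
shape features — the 33-feature "intensity & shape" block.

The 16-statistic summary (:func:`stat_set`) is shared with the filter
banks: every filtered response is summarized by the same statistics,
which is what makes 27 Laws kernels x 16 = 432, 8 wavelet subbands x
16 = 128 and 6 LoG scales x 16 = 96 features.

Degenerate-limit conventions (all documented, all exercised by tests):
skewness and kurtosis of a zero-variance sample are 0 (kurtosis is
reported as excess); the coefficient of variation is 0 when the mean
is 0, keeping zero-mean filter responses finite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .matrices import glcm_pair_stats
from .registry import IVH_PERCENTS, SHAPE_NAMES, STAT_NAMES
from .volumes import EmptyRoiError, ParameterError, RoiPatch


def stat_set(voxels, mask=None, bins: int = 64) -> dict[str, float]:
    """The 16-statistic summary of a (possibly filtered) region.

    ``voxels`` may be a 3D array with a boolean ``mask`` (spatial
    statistics use the patch geometry) or a flat value array, which is
    treated as a 1 x 1 x n patch. ``bins`` controls the histogram used
    for peak/entropy/uniformity; the two texture statistics
    (``contrast``, ``lcl_homo``) come from a 32-level GLCM of the
    region (distance 1, 13 directions averaged).
    """
    voxels = np.asarray(voxels, dtype=np.float64)
    if voxels.ndim == 1:
        voxels = voxels.reshape(1, 1, -1)
    if mask is None:
        mask = np.ones(voxels.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if bins < 2:
        raise ParameterError(f"bins must be >= 2, got {bins}")
    vals = voxels[mask]
    if vals.size == 0:
        raise EmptyRoiError("stat_set requires at least one value")

    vmin = float(vals.min())
    vmax = float(vals.max())
    mean = float(vals.mean())
    sd = float(vals.std())
    if vmax == vmin:
        peak = vmin
        entropy = 0.0
        uniformity = 1.0
    else:
        counts, edges = np.histogram(vals, bins=bins, range=(vmin, vmax))
        centers = 0.5 * (edges[:-1] + edges[1:])
        peak = float(centers[int(np.argmax(counts))])
        p = counts[counts > 0] / vals.size
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float((p ** 2).sum())
    skew = float(sps.skew(vals)) if sd > 0 else 0.0
    kurt = float(sps.kurtosis(vals)) if sd > 0 else 0.0  # excess kurtosis
    contrast, homo = glcm_pair_stats(voxels, mask, levels=32)
    return {
        "min": vmin,
        "max": vmax,
        "median": float(np.median(vals)),
        "peak": peak,
        "mean": mean,
        "sd": sd,
        "cv": sd / mean if mean != 0 else 0.0,
        "rms": float(np.sqrt(np.mean(vals ** 2))),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((vals ** 2).sum()),
        "entropy": entropy,
        "uniformity": uniformity,
        "range": vmax - vmin,
        "contrast": contrast,
        "lcl_homo": homo,
    }


def ivh_features(patch: RoiPatch) -> dict[str, float]:
    """Intensity-volume-histogram features at the decile grid.

    ``Ix`` is the largest intensity such that at least x% of the ROI
    volume lies at or above it; ``Vx`` is the volume fraction at or
    above ``min + x% * range``. The construction mirrors dose-volume
    histogram reporting.
    """
    vals = np.sort(patch.values())[::-1]  # descending
    n = vals.size
    vmin = float(vals[-1])
    rng = float(vals[0]) - vmin
    out = {}
    for p in IVH_PERCENTS:
        k = int(np.ceil(p / 100 * n))
        k = max(k, 1)
        out[f"I{p}"] = float(vals[k - 1])
    for p in IVH_PERCENTS:
        thr = vmin + p / 100 * rng
        out[f"V{p}"] = float((vals >= thr).mean())
    return out


def _surface_area_mm2(mask: np.ndarray, spacing) -> float:
    from skimage.measure import marching_cubes, mesh_surface_area

    padded = np.pad(mask.astype(np.float64), 1, mode="constant")
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    return float(mesh_surface_area(verts, faces))


def _max_diameter_mm(mask: np.ndarray, spacing) -> float:
    """Largest pairwise distance between voxel corners of the surface."""
    from scipy.ndimage import binary_erosion
    from scipy.spatial import ConvexHull
    from scipy.spatial.distance import pdist

    surface = mask & ~binary_erosion(mask)
    idx = np.argwhere(surface).astype(np.float64)
    sp = np.asarray(spacing)
    centers = idx * sp
    corners = []
    for signs in np.ndindex(2, 2, 2):
        shift = (np.asarray(signs) - 0.5) * sp
        corners.append(centers + shift)
    pts = np.unique(np.concatenate(corners, axis=0), axis=0)
    if len(pts) > 300:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (flat) point clouds: fall through to pdist
    return float(pdist(pts).max())


def shape_features(patch: RoiPatch) -> dict[str, float]:
    """Volume, surface area and derived sphericity/compactness metrics.

    Volume is voxel-count based; surface area comes from a
    marching-cubes mesh of the mask. ``compactness2`` equals
    ``sphericity ** 3`` by construction.
    """
    sp = patch.spacing
    voxel_vol = sp[0] * sp[1] * sp[2]
    volume = patch.n_voxels * voxel_vol
    area = _surface_area_mm2(patch.mask, sp)
    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
    return {
        "volume": float(volume),
        "surface_area": area,
        "surface_to_volume": area / volume,
        "sphericity": sphericity,
        "compactness1": float(volume / (np.sqrt(np.pi) * area ** 1.5)),
        "compactness2": float(36 * np.pi * volume ** 2 / area ** 3),
        "max_diameter": _max_diameter_mm(patch.mask, sp),
    }


def intensity_shape_block(patch: RoiPatch, bins: int = 64) -> dict[str, float]:
    """All 33 intensity & shape features with registry names."""
    out = {}
    stats = stat_set(patch.voxels, patch.mask, bins=bins)
    for name in STAT_NAMES:
        out[f"Intensity_{name}"] = stats[name]
    for key, val in ivh_features(patch).items():
        out[f"IVH_{key}"] = val
    shp = shape_features(patch)
    for name in SHAPE_NAMES:
        out[name] = shp[name[len("Shape_"):]]
    return out
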