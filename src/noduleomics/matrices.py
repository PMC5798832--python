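"""Matrix-based texture features.

Gray-level co-occurrence (GLCM), run-length (RLM), size-zone (GLSZM)
and neighborhood gray-tone difference (NGTDM) matrices are built from a
:class:`~noduleomics.volumes.QuantizedPatch`; voxel pairs, runs and
neighborhoods never bridge out-of-mask voxels. Directional statistics
use the 13 unique non-antipodal 3D offsets with components in
{-1, 0, 1} (face, edge and corner neighbors); the GLCM is averaged and
the RLM summed over those directions, following the construction used
for 3D texture analysis of tumor ROIs.

Gray levels enter the feature formulas 1-based (level ``i`` means code
``i - 1``), the common convention for low/high gray-level emphasis
features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import DegenerateRoiError, QuantizedPatch, quantize_array

_EPS = 1e-6

def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if tuple(-c for c in d) in dirs:
                    continue
                dirs.append(d)
    return tuple(dirs)


#: 13 unique non-antipodal neighbor offsets in 3D.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = _unique_directions()
assert len(DIRECTIONS_13) == 13


@dataclass(frozen=True)
class CooccurrenceMatrix:
    probabilities: np.ndarray  # levels x levels, sums to 1, symmetric
    levels: int
    distance: int
    n_directions: int


@dataclass(frozen=True)
class RunLengthMatrix:
    counts: np.ndarray  # levels x max_run, raw run counts over directions
    levels: int
    n_runs: float
    n_voxels: int
    n_directions: int


@dataclass(frozen=True)
class SizeZoneMatrix:
    counts: np.ndarray  # levels x max_zone_size
    levels: int
    n_zones: float
    n_voxels: int


@dataclass(frozen=True)
class NgtdmTable:
    p: np.ndarray  # occurrence probability per level
    s: np.ndarray  # summed |value - neighborhood mean| per level
    levels: int
    n_valid: int


def _shifted_pairs(codes: np.ndarray, d: tuple[int, int, int]):
    """Index slices selecting (voxel, voxel + d) pairs inside the array."""
    src = []
    dst = []
    for c, n in zip(d, codes.shape):
        if c >= 0:
            src.append(slice(0, n - c))
            dst.append(slice(c, n))
        else:
            src.append(slice(-c, n))
            dst.append(slice(0, n + c))
    return codes[tuple(src)], codes[tuple(dst)]


def glcm(q: QuantizedPatch, distance: int = 1,
         directions=DIRECTIONS_13) -> CooccurrenceMatrix:
    """Symmetric co-occurrence probability matrix.

    Pair counts are accumulated over the given offsets (scaled by
    ``distance``), counted in both orders, and normalized to sum to 1.
    Pairs with an out-of-mask member are skipped.
    """
    L = q.levels
    counts = np.zeros((L, L), dtype=np.float64)
    for d in directions:
        off = tuple(distance * c for c in d)
        a, b = _shifted_pairs(q.codes, off)
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        ai = a[ok].ravel()
        bi = b[ok].ravel()
        np.add.at(counts, (ai, bi), 1.0)
        np.add.at(counts, (bi, ai), 1.0)
    total = counts.sum()
    if total == 0:
        raise DegenerateRoiError("degenerate ROI: no valid voxel pair in any direction")
    return CooccurrenceMatrix(counts / total, L, int(distance), len(directions))


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """The canonical 26 co-occurrence features of the registry."""
    P = m.probabilities
    L = m.levels
    lv = np.arange(1, L + 1, dtype=np.float64)  # 1-based gray levels
    i = lv[:, None]
    j = lv[None, :]
    px = P.sum(axis=1)  # symmetric matrix: both marginals coincide
    mu = float((lv * px).sum())
    sig2 = float(((lv - mu) ** 2 * px).sum())
    sig = np.sqrt(sig2)

    diff = np.abs(i - j)
    k_diff = np.arange(0, L, dtype=np.float64)
    p_diff = np.array([P[diff == k].sum() for k in range(L)])
    k_sum = np.arange(2, 2 * L + 1, dtype=np.float64)
    s_idx = (i + j).astype(int)
    p_sum = np.bincount(s_idx.ravel() - 2, weights=P.ravel(), minlength=2 * L - 1)

    def _ent(p):
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())

    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())
    hxy = _ent(P.ravel())
    hx = _ent(px)
    pxj = px[:, None] * px[None, :]
    nzm = (P > 0) & (pxj > 0)
    hxy1 = float(-(P[nzm] * np.log2(pxj[nzm])).sum())
    nz2 = pxj > 0
    hxy2 = float(-(pxj[nz2] * np.log2(pxj[nz2])).sum())

    corr = 1.0 if sig2 == 0 else float(((i - mu) * (j - mu) * P).sum() / sig2)
    imc1 = 0.0 if hx == 0 else (hxy - hxy1) / hx
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    offdiag = diff > 0
    inv_var = float((P[offdiag] / (i - j)[offdiag] ** 2).sum()) if offdiag.any() else 0.0

    return {
        "autocorrelation": float((i * j * P).sum()),
        "joint_average": mu,
        "cluster_prominence": float(((i + j - 2 * mu) ** 4 * P).sum()),
        "cluster_shade": float(((i + j - 2 * mu) ** 3 * P).sum()),
        "cluster_tendency": float(((i + j - 2 * mu) ** 2 * P).sum()),
        "contrast": float(((i - j) ** 2 * P).sum()),
        "correlation": corr,
        "difference_average": da,
        "difference_energy": float((p_diff ** 2).sum()),
        "difference_entropy": _ent(p_diff),
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "dissimilarity": float((diff * P).sum()),
        "energy": float((P ** 2).sum()),
        "entropy": hxy,
        "homogeneity": float((P / (1.0 + diff)).sum()),
        "inverse_difference_moment": float((P / (1.0 + (i - j) ** 2)).sum()),
        "inverse_difference_normalized": float((P / (1.0 + diff / L)).sum()),
        "inverse_difference_moment_normalized": float((P / (1.0 + ((i - j) / L) ** 2)).sum()),
        "inverse_variance": inv_var,
        "imc1": imc1,
        "imc2": imc2,
        "maximum_probability": float(P.max()),
        "sum_average": sa,
        "sum_entropy": _ent(p_sum),
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "joint_variance": float(((i - mu) ** 2 * P).sum()),
    }


def glcm_pair_stats(voxels: np.ndarray, mask: np.ndarray, levels: int = 32):
    """(contrast, homogeneity) of a region re-quantized to ``levels``.

    Degenerate regions without any valid voxel pair return the
    constant-image limits (0, 1).
    """
    codes = quantize_array(voxels, mask, levels)
    q = QuantizedPatch(levels=levels, codes=codes,
                       level_edges=np.linspace(0, 1, levels + 1), spacing=(1, 1, 1))
    try:
        m = glcm(q)
    except DegenerateRoiError:
        return 0.0, 1.0
    P = m.probabilities
    lv = np.arange(1, levels + 1, dtype=np.float64)
    diff = np.abs(lv[:, None] - lv[None, :])
    return float((diff ** 2 * P).sum()), float((P / (1.0 + diff)).sum())


def _runs_in_direction(codes: np.ndarray, valid: np.ndarray, d):
    """Maximal same-code runs along offset ``d``: (levels, lengths)."""
    shp = np.array(codes.shape)
    idx = np.argwhere(valid)
    if idx.size == 0:
        return np.empty(0, int), np.empty(0, int)
    dv = np.array(d)

    def _lookup_ok(pos):
        inside = np.all((pos >= 0) & (pos < shp), axis=1)
        out = np.zeros(len(pos), bool)
        if inside.any():
            pi = pos[inside]
            out[inside] = valid[pi[:, 0], pi[:, 1], pi[:, 2]]
        return out

    prev = idx - dv
    prev_ok = _lookup_ok(prev)
    same_prev = np.zeros(len(idx), bool)
    if prev_ok.any():
        pp = prev[prev_ok]
        same_prev[prev_ok] = (
            codes[pp[:, 0], pp[:, 1], pp[:, 2]]
            == codes[idx[prev_ok, 0], idx[prev_ok, 1], idx[prev_ok, 2]]
        )
    starts = idx[~same_prev]
    start_codes = codes[starts[:, 0], starts[:, 1], starts[:, 2]]
    lengths = np.ones(len(starts), dtype=int)
    pos = starts.copy()
    alive = np.ones(len(starts), bool)
    while alive.any():
        nxt = pos + dv
        cont = np.zeros(len(starts), bool)
        cand = alive.copy()
        cand[cand] = _lookup_ok(nxt[cand])
        if cand.any():
            np_ = nxt[cand]
            cont[cand] = codes[np_[:, 0], np_[:, 1], np_[:, 2]] == start_codes[cand]
        lengths[cont] += 1
        pos[cont] = nxt[cont]
        alive = cont
    return start_codes, lengths


def rlm(q: QuantizedPatch, directions=DIRECTIONS_13) -> RunLengthMatrix:
    """L x R run-length matrix, runs summed over the 13 directions."""
    all_codes = []
    all_lengths = []
    valid = q.mask
    for d in directions:
        c, ln = _runs_in_direction(q.codes, valid, d)
        all_codes.append(c)
        all_lengths.append(ln)
    codes = np.concatenate(all_codes)
    lengths = np.concatenate(all_lengths)
    rmax = int(lengths.max()) if lengths.size else 1
    counts = np.zeros((q.levels, rmax), dtype=np.float64)
    np.add.at(counts, (codes, lengths - 1), 1.0)
    return RunLengthMatrix(counts, q.levels, float(counts.sum()),
                           q.n_voxels, len(directions))


def rlm_features(m: RunLengthMatrix) -> dict[str, float]:
    """Run-length features (Galloway + gray-level-emphasis extensions)."""
    N = m.counts
    nr = m.n_runs
    lv = np.arange(1, m.levels + 1, dtype=np.float64)[:, None]
    rl = np.arange(1, N.shape[1] + 1, dtype=np.float64)[None, :]
    return {
        "SRE": float((N / rl ** 2).sum() / nr),
        "LRE": float((N * rl ** 2).sum() / nr),
        "GLN": float((N.sum(axis=1) ** 2).sum() / nr),
        "RLN": float((N.sum(axis=0) ** 2).sum() / nr),
        "RP": float(nr / (m.n_voxels * m.n_directions)),
        "LGRE": float((N / lv ** 2).sum() / nr),
        "HGRE": float((N * lv ** 2).sum() / nr),
        "SRLGE": float((N / (lv ** 2 * rl ** 2)).sum() / nr),
        "SRHGE": float((N * lv ** 2 / rl ** 2).sum() / nr),
        "LRLGE": float((N * rl ** 2 / lv ** 2).sum() / nr),
        "LRHGE": float((N * (lv * rl) ** 2).sum() / nr),
    }


def glszm(q: QuantizedPatch) -> SizeZoneMatrix:
    """Gray-level size-zone matrix: 26-connected zones of equal code."""
    structure = np.ones((3, 3, 3), dtype=int)
    zmax = 1
    zones = []  # (level, size)
    for lvl in np.unique(q.codes[q.mask]):
        lab, n = ndimage.label(q.codes == lvl, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zmax = max(zmax, int(sizes.max()))
        zones.append((int(lvl), sizes))
    counts = np.zeros((q.levels, zmax), dtype=np.float64)
    for lvl, sizes in zones:
        np.add.at(counts, (lvl, sizes - 1), 1.0)
    return SizeZoneMatrix(counts, q.levels, float(counts.sum()), q.n_voxels)


def glszm_features(m: SizeZoneMatrix) -> dict[str, float]:
    """Size-zone analogues of the 11 run-length features."""
    N = m.counts
    nz = m.n_zones
    lv = np.arange(1, m.levels + 1, dtype=np.float64)[:, None]
    zs = np.arange(1, N.shape[1] + 1, dtype=np.float64)[None, :]
    return {
        "SZE": float((N / zs ** 2).sum() / nz),
        "LZE": float((N * zs ** 2).sum() / nz),
        "GLN": float((N.sum(axis=1) ** 2).sum() / nz),
        "ZSN": float((N.sum(axis=0) ** 2).sum() / nz),
        "ZP": float(nz / m.n_voxels),
        "LGZE": float((N / lv ** 2).sum() / nz),
        "HGZE": float((N * lv ** 2).sum() / nz),
        "SZLGE": float((N / (lv ** 2 * zs ** 2)).sum() / nz),
        "SZHGE": float((N * lv ** 2 / zs ** 2).sum() / nz),
        "LZLGE": float((N * zs ** 2 / lv ** 2).sum() / nz),
        "LZHGE": float((N * (lv * zs) ** 2).sum() / nz),
    }


def ngtdm(q: QuantizedPatch) -> NgtdmTable:
    """Per-level occurrence probabilities and neighborhood deviations.

    The neighborhood is the 26-neighborhood restricted to in-mask
    voxels; voxels without any in-mask neighbor are excluded.
    """
    kernel = np.ones((3, 3, 3), dtype=np.float64)
    kernel[1, 1, 1] = 0.0
    valid = q.mask
    vals = np.where(valid, q.codes, 0).astype(np.float64)
    nsum = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    ncnt = ndimage.convolve(valid.astype(np.float64), kernel, mode="constant", cval=0.0)
    use = valid & (ncnt > 0.5)
    n_valid = int(use.sum())
    p = np.zeros(q.levels)
    s = np.zeros(q.levels)
    if n_valid:
        amean = nsum[use] / ncnt[use]
        dev = np.abs(q.codes[use] - amean)
        cd = q.codes[use]
        np.add.at(s, cd, dev)
        cnts = np.bincount(cd, minlength=q.levels).astype(np.float64)
        p = cnts / n_valid
    return NgtdmTable(p, s, q.levels, n_valid)


def ngtdm_features(t: NgtdmTable) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength."""
    p = t.p
    s = t.s
    n = t.n_valid
    lv = np.arange(1, t.levels + 1, dtype=np.float64)  # 1-based gray tones
    present = p > 0
    ng = int(present.sum())
    ps = float((p * s).sum())
    coarseness = min(1.0 / max(ps, _EPS), 1.0 / _EPS)
    if ng <= 1 or n == 0:
        contrast = 0.0
    else:
        pi = p[present][:, None]
        pj = p[present][None, :]
        li = lv[present][:, None]
        lj = lv[present][None, :]
        contrast = float((pi * pj * (li - lj) ** 2).sum() / (ng * (ng - 1))) * float(
            s.sum() / n
        )
    if ng == 0 or n == 0:
        return {"coarseness": coarseness, "contrast": 0.0, "busyness": 0.0,
                "complexity": 0.0, "strength": 0.0}
    li = lv[present][:, None]
    lj = lv[present][None, :]
    pi = p[present][:, None]
    pj = p[present][None, :]
    si = s[present][:, None]
    sj = s[present][None, :]
    denom_b = float(np.abs(li * pi - lj * pj).sum())
    busyness = ps / denom_b if denom_b > 0 else 0.0
    complexity = float((np.abs(li - lj) * (pi * si + pj * sj) / (n * (pi + pj))).sum())
    strength_num = float(((pi + pj) * (li - lj) ** 2).sum())
    strength = strength_num / max(float(s.sum()), _EPS)
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def box_count(binary: np.ndarray, size: int) -> int:
    """Number of ``size``-cubed boxes containing at least one set voxel."""
    arr = np.asarray(binary, dtype=bool)
    pad = [(0, (-n) % size) for n in arr.shape]
    arr = np.pad(arr, pad, mode="constant", constant_values=False)
    a, b, c = (n // size for n in arr.shape)
    view = arr.reshape(a, size, b, size, c, size)
    return int(view.any(axis=(1, 3, 5)).sum())


def fractal_features(patch, fractions=tuple(f / 100 for f in range(10, 90, 10)),
                     box_sizes=(2, 4, 8, 16)) -> dict[str, float]:
    """Box-counting fractal dimension at 8 intensity thresholds.

    For each fraction ``f`` the in-mask voxels at or above
    ``min + f * range`` form a binary set whose box-counting dimension
    is the least-squares slope of log N(eps) vs log(1/eps) over box
    sizes clipped to the patch extent. An empty set has dimension 0 by
    convention.
    """
    vox = patch.voxels
    mask = patch.mask
    # box sizes need at least a 4-voxel extent to give two fit points
    grow = [(0, max(0, 4 - n)) for n in mask.shape]
    if any(g[1] for g in grow):
        vox = np.pad(vox, grow, mode="edge")
        mask = np.pad(mask, grow, mode="constant", constant_values=False)
    vals = vox[mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    rng = vmax - vmin
    sizes = [s for s in box_sizes if s <= max(mask.shape)]
    out = {}
    for f in fractions:
        thr = vmin + f * rng
        sel = mask & (vox >= thr)
        name = f"FD{int(round(f * 100))}"
        if not sel.any():
            out[name] = 0.0
            continue
        ns = np.array([box_count(sel, s) for s in sizes], dtype=np.float64)
        x = np.log(1.0 / np.array(sizes, dtype=np.float64))
        y = np.log(ns)
        out[name] = float(np.polyfit(x, y, 1)[0])
    return out
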