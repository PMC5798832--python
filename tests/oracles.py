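"""Independent brute-force oracles used by the tests.

Everything here is deliberately slow and literal (triple loops, flood
fills, explicit paddings) and shares no code path with the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np

DIRS_13 = []
for _dx in (-1, 0, 1):
    for _dy in (-1, 0, 1):
        for _dz in (-1, 0, 1):
            d = (_dx, _dy, _dz)
            if d != (0, 0, 0) and tuple(-c for c in d) not in DIRS_13:
                DIRS_13.append(d)
assert len(DIRS_13) == 13


def glcm_counts(codes: np.ndarray, levels: int, distance: int = 1,
                directions=None) -> np.ndarray:
    """Symmetric pair counting by explicit enumeration."""
    dirs = DIRS_13 if directions is None else directions
    counts = np.zeros((levels, levels))
    nx, ny, nz = codes.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = codes[x, y, z]
                if a < 0:
                    continue
                for dx, dy, dz in dirs:
                    u, v, w = x + distance * dx, y + distance * dy, z + distance * dz
                    if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz):
                        continue
                    b = codes[u, v, w]
                    if b < 0:
                        continue
                    counts[a, b] += 1
                    counts[b, a] += 1
    return counts


def rlm_counts(codes: np.ndarray, levels: int) -> np.ndarray:
    """Maximal-run enumeration: walk every line in every direction."""
    nx, ny, nz = codes.shape
    runs = []  # (level, length)
    for d in DIRS_13:
        dx, dy, dz = d
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    a = codes[x, y, z]
                    if a < 0:
                        continue
                    # only start a run if the previous voxel doesn't continue it
                    px, py, pz = x - dx, y - dy, z - dz
                    if (0 <= px < nx and 0 <= py < ny and 0 <= pz < nz
                            and codes[px, py, pz] == a):
                        continue
                    length = 1
                    u, v, w = x + dx, y + dy, z + dz
                    while (0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                           and codes[u, v, w] == a):
                        length += 1
                        u, v, w = u + dx, v + dy, w + dz
                    runs.append((a, length))
    rmax = max(l for _, l in runs)
    counts = np.zeros((levels, rmax))
    for a, l in runs:
        counts[a, l - 1] += 1
    return counts


def glszm_counts(codes: np.ndarray, levels: int) -> np.ndarray:
    """26-connected zones by explicit flood fill."""
    nx, ny, nz = codes.shape
    seen = np.zeros(codes.shape, dtype=bool)
    zones = []  # (level, size)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if seen[x, y, z] or codes[x, y, z] < 0:
                    continue
                lvl = codes[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                u, v, w = cx + dx, cy + dy, cz + dz
                                if (0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                                        and not seen[u, v, w]
                                        and codes[u, v, w] == lvl):
                                    seen[u, v, w] = True
                                    stack.append((u, v, w))
                zones.append((lvl, size))
    zmax = max(s for _, s in zones)
    counts = np.zeros((levels, zmax))
    for lvl, s in zones:
        counts[lvl, s - 1] += 1
    return counts


def ngtdm_table(codes: np.ndarray, levels: int):
    """Per-level (p, s) by explicit 26-neighborhood means."""
    nx, ny, nz = codes.shape
    s = np.zeros(levels)
    cnt = np.zeros(levels)
    n_valid = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = codes[x, y, z]
                if a < 0:
                    continue
                neigh = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            u, v, w = x + dx, y + dy, z + dz
                            if (0 <= u < nx and 0 <= v < ny and 0 <= w < nz
                                    and codes[u, v, w] >= 0):
                                neigh.append(codes[u, v, w])
                if not neigh:
                    continue
                n_valid += 1
                cnt[a] += 1
                s[a] += abs(a - float(np.mean(neigh)))
    p = cnt / n_valid if n_valid else cnt
    return p, s, n_valid


def conv3d_symmetric(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True 3D convolution over symmetric (mirror) padding, by loops."""
    rad = [k // 2 for k in kernel.shape]
    padded = np.pad(data, [(r, r) for r in rad], mode="symmetric")
    flipped = kernel[::-1, ::-1, ::-1]
    out = np.zeros_like(data, dtype=np.float64)
    nx, ny, nz = data.shape
    kx, ky, kz = kernel.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                out[x, y, z] = float(
                    (flipped * padded[x:x + kx, y:y + ky, z:z + kz]).sum()
                )
    return out


def laws_kernel_3d(kernel_id: str) -> np.ndarray:
    one_d = {
        "L": np.array([1.0, 2.0, 1.0]),
        "E": np.array([-1.0, 0.0, 1.0]),
        "S": np.array([-1.0, 2.0, -1.0]),
    }
    a, b, c = (one_d[ch] for ch in kernel_id)
    return a[:, None, None] * b[None, :, None] * c[None, None, :]


def quantize_codes(values: np.ndarray, levels: int) -> np.ndarray:
    """Per-value equal-width binning by direct floor arithmetic."""
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.zeros(values.shape, dtype=int)
    out = np.empty(values.shape, dtype=int)
    width = (vmax - vmin) / levels
    flat = values.ravel()
    res = []
    for v in flat:
        c = int((v - vmin) // width)
        res.append(min(c, levels - 1))
    out = np.array(res).reshape(values.shape)
    return out


def greedy_sfs(eval_accuracy, candidates, k):
    """Reference greedy forward selection re-evaluating the frontier."""
    selected = []
    remaining = list(candidates)
    while len(selected) < k:
        scores = [eval_accuracy(selected + [f]) for f in remaining]
        best = int(np.argmax(scores))  # first max: ties to smaller index
        selected.append(remaining.pop(best))
    return selected
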