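"""Filter banks: Laws 3D texture-energy kernels, one-level wavelet
subbands and multi-scale Laplacian-of-Gaussian.

Each filter response is summarized in-mask by the shared 16-statistic
set, producing 432 Laws, 128 wavelet and 96 LoG features.

Laws kernels are the separable length-3 family: L3 = (1, 2, 1) (local
level), E3 = (-1, 0, 1) (edge) and S3 = (-1, 2, -1) (spot). A 3D
kernel id such as ``LSL`` applies L3 along x, S3 along y and L3 along
z by outer product. E3 and S3 sum to zero, so any id containing them
annihilates constant regions — the bank responds only to micro-
structure (spots and edges), which is exactly the within-nodule
heterogeneity the classifier feeds on.

Boundary handling is symmetric (mirror) padding everywhere, and
out-of-mask voxels are replaced by their nearest in-mask value before
any convolution so background air never contaminates the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .intensity import stat_set
from .registry import LAWS_IDS, LOG_SIGMAS_MM, STAT_NAMES, WAVELET_BANDS, _sigma_tag
from .volumes import ParameterError, RoiPatch, fill_out_of_mask

LAWS_1D: dict[str, np.ndarray] = {
    "L": np.array([1.0, 2.0, 1.0]),
    "E": np.array([-1.0, 0.0, 1.0]),
    "S": np.array([-1.0, 2.0, -1.0]),
}


@dataclass(frozen=True)
class FilterResponse:
    """A filtered image sharing the geometry of its source patch."""

    filter_id: str
    response: np.ndarray


def laws_filter(patch: RoiPatch, kernel_id: str) -> FilterResponse:
    """Separable 3D Laws convolution, one 1D kernel per axis in id order."""
    if len(kernel_id) != 3 or any(ch not in LAWS_1D for ch in kernel_id):
        raise ParameterError(f"unknown Laws kernel id {kernel_id!r}")
    data = fill_out_of_mask(patch.voxels, patch.mask, patch.spacing)
    for axis, letter in enumerate(kernel_id):
        data = ndimage.convolve1d(data, LAWS_1D[letter], axis=axis, mode="reflect")
    return FilterResponse(f"Laws_{kernel_id}", data)


def laws_block(patch: RoiPatch, bins: int = 64) -> dict[str, float]:
    """432 features: StatSet16 of each of the 27 Laws responses."""
    out = {}
    for kid in LAWS_IDS:
        resp = laws_filter(patch, kid).response
        stats = stat_set(resp, patch.mask, bins=bins)
        for name in STAT_NAMES:
            out[f"Laws_{kid}_{name}"] = stats[name]
    return out


def wavelet_subbands(patch: RoiPatch, wavelet: str = "haar") -> list[FilterResponse]:
    """One-level 3D discrete wavelet decomposition into 8 subbands.

    Subbands are named by per-axis low/high (``LLL`` .. ``HHH``) and
    mapped back to the patch geometry (coefficients repeated 2x per
    axis, cropped) so the nodule mask applies directly.
    """
    import pywt

    data = fill_out_of_mask(patch.voxels, patch.mask, patch.spacing)
    orig_shape = data.shape
    # the transform needs at least 2 samples per axis
    grow = [(0, max(0, 2 - n)) for n in data.shape]
    if any(g[1] for g in grow):
        data = np.pad(data, grow, mode="symmetric")
    coeffs = pywt.dwtn(data, wavelet, mode="symmetric")
    responses = []
    for band in WAVELET_BANDS:
        key = "".join("a" if ch == "L" else "d" for ch in band)
        arr = coeffs[key]
        for axis in range(3):
            arr = np.repeat(arr, 2, axis=axis)
        arr = arr[: orig_shape[0], : orig_shape[1], : orig_shape[2]]
        responses.append(FilterResponse(f"Wav_{band}", arr))
    return responses


def wavelet_block(patch: RoiPatch, wavelet: str = "haar", bins: int = 64) -> dict[str, float]:
    """128 features: StatSet16 of each of the 8 subbands."""
    out = {}
    for resp in wavelet_subbands(patch, wavelet):
        stats = stat_set(resp.response, patch.mask, bins=bins)
        band = resp.filter_id[len("Wav_"):]
        for name in STAT_NAMES:
            out[f"Wav_{band}_{name}"] = stats[name]
    return out


def log_kernel(sigma_voxels: np.ndarray) -> np.ndarray:
    """Sampled anisotropic Laplacian-of-Gaussian kernel.

    The Gaussian factor is normalized to unit sum and the kernel is
    shifted to exactly zero mean, so affine images map to (numerically)
    zero response.
    """
    radii = [max(1, int(np.ceil(4.0 * s))) for s in sigma_voxels]
    axes = [np.arange(-r, r + 1, dtype=np.float64) for r in radii]
    gs = [np.exp(-(x ** 2) / (2.0 * s ** 2)) for x, s in zip(axes, sigma_voxels)]
    g3 = gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
    g3 /= g3.sum()
    lap = np.zeros_like(g3)
    for ax, (x, s) in enumerate(zip(axes, sigma_voxels)):
        shape = [1, 1, 1]
        shape[ax] = -1
        lap = lap + ((x ** 2 - s ** 2) / s ** 4).reshape(shape)
    kernel = g3 * lap
    kernel -= kernel.sum() / kernel.size
    return kernel


def log_filter(patch: RoiPatch, sigma_mm: float) -> FilterResponse:
    """Laplacian-of-Gaussian response at physical scale ``sigma_mm``.

    Sigma is converted to voxels per axis through the spacing; the
    convolution runs over symmetric padding via FFT.
    """
    if sigma_mm <= 0:
        raise ParameterError(f"sigma_mm must be positive, got {sigma_mm}")
    sp = np.asarray(patch.spacing)
    sigma_vox = sigma_mm / sp
    if np.all(4.0 * sigma_vox < 1.0):
        raise ParameterError(
            f"sigma {sigma_mm} mm has sub-voxel support on every axis "
            f"at spacing {patch.spacing}"
        )
    kernel = log_kernel(sigma_vox)
    data = fill_out_of_mask(patch.voxels, patch.mask, patch.spacing)
    pads = [(k // 2, k // 2) for k in kernel.shape]
    padded = np.pad(data, pads, mode="symmetric")
    resp = fftconvolve(padded, kernel, mode="valid")
    return FilterResponse(f"LoG_s{_sigma_tag(sigma_mm)}", resp)


def log_block(patch: RoiPatch, sigmas=LOG_SIGMAS_MM, bins: int = 64) -> dict[str, float]:
    """96 features: StatSet16 of the LoG response at each scale."""
    out = {}
    for s in sigmas:
        resp = log_filter(patch, s).response
        stats = stat_set(resp, patch.mask, bins=bins)
        for name in STAT_NAMES:
            out[f"LoG_s{_sigma_tag(s)}_{name}"] = stats[name]
    return out
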