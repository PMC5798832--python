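"""Registry of the 750 extracted features.

Every feature the extractor emits has a stable, documented name. Names
are assembled from category prefixes and the shared 16-statistic
summary, in a fixed order:

=====================  =====  =======================================
category               count  names
=====================  =====  =======================================
intensity & shape         33  ``Intensity_<stat>`` (16), ``IVH_I10..I90``
                              and ``IVH_V10..V90`` (10), ``Shape_*`` (7)
LoG                       96  ``LoG_s<sigma>_<stat>`` for 6 scales
wavelet                  128  ``Wav_<band>_<stat>`` for 8 subbands
Laws                     432  ``Laws_<id>_<stat>`` for 27 kernel ids
co-occurrence             26  ``GLCM_<name>``
run-length                11  ``RLM_<name>``
size-zone                 11  ``GLSZM_<name>``
NGTDM                      5  ``NGTDM_<name>``
fractal dimension          8  ``Fractal_FD10..FD80``
=====================  =====  =======================================

Total: 750. The registry is generated programmatically so the name
list, the extractor and the documentation cannot drift apart; use
:func:`write_registry` (or ``noduleomics registry``) to export it.
"""

from __future__ import annotations

from itertools import product

import pandas as pd

#: The 16 summary statistics applied to the raw ROI and to every
#: filtered response. ``contrast``/``lcl_homo`` are GLCM contrast and
#: homogeneity of the response re-quantized to 32 levels.
STAT_NAMES: tuple[str, ...] = (
    "min", "max", "median", "peak", "mean", "sd", "cv", "rms",
    "skewness", "kurtosis", "energy", "entropy", "uniformity", "range",
    "contrast", "lcl_homo",
)

#: 27 Laws kernel ids: triples over L (level), E (edge), S (spot).
LAWS_IDS: tuple[str, ...] = tuple("".join(t) for t in product("LES", repeat=3))

#: 8 one-level 3D wavelet subbands, low/high per axis.
WAVELET_BANDS: tuple[str, ...] = tuple("".join(t) for t in product("LH", repeat=3))

#: Laplacian-of-Gaussian scales in mm (fine to coarse texture).
LOG_SIGMAS_MM: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)

#: Intensity-volume-histogram grid (percent).
IVH_PERCENTS: tuple[int, ...] = (10, 30, 50, 70, 90)

IVH_NAMES: tuple[str, ...] = tuple(f"IVH_I{p}" for p in IVH_PERCENTS) + tuple(
    f"IVH_V{p}" for p in IVH_PERCENTS
)

SHAPE_NAMES: tuple[str, ...] = (
    "Shape_volume", "Shape_surface_area", "Shape_surface_to_volume",
    "Shape_sphericity", "Shape_compactness1", "Shape_compactness2",
    "Shape_max_diameter",
)

GLCM_FEATURES: tuple[str, ...] = (
    "autocorrelation", "joint_average", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_energy", "difference_entropy", "difference_variance",
    "dissimilarity", "energy", "entropy", "homogeneity",
    "inverse_difference_moment", "inverse_difference_normalized",
    "inverse_difference_moment_normalized", "inverse_variance",
    "imc1", "imc2", "maximum_probability", "sum_average", "sum_entropy",
    "sum_variance", "joint_variance",
)

RLM_FEATURES: tuple[str, ...] = (
    "SRE", "LRE", "GLN", "RLN", "RP",
    "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
)

GLSZM_FEATURES: tuple[str, ...] = (
    "SZE", "LZE", "GLN", "ZSN", "ZP",
    "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE",
)

NGTDM_FEATURES: tuple[str, ...] = (
    "coarseness", "contrast", "busyness", "complexity", "strength",
)

FRACTAL_NAMES: tuple[str, ...] = tuple(f"Fractal_FD{p}" for p in range(10, 90, 10))


def _sigma_tag(sigma: float) -> str:
    return f"{sigma:g}".replace(".", "p")


def intensity_shape_names() -> list[str]:
    return (
        [f"Intensity_{s}" for s in STAT_NAMES]
        + list(IVH_NAMES)
        + list(SHAPE_NAMES)
    )


def log_names(sigmas=LOG_SIGMAS_MM) -> list[str]:
    return [f"LoG_s{_sigma_tag(s)}_{stat}" for s in sigmas for stat in STAT_NAMES]


def wavelet_names() -> list[str]:
    return [f"Wav_{b}_{stat}" for b in WAVELET_BANDS for stat in STAT_NAMES]


def laws_names() -> list[str]:
    return [f"Laws_{k}_{stat}" for k in LAWS_IDS for stat in STAT_NAMES]


def matrix_names() -> list[str]:
    return (
        [f"GLCM_{n}" for n in GLCM_FEATURES]
        + [f"RLM_{n}" for n in RLM_FEATURES]
        + [f"GLSZM_{n}" for n in GLSZM_FEATURES]
        + [f"NGTDM_{n}" for n in NGTDM_FEATURES]
        + list(FRACTAL_NAMES)
    )


def feature_names() -> list[str]:
    """All 750 feature names in extraction order."""
    return (
        intensity_shape_names()
        + log_names()
        + wavelet_names()
        + laws_names()
        + matrix_names()
    )


def category_totals() -> dict[str, int]:
    return {
        "intensity_shape": len(intensity_shape_names()),
        "log": len(log_names()),
        "wavelet": len(wavelet_names()),
        "laws": len(laws_names()),
        "glcm": len(GLCM_FEATURES),
        "rlm": len(RLM_FEATURES),
        "glszm": len(GLSZM_FEATURES),
        "ngtdm": len(NGTDM_FEATURES),
        "fractal": len(FRACTAL_NAMES),
    }


def category_of(name: str) -> str:
    prefix = name.split("_", 1)[0]
    return {
        "Intensity": "intensity_shape", "IVH": "intensity_shape",
        "Shape": "intensity_shape", "LoG": "log", "Wav": "wavelet",
        "Laws": "laws", "GLCM": "glcm", "RLM": "rlm", "GLSZM": "glszm",
        "NGTDM": "ngtdm", "Fractal": "fractal",
    }[prefix]


_STAT_DEFS = {
    "min": "minimum in-mask value",
    "max": "maximum in-mask value",
    "median": "median in-mask value",
    "peak": "mode of the 64-bin histogram (bin center)",
    "mean": "arithmetic mean",
    "sd": "population standard deviation",
    "cv": "coefficient of variation sd/mean (0 if mean = 0)",
    "rms": "root mean square",
    "skewness": "sample skewness (0 if sd = 0)",
    "kurtosis": "excess kurtosis (0 if sd = 0)",
    "energy": "sum of squared values",
    "entropy": "Shannon entropy of the 64-bin histogram, bits",
    "uniformity": "sum of squared 64-bin histogram probabilities",
    "range": "max - min",
    "contrast": "GLCM contrast of the region re-quantized to 32 levels",
    "lcl_homo": "GLCM homogeneity of the region re-quantized to 32 levels",
}


def _definition(name: str) -> str:
    cat = category_of(name)
    if cat == "intensity_shape":
        if name.startswith("Intensity_"):
            return f"raw-intensity statistic: {_STAT_DEFS[name[len('Intensity_'):]]}"
        if name.startswith("IVH_I"):
            p = name[len("IVH_I"):]
            return (f"largest intensity covering >= {p}% of the ROI volume "
                    "at or above it")
        if name.startswith("IVH_V"):
            p = name[len("IVH_V"):]
            return (f"ROI volume fraction at or above min + {p}% of the "
                    "intensity range")
        return {
            "Shape_volume": "mask voxel count x voxel volume, mm^3",
            "Shape_surface_area": "marching-cubes mesh surface area, mm^2",
            "Shape_surface_to_volume": "surface area / volume, 1/mm",
            "Shape_sphericity": "pi^(1/3) (6V)^(2/3) / A",
            "Shape_compactness1": "V / (sqrt(pi) A^(3/2))",
            "Shape_compactness2": "36 pi V^2 / A^3 (= sphericity^3)",
            "Shape_max_diameter": "largest pairwise distance between mask voxel corners, mm",
        }[name]
    if cat == "log":
        _, sig, stat = name.split("_", 2)
        sigma = sig[1:].replace("p", ".")
        return (f"{_STAT_DEFS[stat]} of the Laplacian-of-Gaussian response, "
                f"sigma = {sigma} mm")
    if cat == "wavelet":
        _, band, stat = name.split("_", 2)
        return (f"{_STAT_DEFS[stat]} of the one-level 3D wavelet subband "
                f"{band} (L = low-pass, H = high-pass per axis)")
    if cat == "laws":
        _, kid, stat = name.split("_", 2)
        return (f"{_STAT_DEFS[stat]} of the Laws {kid} 3D texture response "
                "(L = level, E = edge, S = spot 1D kernels)")
    if cat == "glcm":
        return ("co-occurrence feature from the 13-direction averaged "
                "gray-level co-occurrence matrix")
    if cat == "rlm":
        return "run-length feature from the 13-direction summed run-length matrix"
    if cat == "glszm":
        return "size-zone feature from the 26-connected gray-level size-zone matrix"
    if cat == "ngtdm":
        return "neighborhood gray-tone difference feature (26-neighborhood)"
    pct = name[len("Fractal_FD"):]
    return (f"box-counting fractal dimension of the set thresholded at "
            f"min + {pct}% of the intensity range")


def registry_frame() -> pd.DataFrame:
    """The full registry as a DataFrame (name, category, definition)."""
    names = feature_names()
    return pd.DataFrame(
        {
            "name": names,
            "category": [category_of(n) for n in names],
            "definition": [_definition(n) for n in names],
        }
    )


def write_registry(path) -> None:
    """Export the machine-readable registry as CSV."""
    registry_frame().to_csv(path, index=False)
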