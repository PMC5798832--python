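"""Assembly of the full 750-feature vector and cohort extraction.

Category totals (33 intensity & shape, 96 LoG, 128 wavelet, 432 Laws,
26 GLCM, 11 RLM, 11 GLSZM, 5 NGTDM, 8 fractal) are fixed by the
registry; the assembly refuses to emit a non-finite feature.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import matrices
from .filters import laws_block, log_block, wavelet_block
from .intensity import intensity_shape_block
from .registry import LOG_SIGMAS_MM, feature_names
from .volumes import (RoiPatch, extract_roi, load_mask, quantize,
                      read_manifest, read_volume)

logger = logging.getLogger("noduleomics")


def full_feature_vector(
    patch: RoiPatch,
    *,
    glcm_levels: int = 256,
    rlm_levels: int = 256,
    glszm_levels: int = 64,
    ngtdm_levels: int = 64,
    log_sigmas=LOG_SIGMAS_MM,
    wavelet: str = "haar",
    bins: int = 64,
) -> dict[str, float]:
    """All 750 named features of one ROI patch, in registry order."""
    feats: dict[str, float] = {}
    feats.update(intensity_shape_block(patch, bins=bins))
    feats.update(log_block(patch, sigmas=log_sigmas, bins=bins))
    feats.update(wavelet_block(patch, wavelet=wavelet, bins=bins))
    feats.update(laws_block(patch, bins=bins))
    q_glcm = quantize(patch, glcm_levels)
    for name, val in matrices.glcm_features(matrices.glcm(q_glcm)).items():
        feats[f"GLCM_{name}"] = val
    q_rlm = q_glcm if rlm_levels == glcm_levels else quantize(patch, rlm_levels)
    for name, val in matrices.rlm_features(matrices.rlm(q_rlm)).items():
        feats[f"RLM_{name}"] = val
    q_szm = quantize(patch, glszm_levels)
    for name, val in matrices.glszm_features(matrices.glszm(q_szm)).items():
        feats[f"GLSZM_{name}"] = val
    q_ngt = q_szm if ngtdm_levels == glszm_levels else quantize(patch, ngtdm_levels)
    for name, val in matrices.ngtdm_features(matrices.ngtdm(q_ngt)).items():
        feats[f"NGTDM_{name}"] = val
    for name, val in matrices.fractal_features(patch).items():
        feats[f"Fractal_{name}"] = val

    ordered = feature_names()
    missing = [n for n in ordered if n not in feats]
    if missing:
        raise RuntimeError(f"extractor produced no value for: {missing[:5]} ...")
    out = {n: float(feats[n]) for n in ordered}
    bad = [n for n, v in out.items() if not np.isfinite(v)]
    if bad:
        raise RuntimeError(f"non-finite feature value(s): {bad}")
    return out


def extract_case(image_path, mask_path, **kwargs) -> dict[str, float]:
    """Load one image/mask pair and extract its feature vector."""
    volume = read_volume(image_path)
    mask = load_mask(mask_path)
    patch = extract_roi(volume, mask)
    return full_feature_vector(patch, **kwargs)


def extract_cohort(manifest_path, **kwargs) -> pd.DataFrame:
    """Extract features for every manifest case.

    Returns a DataFrame indexed by case_id with a ``label`` column
    followed by the 750 feature columns in registry order. An
    unreadable case aborts the run (no silent skipping).
    """
    manifest = read_manifest(manifest_path)
    rows = []
    for _, rec in manifest.iterrows():
        t0 = time.perf_counter()
        feats = extract_case(rec["image_path"], rec["mask_path"], **kwargs)
        logger.info("extracted %s (%d features, %.2f s)",
                    rec["case_id"], len(feats), time.perf_counter() - t0)
        rows.append({"case_id": rec["case_id"], "label": rec["label"], **feats})
    df = pd.DataFrame(rows).set_index("case_id")
    return df[["label"] + feature_names()]
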