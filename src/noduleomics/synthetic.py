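"""Synthetic two-class nodule phantoms and micro-fixtures.

The generator emulates the study conditions of a benign/malignant CT
nodule cohort in which the two classes differ in *regional texture
heterogeneity* rather than size or mean intensity: every phantom is an
ellipsoidal soft-tissue nodule carrying a spatially correlated noise
texture, and malignant phantoms additionally receive a coarse blob
component (a handful of smooth intensity bumps at roughly a third of
the nodule diameter) that creates the spot/edge micro-structure the
Laws filter bank detects. Benign phantoms have the blob amplitude set
to zero, so class separation is driven purely by within-nodule
heterogeneity.

Defaults: 1 mm isotropic spacing, 25 mm diameter, base intensity
40 HU, correlated noise with 15 HU standard deviation and 1.5 mm
correlation length, and a 40 HU blob amplitude for the malignant
class. Identical spec + seed always yields a bit-identical phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .registry import feature_names
from .volumes import ImageVolume, ParameterError, write_volume

#: Default signal features planted in synthetic feature tables — the
#: four Laws features a well-run selection should rediscover.
DEFAULT_PLANTED = (
    "Laws_LSL_min", "Laws_SLL_energy", "Laws_SSL_skewness", "Laws_EEL_uniformity",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic nodule."""

    label: str = "benign"
    diameter_mm: float = 25.0
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    base_intensity: float = 40.0
    noise_sd: float = 15.0
    correlation_length_mm: float = 1.5
    heterogeneity_amp: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ParameterError("diameter_mm must be positive")
        if self.noise_sd < 0 or self.heterogeneity_amp < 0:
            raise ParameterError("noise_sd and heterogeneity_amp must be >= 0")


def benign_default(seed: int = 0, **overrides) -> PhantomSpec:
    return replace(PhantomSpec(label="benign", heterogeneity_amp=0.0, seed=seed), **overrides)


def malignant_default(seed: int = 0, **overrides) -> PhantomSpec:
    return replace(PhantomSpec(label="malignant", heterogeneity_amp=40.0, seed=seed), **overrides)


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, np.ndarray]:
    """Generate one ellipsoidal nodule phantom and its binary mask.

    The in-mask intensity model is::

        base + smoothed Gaussian field + amp * coarse blob component

    where the field is white noise convolved with a Gaussian kernel of
    the requested correlation length (rescaled back to ``noise_sd``)
    and the blob component is 3-6 randomly placed smooth bumps of
    random sign at ~1/3 nodule diameter.
    """
    sp = np.asarray(spec.spacing_mm, dtype=np.float64)
    if np.any(sp <= 0):
        raise ParameterError(f"spacing must be positive, got {spec.spacing_mm}")
    if spec.diameter_mm < sp.min():
        raise ParameterError(
            f"diameter {spec.diameter_mm} mm is smaller than one voxel at spacing {tuple(sp)}"
        )
    rng = np.random.default_rng(spec.seed)
    radius = spec.diameter_mm / 2.0
    margin = 3
    shape = tuple(int(np.ceil(spec.diameter_mm / s)) + 2 * margin + 1 for s in sp)
    coords = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, sp)],
        indexing="ij",
    )
    mask = sum((c / radius) ** 2 for c in coords) <= 1.0
    voxels = np.full(shape, float(spec.base_intensity))
    if spec.noise_sd > 0:
        field = rng.standard_normal(shape)
        sigma_vox = spec.correlation_length_mm / sp
        field = gaussian_filter(field, sigma=sigma_vox, mode="reflect")
        std = field.std()
        if std > 0:
            voxels = voxels + field * (spec.noise_sd / std)
    if spec.heterogeneity_amp > 0:
        n_blobs = int(rng.integers(3, 7))
        blob_sigma = spec.diameter_mm / 6.0  # blob FWHM ~ diameter / 3
        blobfield = np.zeros(shape)
        for _ in range(n_blobs):
            # centers uniform in a sphere of 0.7 * radius
            while True:
                c = rng.uniform(-0.7, 0.7, size=3)
                if (c ** 2).sum() <= 0.49:
                    break
            center = c * radius
            sign = 1.0 if rng.random() < 0.5 else -1.0
            d2 = sum(((cc - mu) / blob_sigma) ** 2 for cc, mu in zip(coords, center))
            blobfield += sign * np.exp(-d2 / 2.0)
        voxels = voxels + spec.heterogeneity_amp * blobfield
    return ImageVolume(voxels, tuple(sp)), mask


@dataclass(frozen=True)
class CohortManifest:
    """Rows of (case_id, image_path, mask_path, label) plus class counts."""

    frame: pd.DataFrame
    path: Path

    @property
    def counts(self) -> dict[str, int]:
        return self.frame["label"].value_counts().to_dict()


def generate_cohort(
    n_benign: int,
    n_malignant: int,
    out_dir,
    benign: PhantomSpec | None = None,
    malignant: PhantomSpec | None = None,
    master_seed: int = 0,
    diameter_range_mm: tuple[float, float] | None = (12.0, 30.0),
) -> CohortManifest:
    """Write ``n_benign + n_malignant`` NIfTI image/mask pairs + manifest.

    Per-case phantom seeds are ``master_seed + case_index`` (documented
    and reproducible); nodule diameters are drawn per case from
    ``diameter_range_mm`` by a cohort-level generator seeded with
    ``master_seed``, emulating the size diversity of a clinical cohort.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ParameterError("both class counts must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    benign = benign if benign is not None else benign_default()
    malignant = malignant if malignant is not None else malignant_default()
    size_rng = np.random.default_rng(master_seed)
    rows = []
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    for i, label in enumerate(labels):
        template = benign if label == "benign" else malignant
        diameter = template.diameter_mm
        if diameter_range_mm is not None:
            diameter = float(size_rng.uniform(*diameter_range_mm))
        spec = replace(template, label=label, diameter_mm=diameter,
                       seed=master_seed + i)
        volume, mask = generate_phantom(spec)
        case_id = f"case_{i:04d}_{label}"
        image_path = out_dir / f"{case_id}_image.nii.gz"
        mask_path = out_dir / f"{case_id}_mask.nii.gz"
        write_volume(volume, image_path)
        write_volume(ImageVolume(mask.astype(np.float64), volume.spacing), mask_path)
        rows.append(
            {"case_id": case_id, "image_path": image_path.name,
             "mask_path": mask_path.name, "label": label}
        )
    frame = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.csv"
    frame.to_csv(manifest_path, index=False)
    return CohortManifest(frame, manifest_path)


def fixture_microvolumes() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Tiny fixed (voxels, mask) pairs used as oracle substrates.

    ============  =========  =============================================
    name          shape      content
    ============  =========  =============================================
    constant4     4x4x4      all voxels 5, full mask
    checker221    2x2x1      codes [[0, 1], [1, 0]], full mask
    run331        3x3x1      column x: (2, 2, 2) at y=0, all other codes
                             distinct — exactly one run of length 3
    twoblob441    4x4x1      two disjoint single-code corners on a
                             contrasting background
    deviant333    3x3x3      constant 1 with center voxel 5
    ============  =========  =============================================
    """
    constant4 = np.full((4, 4, 4), 5.0)
    checker = np.array([[0.0, 1.0], [1.0, 0.0]]).reshape(2, 2, 1)
    run = np.array([[2.0, 0.0, 1.0], [2.0, 3.0, 4.0], [2.0, 5.0, 6.0]]).reshape(3, 3, 1)
    twoblob = np.array(
        [[9.0, 9.0, 0.0, 0.0],
         [9.0, 0.0, 0.0, 0.0],
         [0.0, 0.0, 0.0, 9.0],
         [0.0, 0.0, 9.0, 9.0]]
    ).reshape(4, 4, 1)
    deviant = np.full((3, 3, 3), 1.0)
    deviant[1, 1, 1] = 5.0
    out = {}
    for name, vox in [("constant4", constant4), ("checker221", checker),
                      ("run331", run), ("twoblob441", twoblob),
                      ("deviant333", deviant)]:
        out[name] = (vox, np.ones(vox.shape, dtype=bool))
    return out


def planted_feature_table(
    n_benign: int = 20,
    n_malignant: int = 20,
    n_features: int = 750,
    planted: tuple[str, ...] = DEFAULT_PLANTED,
    effect: float = 3.0,
    seed: int = 0,
):
    """A synthetic feature table with known discriminative features.

    All features are iid standard normal across cases; each planted
    feature is shifted by ``effect`` standard deviations in the
    malignant class. With ``effect=0`` or ``planted=()`` the table is
    an exact global null, which is what the screening-calibration
    property tests use. Feature names follow the registry (truncated
    or padded with generic names if ``n_features != 750``).
    """
    from .pipeline import FeatureTable

    rng = np.random.default_rng(seed)
    names = feature_names()
    if n_features <= len(names):
        names = names[:n_features]
    else:
        names = names + [f"f{i:04d}" for i in range(n_features - len(names))]
    # keep planted names present even in truncated tables
    missing = [f for f in planted if f not in names]
    for i, f in enumerate(missing):
        names[-(i + 1)] = f
    if len(set(names)) != len(names):
        raise ParameterError("feature names collide after inserting planted names")
    n = n_benign + n_malignant
    X = rng.standard_normal((n, n_features))
    labels = np.array(["benign"] * n_benign + ["malignant"] * n_malignant)
    for f in planted:
        X[labels == "malignant", names.index(f)] += effect
    case_ids = [f"case_{i:04d}" for i in range(n)]
    Xdf = pd.DataFrame(X, index=case_ids, columns=names)
    y = pd.Series(labels, index=case_ids, name="label")
    return FeatureTable(Xdf, y)
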