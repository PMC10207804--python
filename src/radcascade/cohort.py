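"""Synthetic CT-like cohorts with class-dependent tumor texture and age structure.

Each subject is an ellipsoidal "tumor" on a uniform background: the in-mask
signal is ``base_intensity`` plus a spatially correlated Gaussian random
field (white noise smoothed with an isotropic Gaussian kernel of the class's
correlation length, rescaled to the class's heterogeneity amplitude) plus
independent voxel noise.  Class separability is therefore carried by the
correlation length and the heterogeneity amplitude — exactly the properties
the GLCM correlation/Imc and GLSZM zone-size feature families measure — and
by the age distribution.

Default class composition and ages follow the published cohort this package
models: 14 ganglioneuroma / 24 ganglioneuroblastoma / 65 neuroblastoma,
ages (months, truncated normal at 0) 7.36 +/- 3.77, 4.38 +/- 2.61,
2.38 +/- 2.49, and per-class male fractions 8/14, 13/24, 38/65.  The default
grid spacing equals the pipeline's resampling target (0.5, 0.5, 5 mm).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .features import ExtractionConfig, extract_feature_vector, feature_names
from .volume_io import RoiMask, VolumeGrid, resample_pair

__all__ = ["TextureParams", "CohortSpec", "Subject", "sample_cohort", "cohort_to_feature_table"]


@dataclass(frozen=True)
class TextureParams:
    """In-mask texture parameters for one class.

    correlation_length : Gaussian smoothing sigma (voxels) of the correlated
        component — larger values give smoother, more spatially coherent tumors.
    noise_sd : SD of the independent per-voxel noise (intensity units).
    base_intensity : mean in-mask intensity (HU-like).
    heterogeneity : SD of the correlated component (intensity units).
    """

    correlation_length: float
    noise_sd: float
    base_intensity: float
    heterogeneity: float


# benign -> malignant: increasingly fine-grained and heterogeneous texture
DEFAULT_TEXTURE = OrderedDict(
    [
        ("GN", TextureParams(4.0, 8.0, 45.0, 20.0)),
        ("GNB", TextureParams(2.2, 8.0, 45.0, 32.0)),
        ("NB", TextureParams(1.1, 8.0, 45.0, 45.0)),
    ]
)

DEFAULT_AGES = OrderedDict(
    [("GN", (7.36, 3.77)), ("GNB", (4.38, 2.61)), ("NB", (2.38, 2.49))]
)

DEFAULT_GENDER_P = OrderedDict([("GN", 8 / 14), ("GNB", 13 / 24), ("NB", 38 / 65)])


@dataclass
class CohortSpec:
    """Generator settings; defaults reproduce the modeled study's cohort."""

    n_per_class: tuple[int, int, int] = (14, 24, 65)  # (GN, GNB, NB)
    age_params: dict = field(default_factory=lambda: dict(DEFAULT_AGES))
    gender_p: dict = field(default_factory=lambda: dict(DEFAULT_GENDER_P))
    texture_params: dict = field(default_factory=lambda: dict(DEFAULT_TEXTURE))
    tumor_axes: tuple[float, float] = (5.0, 11.0)  # semi-axis range, voxels
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (0.5, 0.5, 5.0)
    background_intensity: float = -40.0
    background_noise_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if any(n < 2 for n in self.n_per_class):
            raise ValueError("each class needs at least 2 subjects")
        if self.tumor_axes[0] < 2:
            raise ValueError("tumor semi-axes must be >= 2 voxels")
        for mu, sd in self.age_params.values():
            if sd < 0:
                raise ValueError("age SD must be non-negative")

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["texture_params"] = {k: asdict(v) for k, v in self.texture_params.items()}
        return d


@dataclass
class Subject:
    subject_id: str
    volume: VolumeGrid
    mask: RoiMask
    age: float
    gender: int  # female = 0, male = 1
    label: str


def _ellipsoid_mask(shape, center, axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return acc <= 1.0


def _sample_subject(
    rng: np.random.Generator, spec: CohortSpec, label: str, subject_id: str
) -> Subject:
    shape = spec.grid_shape
    lo, hi = spec.tumor_axes
    for _ in range(100):
        axes = rng.uniform(lo, hi, size=3)
        margins = np.ceil(axes).astype(int) + 1
        if all(shape[i] - 2 * margins[i] > 0 for i in range(3)):
            center = [rng.uniform(m, shape[i] - m) for i, m in enumerate(margins)]
            break
    else:
        raise ValueError(
            f"could not place an ellipsoid with axes in {spec.tumor_axes} "
            f"inside grid {shape} after 100 attempts"
        )
    mask = _ellipsoid_mask(shape, center, axes)

    tp: TextureParams = spec.texture_params[label]
    white = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(white, sigma=tp.correlation_length, mode="reflect")
    # scale so the *in-mask* SD of the correlated component equals the class's
    # heterogeneity amplitude; otherwise long correlation lengths leave almost
    # no variance inside a small tumor and voxel noise swamps the texture signal
    sd = smooth[mask].std()
    field_arr = smooth / sd * tp.heterogeneity if sd > 0 else np.zeros(shape)

    data = (
        spec.background_intensity
        + rng.normal(0.0, spec.background_noise_sd, size=shape)
    )
    data[mask] = (
        tp.base_intensity
        + field_arr[mask]
        + rng.normal(0.0, tp.noise_sd, size=int(mask.sum()))
    )

    mu, sd_age = spec.age_params[label]
    if sd_age > 0:
        a = (0.0 - mu) / sd_age
        age = float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd_age, random_state=rng))
    else:
        age = float(mu)
    gender = int(rng.random() < spec.gender_p[label])

    return Subject(
        subject_id=subject_id,
        volume=VolumeGrid(data=data, spacing=spec.spacing),
        mask=RoiMask(data=mask, spacing=spec.spacing),
        age=age,
        gender=gender,
        label=label,
    )


def sample_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate the full labeled cohort; fully determined by ``spec.seed``."""
    spec.validate()
    labels = ["GN", "GNB", "NB"]
    total = sum(spec.n_per_class)
    seeds = np.random.SeedSequence(spec.seed).spawn(total)
    subjects: list[Subject] = []
    k = 0
    for label, n in zip(labels, spec.n_per_class):
        for i in range(n):
            rng = np.random.default_rng(seeds[k])
            subjects.append(_sample_subject(rng, spec, label, f"{label}_{i:03d}"))
            k += 1
    return subjects


def cohort_to_feature_table(
    cohort: list[Subject],
    config: ExtractionConfig | None = None,
    target_spacing: tuple[float, float, float] = (0.5, 0.5, 5.0),
) -> pd.DataFrame:
    """Resample, extract 851 radiomic features per subject, attach clinical columns."""
    if not cohort:
        raise ValueError("cohort is empty")
    config = config or ExtractionConfig()
    rows = []
    for subj in cohort:
        vol, mask = resample_pair(subj.volume, subj.mask, target_spacing)
        feats = extract_feature_vector(vol, mask, config)
        feats["age"] = subj.age
        feats["gender"] = subj.gender
        feats["label"] = subj.label
        rows.append(pd.Series(feats, name=subj.subject_id))
    table = pd.DataFrame(rows)
    table.index.name = "subject_id"
    expected = feature_names(config)
    return table[expected + ["age", "gender", "label"]]
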