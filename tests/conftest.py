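import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from radcascade.volume_io import DiscretizedRoi, RoiMask, VolumeGrid


def make_roi(levels: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> DiscretizedRoi:
    """Wrap an integer level array (0 = outside mask) as a DiscretizedRoi."""
    levels = np.asarray(levels, dtype=np.int64)
    if levels.ndim == 2:
        levels = levels[:, :, None]
    mask = levels > 0
    return DiscretizedRoi(
        level_array=levels,
        mask=mask,
        n_levels=int(levels.max()) if mask.any() else 0,
        bin_width=1.0,
        spacing=spacing,
    )


def random_roi(rng: np.random.Generator, shape=(6, 6, 3), ng=5, p_mask=0.85):
    """Random small discretized ROI for oracle comparisons (never empty)."""
    while True:
        mask = rng.random(shape) < p_mask
        if mask.any():
            break
    levels = np.where(mask, rng.integers(1, ng + 1, size=shape), 0)
    return make_roi(levels)


def ellipsoid_mask(shape, semi_axes, center=None) -> np.ndarray:
    center = center or tuple((n - 1) / 2.0 for n in shape)
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return acc <= 1.0


def make_label_table(
    rng: np.random.Generator,
    n_per_class=(14, 24, 65),
    n_features: int = 30,
    class_shift: float = 0.0,
) -> pd.DataFrame:
    """Fabricated feature table (no images) for selection/cascade/pipeline tests.

    ``class_shift`` moves the first half of the features by class index, so a
    positive value plants recoverable signal.
    """
    rows, labels = [], []
    for ci, (label, n) in enumerate(zip(("GN", "GNB", "NB"), n_per_class)):
        X = rng.normal(size=(n, n_features))
        X[:, : n_features // 2] += class_shift * ci
        rows.append(X)
        labels += [label] * n
    X = np.vstack(rows)
    table = pd.DataFrame(X, columns=[f"feat_{i:03d}" for i in range(n_features)])
    table["age"] = rng.normal(5, 2, size=len(table)).clip(0.1)
    table["gender"] = rng.integers(0, 2, size=len(table))
    table["label"] = labels
    table.index = [f"S{i:03d}" for i in range(len(table))]
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_volume_pair(rng):
    """Noise volume + centered ellipsoid mask on a small anisotropic grid."""
    shape = (24, 24, 10)
    spacing = (0.5, 0.5, 5.0)
    vol = VolumeGrid(rng.normal(40.0, 25.0, size=shape), spacing=spacing)
    mask = RoiMask(ellipsoid_mask(shape, (8, 8, 3.5)), spacing=spacing)
    return vol, mask
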