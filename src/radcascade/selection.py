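"""Cohort splitting, univariate feature screening, and mRMR ranking.

The screening route follows common radiomics practice for three-group
comparisons: a feature is compared across the three tumor types with one-way
ANOVA when every class passes a Shapiro–Wilk normality check (p > 0.05 in all
three classes), and with the Kruskal–Wallis test otherwise.  Raw p < alpha
(no multiple-testing correction) defines the survivors; the clinical
covariates (age, gender) bypass the screen and enter the ranking pool
directly.

mRMR uses the mutual-information-difference (MID) objective
``I(f; y) - (1/|S|) * sum_{s in S} I(f; s)`` with greedy forward selection.
Continuous features are discretized to 4 equal-frequency bins before mutual
information is computed; class labels are used as-is.  Ties are broken by
candidate name (lexicographic), making the ranking deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLASS_LABELS",
    "CLINICAL_FEATURES",
    "SelectionResult",
    "radiomic_columns",
    "stratified_split",
    "univariate_screen",
    "mrmr_rank",
    "mutual_information",
    "discretize_equal_frequency",
]

CLASS_LABELS = ("GN", "GNB", "NB")
CLINICAL_FEATURES = ("age", "gender")
_META_COLUMNS = {"label", "split", "subject_id"}


def radiomic_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns excluding clinical covariates and metadata."""
    return [
        c
        for c in table.columns
        if c not in _META_COLUMNS and c not in CLINICAL_FEATURES
    ]


@dataclass
class SelectionResult:
    """Output of screening and ranking.

    pvalues : screening p-value per radiomic feature
    survivors : features with p < alpha, in table column order
    ranked : (feature, importance) pairs in selection order; the importance is
        the mRMR objective value at the moment of selection
    """

    pvalues: dict[str, float] = field(default_factory=dict)
    survivors: list[str] = field(default_factory=list)
    ranked: list[tuple[str, float]] = field(default_factory=list)

    def ranked_names(self) -> list[str]:
        return [name for name, _ in self.ranked]


# ---------------------------------------------------------------------------
# Split


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    table: pd.DataFrame, ratio: float = 0.75, seed: int = 0
) -> pd.DataFrame:
    """Assign each subject to 'train' or 'validation', stratified by class.

    Per class, the validation count is round-half-up of ``n * (1 - ratio)``
    (minimum 1 subject unless ``ratio == 1.0``); with the 3:1 default this
    sends round(n/4) subjects per class to validation.  The assignment is a
    deterministic function of ``seed``.
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"train ratio must be in (0, 1], got {ratio}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["split"] = "train"
    for label in CLASS_LABELS:
        idx = out.index[out["label"] == label].to_numpy()
        n = len(idx)
        if n < 2:
            raise ValueError(f"class {label} has {n} subject(s); need >= 2 to stratify")
        if ratio == 1.0:
            continue
        n_val = max(1, _round_half_up(n * (1.0 - ratio)))
        chosen = rng.permutation(idx)[:n_val]
        out.loc[chosen, "split"] = "validation"
    return out


# ---------------------------------------------------------------------------
# Univariate screening


def _screen_pvalue(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 1.0
    normal = True
    for g in groups:
        if len(g) < 3 or np.ptp(g) == 0:
            normal = False
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stats.shapiro(g).pvalue <= 0.05:
                normal = False
                break
    try:
        if normal:
            p = stats.f_oneway(*groups).pvalue
        else:
            p = stats.kruskal(*groups).pvalue
    except ValueError:
        return 1.0
    return 1.0 if np.isnan(p) else float(p)


def univariate_screen(train: pd.DataFrame, alpha: float = 0.05) -> SelectionResult:
    """Screen each radiomic feature across the three classes at level alpha.

    Normally distributed features (Shapiro–Wilk p > 0.05 in every class) are
    tested by one-way ANOVA, the rest by Kruskal–Wallis.  Zero-variance
    features get p = 1 and never survive.  Clinical covariates are not
    screened.
    """
    present = set(train["label"].unique())
    if not set(CLASS_LABELS) <= present:
        raise ValueError(f"screening requires all three classes, found {sorted(present)}")
    features = radiomic_columns(train)
    groups_idx = [train["label"] == lab for lab in CLASS_LABELS]
    pvalues: dict[str, float] = {}
    for feat in features:
        col = train[feat].to_numpy(dtype=float)
        groups = [col[gi.to_numpy()] for gi in groups_idx]
        pvalues[feat] = _screen_pvalue(groups)
    survivors = [f for f in features if pvalues[f] < alpha]
    return SelectionResult(pvalues=pvalues, survivors=survivors)


# ---------------------------------------------------------------------------
# mRMR


def discretize_equal_frequency(values: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Map a continuous sample to integer codes by equal-frequency binning.

    Bin edges are the interior quantiles; duplicate edges (heavily tied data,
    e.g. a binary covariate) simply produce fewer occupied bins, which leaves
    mutual information well defined.
    """
    x = np.asarray(values, dtype=float)
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="left").astype(np.int64)


def _codes(values: np.ndarray) -> np.ndarray:
    _, inv = np.unique(values, return_inverse=True)
    return inv.astype(np.int64)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Discrete mutual information in bits between two integer code arrays."""
    a = _codes(a)
    b = _codes(b)
    na = int(a.max()) + 1
    nb = int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).astype(float).reshape(na, nb)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float(
        (joint[nz] * np.log2(joint[nz] / (pa[:, None] * pb[None, :])[nz])).sum()
    )


def mrmr_rank(
    candidates: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    k: int = 10,
    n_bins: int = 4,
) -> list[tuple[str, float]]:
    """Greedy mRMR (MID variant) ranking of ``k`` features.

    Each step selects the candidate maximizing
    ``I(f; y) - mean_{s in selected} I(f; s)``; the first pick maximizes
    relevance alone.  Returns (name, objective value at selection) pairs.
    """
    names = list(candidates.columns)
    if k > len(names):
        raise ValueError(f"requested k={k} from only {len(names)} candidates")
    y = _codes(np.asarray(labels))
    disc = {
        name: discretize_equal_frequency(candidates[name].to_numpy(dtype=float), n_bins)
        for name in names
    }
    relevance = {name: mutual_information(disc[name], y) for name in names}

    selected: list[tuple[str, float]] = []
    remaining = sorted(names)  # lexicographic order makes ties deterministic
    red_sum = {name: 0.0 for name in names}
    while len(selected) < k:
        best_name, best_score = None, -np.inf
        for name in remaining:
            if selected:
                score = relevance[name] - red_sum[name] / len(selected)
            else:
                score = relevance[name]
            if score > best_score + 1e-12:
                best_name, best_score = name, score
        selected.append((best_name, float(best_score)))
        remaining.remove(best_name)
        for name in remaining:
            red_sum[name] += mutual_information(disc[name], disc[best_name])
    return selected
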