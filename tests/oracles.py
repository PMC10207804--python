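"""Independent brute-force oracles for texture features, used only by tests.

Everything here is written as explicit Python loops over voxels / matrix
entries: co-occurrence by direct pair enumeration, runs by walking lines,
zones by breadth-first flood fill, dependence and neighborhood means by
per-voxel neighbor loops.  The implementations deliberately avoid the
package's vectorized code paths.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np

OFFSETS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
DIRECTIONS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]


def _in_bounds(v, shape):
    return all(0 <= v[i] < shape[i] for i in range(3))


def _entropy(ps):
    return -sum(p * math.log2(p) for p in ps if p > 0)


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(levels, ng, d):
    shape = levels.shape
    C = np.zeros((ng, ng))
    for v in itertools.product(*(range(n) for n in shape)):
        a = levels[v]
        if a == 0:
            continue
        w = tuple(v[i] + d[i] for i in range(3))
        if not _in_bounds(w, shape):
            continue
        b = levels[w]
        if b == 0:
            continue
        C[a - 1, b - 1] += 1
        C[b - 1, a - 1] += 1
    return C


def glcm_features(P):
    ng = P.shape[0]
    lv = list(range(1, ng + 1))
    px = [sum(P[i - 1, j - 1] for j in lv) for i in lv]
    py = [sum(P[i - 1, j - 1] for i in lv) for j in lv]
    ux = sum(px[i - 1] * i for i in lv)
    uy = sum(py[j - 1] * j for j in lv)
    sx = math.sqrt(sum(px[i - 1] * (i - ux) ** 2 for i in lv))
    sy = math.sqrt(sum(py[j - 1] * (j - uy) ** 2 for j in lv))

    p_sum = {}
    p_diff = {}
    for i in lv:
        for j in lv:
            p_sum[i + j] = p_sum.get(i + j, 0.0) + P[i - 1, j - 1]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i - 1, j - 1]
    da = sum(k * v for k, v in p_diff.items())

    hxy = _entropy(P.ravel())
    hx = _entropy(px)
    hy = _entropy(py)
    hxy1 = -sum(
        P[i - 1, j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in lv
        for j in lv
        if P[i - 1, j - 1] > 0
    )
    hxy2 = -sum(
        px[i - 1] * py[j - 1] * math.log2(px[i - 1] * py[j - 1])
        for i in lv
        for j in lv
        if px[i - 1] * py[j - 1] > 0
    )
    div = max(hx, hy)
    imc1 = (hxy - hxy1) / div if div > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    if sx * sy == 0:
        corr = 1.0
    else:
        corr = (sum(P[i - 1, j - 1] * i * j for i in lv for j in lv) - ux * uy) / (sx * sy)

    present = [i for i in lv if px[i - 1] > 0]
    if len(present) < 2:
        mcc = 1.0
    else:
        Q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a, b] = sum(
                    P[i - 1, k - 1] * P[j - 1, k - 1] / (px[i - 1] * py[k - 1])
                    for k in present
                    if py[k - 1] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        mcc = math.sqrt(max(0.0, eig[1]))

    return {
        "Autocorrelation": sum(P[i - 1, j - 1] * i * j for i in lv for j in lv),
        "ClusterProminence": sum(
            P[i - 1, j - 1] * (i + j - ux - uy) ** 4 for i in lv for j in lv
        ),
        "ClusterShade": sum(
            P[i - 1, j - 1] * (i + j - ux - uy) ** 3 for i in lv for j in lv
        ),
        "ClusterTendency": sum(
            P[i - 1, j - 1] * (i + j - ux - uy) ** 2 for i in lv for j in lv
        ),
        "Contrast": sum(P[i - 1, j - 1] * (i - j) ** 2 for i in lv for j in lv),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy(p_diff.values()),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "Id": sum(P[i - 1, j - 1] / (1 + abs(i - j)) for i in lv for j in lv),
        "Idm": sum(P[i - 1, j - 1] / (1 + (i - j) ** 2) for i in lv for j in lv),
        "Idmn": sum(
            P[i - 1, j - 1] / (1 + (i - j) ** 2 / ng**2) for i in lv for j in lv
        ),
        "Idn": sum(P[i - 1, j - 1] / (1 + abs(i - j) / ng) for i in lv for j in lv),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": sum(
            P[i - 1, j - 1] / (i - j) ** 2 for i in lv for j in lv if i != j
        ),
        "JointAverage": ux,
        "JointEnergy": sum(P[i - 1, j - 1] ** 2 for i in lv for j in lv),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": P.max(),
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": _entropy(p_sum.values()),
        "SumSquares": sum(P[i - 1, j - 1] * (i - ux) ** 2 for i in lv for j in lv),
    }


def glcm_features_averaged(levels, ng):
    per_dir = []
    for d in DIRECTIONS_13:
        C = glcm_matrix(levels, ng, d)
        if C.sum() == 0:
            continue
        per_dir.append(glcm_features(C / C.sum()))
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}


# ---------------------------------------------------------------------------
# size/run/dependence matrix statistics (explicit loops)


def _matrix_stats(M, n_vox):
    ng, ns = M.shape
    n = M.sum()
    gl_marg = [sum(M[i, j] for j in range(ns)) for i in range(ng)]
    sz_marg = [sum(M[i, j] for i in range(ng)) for j in range(ns)]
    mu_i = sum((i + 1) * M[i, j] for i in range(ng) for j in range(ns)) / n
    mu_j = sum((j + 1) * M[i, j] for i in range(ng) for j in range(ns)) / n
    stats = {
        "small": sum(M[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(ns)) / n,
        "large": sum(M[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(ns)) / n,
        "gln": sum(g**2 for g in gl_marg) / n,
        "glnn": sum(g**2 for g in gl_marg) / n**2,
        "szn": sum(s**2 for s in sz_marg) / n,
        "sznn": sum(s**2 for s in sz_marg) / n**2,
        "pct": n / n_vox,
        "glv": sum(
            (i + 1 - mu_i) ** 2 * M[i, j] / n for i in range(ng) for j in range(ns)
        ),
        "szv": sum(
            (j + 1 - mu_j) ** 2 * M[i, j] / n for i in range(ng) for j in range(ns)
        ),
        "entropy": _entropy((M / n).ravel()),
        "lgl": sum(M[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(ns)) / n,
        "hgl": sum(M[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(ns)) / n,
        "slgl": sum(
            M[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(ns)
        )
        / n,
        "shgl": sum(
            M[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(ns)
        )
        / n,
        "llgl": sum(
            M[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(ns)
        )
        / n,
        "lhgl": sum(
            M[i, j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(ns)
        )
        / n,
    }
    return stats


_RLM_NAMES = {
    "ShortRunEmphasis": "small",
    "LongRunEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "RunLengthNonUniformity": "szn",
    "RunLengthNonUniformityNormalized": "sznn",
    "RunPercentage": "pct",
    "GrayLevelVariance": "glv",
    "RunVariance": "szv",
    "RunEntropy": "entropy",
    "LowGrayLevelRunEmphasis": "lgl",
    "HighGrayLevelRunEmphasis": "hgl",
    "ShortRunLowGrayLevelEmphasis": "slgl",
    "ShortRunHighGrayLevelEmphasis": "shgl",
    "LongRunLowGrayLevelEmphasis": "llgl",
    "LongRunHighGrayLevelEmphasis": "lhgl",
}

_SZM_NAMES = {
    "SmallAreaEmphasis": "small",
    "LargeAreaEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "SizeZoneNonUniformity": "szn",
    "SizeZoneNonUniformityNormalized": "sznn",
    "ZonePercentage": "pct",
    "GrayLevelVariance": "glv",
    "ZoneVariance": "szv",
    "ZoneEntropy": "entropy",
    "LowGrayLevelZoneEmphasis": "lgl",
    "HighGrayLevelZoneEmphasis": "hgl",
    "SmallAreaLowGrayLevelEmphasis": "slgl",
    "SmallAreaHighGrayLevelEmphasis": "shgl",
    "LargeAreaLowGrayLevelEmphasis": "llgl",
    "LargeAreaHighGrayLevelEmphasis": "lhgl",
}

_DM_NAMES = {
    "SmallDependenceEmphasis": "small",
    "LargeDependenceEmphasis": "large",
    "GrayLevelNonUniformity": "gln",
    "DependenceNonUniformity": "szn",
    "DependenceNonUniformityNormalized": "sznn",
    "GrayLevelVariance": "glv",
    "DependenceVariance": "szv",
    "DependenceEntropy": "entropy",
    "LowGrayLevelEmphasis": "lgl",
    "HighGrayLevelEmphasis": "hgl",
    "SmallDependenceLowGrayLevelEmphasis": "slgl",
    "SmallDependenceHighGrayLevelEmphasis": "shgl",
    "LargeDependenceLowGrayLevelEmphasis": "llgl",
    "LargeDependenceHighGrayLevelEmphasis": "lhgl",
}


# ---------------------------------------------------------------------------
# GLRLM by walking runs


def glrlm_matrix(levels, ng, d):
    shape = levels.shape
    runs = []
    for v in itertools.product(*(range(n) for n in shape)):
        lev = levels[v]
        if lev == 0:
            continue
        prev = tuple(v[i] - d[i] for i in range(3))
        if _in_bounds(prev, shape) and levels[prev] == lev:
            continue  # not a run start
        length = 1
        w = tuple(v[i] + d[i] for i in range(3))
        while _in_bounds(w, shape) and levels[w] == lev:
            length += 1
            w = tuple(w[i] + d[i] for i in range(3))
        runs.append((lev, length))
    max_len = max(l for _, l in runs)
    R = np.zeros((ng, max_len))
    for lev, length in runs:
        R[lev - 1, length - 1] += 1
    return R


def glrlm_features_averaged(levels, ng, n_vox):
    per_dir = [
        _matrix_stats(glrlm_matrix(levels, ng, d), n_vox) for d in DIRECTIONS_13
    ]
    return {
        name: float(np.mean([f[key] for f in per_dir]))
        for name, key in _RLM_NAMES.items()
    }


# ---------------------------------------------------------------------------
# GLSZM by flood fill


def glszm_matrix(levels, ng):
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones = []
    for v in itertools.product(*(range(n) for n in shape)):
        if levels[v] == 0 or visited[v]:
            continue
        lev = levels[v]
        size = 0
        queue = deque([v])
        visited[v] = True
        while queue:
            u = queue.popleft()
            size += 1
            for d in OFFSETS_26:
                w = tuple(u[i] + d[i] for i in range(3))
                if _in_bounds(w, shape) and not visited[w] and levels[w] == lev:
                    visited[w] = True
                    queue.append(w)
        zones.append((lev, size))
    max_size = max(s for _, s in zones)
    Z = np.zeros((ng, max_size))
    for lev, size in zones:
        Z[lev - 1, size - 1] += 1
    return Z


def glszm_features(levels, ng, n_vox):
    stats = _matrix_stats(glszm_matrix(levels, ng), n_vox)
    return {name: float(stats[key]) for name, key in _SZM_NAMES.items()}


# ---------------------------------------------------------------------------
# GLDM by per-voxel neighbor counting


def gldm_matrix(levels, ng):
    shape = levels.shape
    entries = []
    for v in itertools.product(*(range(n) for n in shape)):
        lev = levels[v]
        if lev == 0:
            continue
        dep = 1  # center voxel
        for d in OFFSETS_26:
            w = tuple(v[i] + d[i] for i in range(3))
            if _in_bounds(w, shape) and levels[w] == lev:
                dep += 1
        entries.append((lev, dep))
    max_dep = max(d for _, d in entries)
    D = np.zeros((ng, max_dep))
    for lev, dep in entries:
        D[lev - 1, dep - 1] += 1
    return D


def gldm_features(levels, ng, n_vox):
    stats = _matrix_stats(gldm_matrix(levels, ng), n_vox)
    return {name: float(stats[key]) for name, key in _DM_NAMES.items()}


# ---------------------------------------------------------------------------
# NGTDM per-voxel


def ngtdm_features(levels, ng):
    shape = levels.shape
    n_i = [0.0] * ng
    s_i = [0.0] * ng
    for v in itertools.product(*(range(n) for n in shape)):
        lev = levels[v]
        if lev == 0:
            continue
        neigh = []
        for d in OFFSETS_26:
            w = tuple(v[i] + d[i] for i in range(3))
            if _in_bounds(w, shape) and levels[w] > 0:
                neigh.append(levels[w])
        if not neigh:
            continue
        n_i[lev - 1] += 1
        s_i[lev - 1] += abs(lev - sum(neigh) / len(neigh))
    nvp = sum(n_i)
    if nvp == 0:
        return {"Coarseness": 1e6, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    p_i = [n / nvp for n in n_i]
    present = [i for i in range(ng) if p_i[i] > 0]
    ngp = len(present)

    denom = sum(p_i[i] * s_i[i] for i in range(ng))
    coarseness = min(1e6, 1.0 / denom) if denom > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(
                p_i[i] * p_i[j] * (i - j) ** 2
                for i in present
                for j in present
            )
            / (ngp * (ngp - 1))
            * (sum(s_i) / nvp)
        )
        busy_den = sum(
            abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in present for j in present
        )
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(i - j)
                * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                / (p_i[i] + p_i[j])
                for i in present
                for j in present
            )
            / nvp
        )
        s_tot = sum(s_i)
        strength = (
            sum((p_i[i] + p_i[j]) * (i - j) ** 2 for i in present for j in present)
            / s_tot
            if s_tot > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
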