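"""Independent brute-force reference implementations of the texture features.

Everything here is written with naive Python loops and explicit neighbourhood
enumeration, deliberately sharing no code with the package implementation, so
the two can serve as cross-checks of one another.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np

DIRS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
DIRS_13 = [d for d in DIRS_26 if d > (0, 0, 0)]


def _in_bounds(shape, v):
    return all(0 <= v[i] < shape[i] for i in range(3))


def _voxels(mask):
    return [tuple(v) for v in np.argwhere(mask)]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_oracle(disc: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    shape = disc.shape
    per_dir = []
    for d in DIRS_13:
        counts = {}
        for v in _voxels(mask):
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in_bounds(shape, w) and mask[w]:
                a, b = int(disc[v]), int(disc[w])
                counts[(a, b)] = counts.get((a, b), 0) + 1
                counts[(b, a)] = counts.get((b, a), 0) + 1
        total = sum(counts.values())
        if total == 0:
            continue
        p = {k: c / total for k, c in counts.items()}
        mu = sum(i * sum(pv for (a, _), pv in p.items() if a == i) for i in range(1, n_levels + 1))
        var = sum((i - mu) ** 2 * sum(pv for (a, _), pv in p.items() if a == i) for i in range(1, n_levels + 1))
        sd = math.sqrt(var)
        feats = {
            "glcm/joint_energy": sum(pv**2 for pv in p.values()),
            "glcm/joint_entropy": -sum(pv * math.log2(pv) for pv in p.values()),
            "glcm/contrast": sum((a - b) ** 2 * pv for (a, b), pv in p.items()),
            "glcm/correlation": (
                sum((a - mu) * (b - mu) * pv for (a, b), pv in p.items()) / var
                if sd > 0
                else 1.0
            ),
            "glcm/inverse_difference_moment": sum(
                pv / (1 + (a - b) ** 2) for (a, b), pv in p.items()
            ),
            "glcm/cluster_shade": sum(
                (a + b - 2 * mu) ** 3 * pv for (a, b), pv in p.items()
            ),
            "glcm/cluster_prominence": sum(
                (a + b - 2 * mu) ** 4 * pv for (a, b), pv in p.items()
            ),
            "glcm/maximum_probability": max(p.values()),
        }
        per_dir.append(feats)
    if not per_dir:
        return {
            "glcm/joint_energy": 1.0,
            "glcm/joint_entropy": 0.0,
            "glcm/contrast": 0.0,
            "glcm/correlation": 1.0,
            "glcm/inverse_difference_moment": 1.0,
            "glcm/cluster_shade": 0.0,
            "glcm/cluster_prominence": 0.0,
            "glcm/maximum_probability": 1.0,
        }
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def glrlm_oracle(disc: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    shape = disc.shape
    n_vox = int(mask.sum())
    per_dir = []
    for d in DIRS_13:
        runs = []  # (level, length)
        for v in _voxels(mask):
            prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
            if _in_bounds(shape, prev) and mask[prev] and disc[prev] == disc[v]:
                continue  # not a run start
            length = 1
            cur = v
            while True:
                nxt = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if _in_bounds(shape, nxt) and mask[nxt] and disc[nxt] == disc[v]:
                    length += 1
                    cur = nxt
                else:
                    break
            runs.append((int(disc[v]), length))
        n_runs = len(runs)
        by_len: dict[int, int] = {}
        by_lvl: dict[int, int] = {}
        for g, L in runs:
            by_len[L] = by_len.get(L, 0) + 1
            by_lvl[g] = by_lvl.get(g, 0) + 1
        mu = sum(L * c for L, c in by_len.items()) / n_runs
        per_dir.append(
            {
                "glrlm/short_run_emphasis": sum(c / L**2 for L, c in by_len.items()) / n_runs,
                "glrlm/long_run_emphasis": sum(c * L**2 for L, c in by_len.items()) / n_runs,
                "glrlm/gray_level_nonuniformity": sum(c**2 for c in by_lvl.values()) / n_runs,
                "glrlm/run_length_nonuniformity": sum(c**2 for c in by_len.values()) / n_runs,
                "glrlm/run_percentage": n_runs / n_vox,
                "glrlm/run_variance": sum((L - mu) ** 2 * c for L, c in by_len.items()) / n_runs,
            }
        )
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------


def glszm_oracle(disc: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    shape = disc.shape
    n_vox = int(mask.sum())
    seen = set()
    zones = []  # (level, size) via BFS flood fill, 26-connected
    for start in _voxels(mask):
        if start in seen:
            continue
        level = int(disc[start])
        q = deque([start])
        seen.add(start)
        size = 0
        while q:
            v = q.popleft()
            size += 1
            for d in DIRS_26:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if (
                    _in_bounds(shape, w)
                    and w not in seen
                    and mask[w]
                    and int(disc[w]) == level
                ):
                    seen.add(w)
                    q.append(w)
        zones.append((level, size))
    n_z = len(zones)
    by_size: dict[int, int] = {}
    by_lvl: dict[int, int] = {}
    for g, s in zones:
        by_size[s] = by_size.get(s, 0) + 1
        by_lvl[g] = by_lvl.get(g, 0) + 1
    return {
        "glszm/small_area_emphasis": sum(c / s**2 for s, c in by_size.items()) / n_z,
        "glszm/large_area_emphasis": sum(c * s**2 for s, c in by_size.items()) / n_z,
        "glszm/zone_percentage": n_z / n_vox,
        "glszm/gray_level_nonuniformity": sum(c**2 for c in by_lvl.values()) / n_z,
        "glszm/size_zone_nonuniformity": sum(c**2 for c in by_size.values()) / n_z,
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm_oracle(disc: np.ndarray, mask: np.ndarray, n_levels: int) -> dict[str, float]:
    shape = disc.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for v in _voxels(mask):
        neigh = []
        for d in DIRS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in_bounds(shape, w) and mask[w]:
                neigh.append(int(disc[w]))
        if not neigh:
            continue
        g = int(disc[v])
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - sum(neigh) / len(neigh))
    N = n_i.sum()
    p_i = n_i / N
    nz = [i for i in range(n_levels) if p_i[i] > 0]
    ngp = len(nz)
    denom = float((p_i * s_i).sum())
    coarseness = min(1.0 / denom, 1e6) if denom > 1e-12 else 1e6
    if ngp > 1:
        contrast = (
            sum(p_i[i] * p_i[j] * (i - j) ** 2 for i in nz for j in nz)
            / (ngp * (ngp - 1))
            * (s_i.sum() / N)
        )
        busy_den = sum(
            abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in nz for j in nz
        )
        busyness = float((p_i * s_i).sum() / busy_den) if busy_den > 1e-12 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j]) / (p_i[i] + p_i[j])
                for i in nz
                for j in nz
            )
            / N
        )
        s_sum = s_i.sum()
        strength = (
            sum((p_i[i] + p_i[j]) * (i - j) ** 2 for i in nz for j in nz) / s_sum
            if s_sum > 1e-12
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm/coarseness": float(coarseness),
        "ngtdm/contrast": float(contrast),
        "ngtdm/busyness": float(busyness),
        "ngtdm/complexity": float(complexity),
        "ngtdm/strength": float(strength),
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def gldm_oracle(
    disc: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0
) -> dict[str, float]:
    shape = disc.shape
    entries = []  # (level, dependence count)
    for v in _voxels(mask):
        dep = 0
        for d in DIRS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _in_bounds(shape, w) and mask[w] and abs(int(disc[w]) - int(disc[v])) <= alpha:
                dep += 1
        entries.append((int(disc[v]), dep))
    n = len(entries)
    by_dep: dict[int, int] = {}
    by_lvl: dict[int, int] = {}
    by_cell: dict[tuple[int, int], int] = {}
    for g, dep in entries:
        by_dep[dep] = by_dep.get(dep, 0) + 1
        by_lvl[g] = by_lvl.get(g, 0) + 1
        by_cell[(g, dep)] = by_cell.get((g, dep), 0) + 1
    return {
        "gldm/small_dependence_emphasis": sum(
            c / (dep + 1) ** 2 for dep, c in by_dep.items()
        )
        / n,
        "gldm/large_dependence_emphasis": sum(
            c * (dep + 1) ** 2 for dep, c in by_dep.items()
        )
        / n,
        "gldm/dependence_nonuniformity": sum(c**2 for c in by_dep.values()) / n,
        "gldm/gray_level_nonuniformity": sum(c**2 for c in by_lvl.values()) / n,
        "gldm/dependence_entropy": -sum(
            (c / n) * math.log2(c / n) for c in by_cell.values()
        ),
    }
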