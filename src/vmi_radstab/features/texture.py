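"""3D texture-matrix features on a discretized lattice.

All five families operate on an integer lattice (0 = outside mask, levels
1..L inside) and a boolean mask, restricted to the mask bounding box:

* GLCM  — gray level co-occurrence (13 unique unit directions, symmetrized,
  normalized per direction, features averaged over directions)
* GLRLM — gray level run length (13 directions, mask-broken runs, averaged)
* GLSZM — gray level size zone (26-connected equal-level components)
* NGTDM — neighbouring gray tone difference (26-neighbourhood in-mask mean)
* GLDM  — gray level dependence (26-neighbour same-level counts)

Aggregation over directions averages the per-direction feature values rather
than merging the matrices. Degenerate inputs (a single in-mask voxel, a
single gray level) follow fixed documented rules so downstream tables stay
dense: see the per-family docstrings.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.ndimage import label as cc_label

__all__ = [
    "OFFSETS_13",
    "OFFSETS_26",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "GLDM_NAMES",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
]

_EPS = 1e-12
_COARSENESS_CAP = 1e6

#: the 26 neighbour offsets of a voxel
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)

#: 13 unique direction vectors (one of each antipodal pair, first
#: nonzero component positive)
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    d for d in OFFSETS_26 if d > (0, 0, 0)
)

GLCM_NAMES = tuple(
    f"glcm/{n}"
    for n in (
        "joint_energy",
        "joint_entropy",
        "contrast",
        "correlation",
        "inverse_difference_moment",
        "cluster_shade",
        "cluster_prominence",
        "maximum_probability",
    )
)
GLRLM_NAMES = tuple(
    f"glrlm/{n}"
    for n in (
        "short_run_emphasis",
        "long_run_emphasis",
        "gray_level_nonuniformity",
        "run_length_nonuniformity",
        "run_percentage",
        "run_variance",
    )
)
GLSZM_NAMES = tuple(
    f"glszm/{n}"
    for n in (
        "small_area_emphasis",
        "large_area_emphasis",
        "zone_percentage",
        "gray_level_nonuniformity",
        "size_zone_nonuniformity",
    )
)
NGTDM_NAMES = tuple(
    f"ngtdm/{n}" for n in ("coarseness", "contrast", "busyness", "complexity", "strength")
)
GLDM_NAMES = tuple(
    f"gldm/{n}"
    for n in (
        "small_dependence_emphasis",
        "large_dependence_emphasis",
        "dependence_nonuniformity",
        "gray_level_nonuniformity",
        "dependence_entropy",
    )
)


def _crop(disc: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if not mask.any():
        raise ValueError("mask is empty")
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return disc[sl], mask[sl]


def _shifted(arr: np.ndarray, d: tuple[int, int, int], fill) -> np.ndarray:
    """Array ``out[v] = arr[v + d]`` with out-of-bounds positions = fill."""
    out = np.full_like(arr, fill)
    dst = tuple(
        slice(max(0, -di), arr.shape[i] - max(0, di)) for i, di in enumerate(d)
    )
    src = tuple(
        slice(max(0, di), arr.shape[i] + min(0, di)) for i, di in enumerate(d)
    )
    if all(s.start < s.stop for s in dst):
        out[dst] = arr[src]
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def _glcm_matrix(disc: np.ndarray, mask: np.ndarray, d, n_levels: int) -> np.ndarray:
    nb = _shifted(disc, d, 0)
    valid = mask & (_shifted(mask, d, False))
    a = disc[valid] - 1
    b = nb[valid] - 1
    if a.size == 0:
        return np.zeros((n_levels, n_levels))
    p = np.bincount(a * n_levels + b, minlength=n_levels * n_levels).reshape(
        n_levels, n_levels
    ).astype(float)
    p = p + p.T  # symmetrize
    return p / p.sum()


def _glcm_feature_values(p: np.ndarray) -> dict[str, float]:
    L = p.shape[0]
    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    nz = p[p > 0]
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0:
        corr = float((((ii - mu_x) * (jj - mu_x) * p).sum()) / (sd_x * sd_x))
    else:
        corr = 1.0  # single gray level: perfectly correlated by convention
    return {
        "glcm/joint_energy": float((p**2).sum()),
        "glcm/joint_entropy": float(-(nz * np.log2(nz)).sum()),
        "glcm/contrast": contrast,
        "glcm/correlation": corr,
        "glcm/inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "glcm/cluster_shade": float((((ii + jj - 2 * mu_x) ** 3) * p).sum()),
        "glcm/cluster_prominence": float((((ii + jj - 2 * mu_x) ** 4) * p).sum()),
        "glcm/maximum_probability": float(p.max()),
    }


_GLCM_DEGENERATE = {
    "glcm/joint_energy": 1.0,
    "glcm/joint_entropy": 0.0,
    "glcm/contrast": 0.0,
    "glcm/correlation": 1.0,
    "glcm/inverse_difference_moment": 1.0,
    "glcm/cluster_shade": 0.0,
    "glcm/cluster_prominence": 0.0,
    "glcm/maximum_probability": 1.0,
}


def glcm_features(
    disc: np.ndarray, mask: np.ndarray, n_levels: int | None = None
) -> dict[str, float]:
    """Co-occurrence features averaged over the 13 unique 3D directions.

    Directions with no valid in-mask pair are dropped from the average; if no
    direction has a pair (single in-mask voxel) the degenerate rule applies:
    energy 1, entropy 0, contrast 0, correlation 1, IDM 1, shade/prominence
    0, maximum probability 1.
    """
    disc, mask = _crop(disc, mask)
    L = int(n_levels if n_levels is not None else disc.max())
    per_dir: list[dict[str, float]] = []
    for d in OFFSETS_13:
        p = _glcm_matrix(disc, mask, d, L)
        if p.sum() == 0:
            continue
        per_dir.append(_glcm_feature_values(p))
    if not per_dir:
        return dict(_GLCM_DEGENERATE)
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _glrlm_matrix(disc: np.ndarray, mask: np.ndarray, d, n_levels: int) -> np.ndarray:
    """Run-length matrix R[level-1, length-1] along one direction."""
    max_len = int(np.ceil(np.sqrt(sum((di * s) ** 2 for di, s in zip(d, disc.shape)))))
    same_next = mask & _shifted(mask, d, False) & (disc == _shifted(disc, d, 0))
    prev_same = _shifted(same_next, tuple(-di for di in d), False)
    is_start = mask & ~prev_same
    R = np.zeros((n_levels, max_len + 1))
    ext = is_start
    k = 1
    while ext.any():
        step = tuple(di * (k - 1) for di in d)
        nxt = ext & _shifted(same_next, step, False)
        exact = ext & ~nxt
        if exact.any():
            levels = disc[exact] - 1
            R[:, k - 1] += np.bincount(levels, minlength=n_levels)
        ext = nxt
        k += 1
    return R[:, : max(k - 1, 1)]


def _glrlm_feature_values(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    n_runs = R.sum()
    j = np.arange(1, R.shape[1] + 1, dtype=float)
    r_j = R.sum(axis=0)
    r_g = R.sum(axis=1)
    p_j = r_j / n_runs
    mu_j = float((j * p_j).sum())
    return {
        "glrlm/short_run_emphasis": float((r_j / j**2).sum() / n_runs),
        "glrlm/long_run_emphasis": float((r_j * j**2).sum() / n_runs),
        "glrlm/gray_level_nonuniformity": float((r_g**2).sum() / n_runs),
        "glrlm/run_length_nonuniformity": float((r_j**2).sum() / n_runs),
        "glrlm/run_percentage": float(n_runs / n_voxels),
        "glrlm/run_variance": float((p_j * (j - mu_j) ** 2).sum()),
    }


def glrlm_features(
    disc: np.ndarray, mask: np.ndarray, n_levels: int | None = None
) -> dict[str, float]:
    """Run-length features averaged over the 13 unique 3D directions.

    Runs are broken by the mask. Every in-mask voxel belongs to exactly one
    run per direction, so no degenerate case arises beyond an empty mask.
    """
    disc, mask = _crop(disc, mask)
    L = int(n_levels if n_levels is not None else disc.max())
    n_vox = int(mask.sum())
    per_dir = [
        _glrlm_feature_values(_glrlm_matrix(disc, mask, d, L), n_vox)
        for d in OFFSETS_13
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=int)


def glszm_features(
    disc: np.ndarray, mask: np.ndarray, n_levels: int | None = None
) -> dict[str, float]:
    """Size-zone features; zones are 26-connected equal-level components."""
    disc, mask = _crop(disc, mask)
    L = int(n_levels if n_levels is not None else disc.max())
    n_vox = int(mask.sum())
    zone_sizes: list[np.ndarray] = []
    zone_levels: list[np.ndarray] = []
    present = np.unique(disc[mask])
    for g in present:
        lab, n_zones = cc_label((disc == g) & mask, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_sizes.append(sizes)
        zone_levels.append(np.full(n_zones, g))
    sizes = np.concatenate(zone_sizes).astype(float)
    levels = np.concatenate(zone_levels)
    n_z = float(len(sizes))
    s_g = np.bincount(levels - 1, minlength=L).astype(float)  # zones per level
    size_ids, size_counts = np.unique(sizes, return_counts=True)
    return {
        "glszm/small_area_emphasis": float((1.0 / sizes**2).sum() / n_z),
        "glszm/large_area_emphasis": float((sizes**2).sum() / n_z),
        "glszm/zone_percentage": float(n_z / n_vox),
        "glszm/gray_level_nonuniformity": float((s_g**2).sum() / n_z),
        "glszm/size_zone_nonuniformity": float(
            (size_counts.astype(float) ** 2).sum() / n_z
        ),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def _neighbour_mean(disc: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean level of in-mask 26-neighbours and the neighbour count."""
    total = np.zeros(disc.shape, dtype=float)
    count = np.zeros(disc.shape, dtype=float)
    for d in OFFSETS_26:
        total += _shifted(np.where(mask, disc, 0), d, 0)
        count += _shifted(mask, d, False)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return mean, count


def ngtdm_features(
    disc: np.ndarray, mask: np.ndarray, n_levels: int | None = None
) -> dict[str, float]:
    """Neighbouring gray tone difference features (IBSI definitions).

    Only voxels with at least one in-mask neighbour contribute. Coarseness is
    capped at 1e6 when its denominator vanishes (fully homogeneous region);
    contrast and strength are 0 when only one level is present; busyness is 0
    when its denominator vanishes. eps = 1e-12 guards all divisions.
    """
    disc, mask = _crop(disc, mask)
    L = int(n_levels if n_levels is not None else disc.max())
    mean, count = _neighbour_mean(disc, mask)
    contrib = mask & (count > 0)
    levels = disc[contrib] - 1
    absdiff = np.abs(disc[contrib] - mean[contrib])
    n_i = np.bincount(levels, minlength=L).astype(float)
    s_i = np.zeros(L)
    np.add.at(s_i, levels, absdiff)
    N = n_i.sum()
    p_i = n_i / N
    i = np.arange(1, L + 1, dtype=float)
    nz = p_i > 0
    n_gp = int(nz.sum())

    denom_coarse = float((p_i * s_i).sum())
    coarseness = min(1.0 / denom_coarse, _COARSENESS_CAP) if denom_coarse > _EPS else _COARSENESS_CAP

    if n_gp > 1:
        pi_, pj_ = np.meshgrid(p_i, p_i, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        contrast = float(
            (pi_ * pj_ * (ii - jj) ** 2).sum()
            / (n_gp * (n_gp - 1))
            * (s_i.sum() / N)
        )
        ip = i * p_i
        busy_den = float(np.abs(ip[nz][:, None] - ip[nz][None, :]).sum())
        busyness = float((p_i * s_i).sum() / busy_den) if busy_den > _EPS else 0.0
        both = nz[:, None] & nz[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            cmplx = np.where(
                both,
                np.abs(ii - jj)
                * (pi_ * s_i[:, None] + pj_ * s_i[None, :])
                / np.where(both, pi_ + pj_, 1.0),
                0.0,
            )
        complexity = float(cmplx.sum() / N)
        s_sum = float(s_i.sum())
        strength = (
            float(((pi_ + pj_) * (ii - jj) ** 2 * both).sum() / s_sum)
            if s_sum > _EPS
            else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0

    return {
        "ngtdm/coarseness": float(coarseness),
        "ngtdm/contrast": contrast,
        "ngtdm/busyness": busyness,
        "ngtdm/complexity": complexity,
        "ngtdm/strength": strength,
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def gldm_features(
    disc: np.ndarray, mask: np.ndarray, n_levels: int | None = None, alpha: int = 0
) -> dict[str, float]:
    """Gray level dependence features.

    The dependence count d of a voxel is the number of its in-mask
    26-neighbours whose level differs by at most ``alpha`` (default 0, i.e.
    equal level); an interior voxel of a constant region has d = 26. The
    small/large dependence emphases weight by (d + 1) so that an isolated
    level (d = 0 everywhere) gives small_dependence_emphasis = 1.
    """
    disc, mask = _crop(disc, mask)
    L = int(n_levels if n_levels is not None else disc.max())
    dep = np.zeros(disc.shape, dtype=int)
    for d in OFFSETS_26:
        nb_level = _shifted(disc, d, -10**9)
        nb_in = _shifted(mask, d, False)
        dep += (nb_in & (np.abs(disc - nb_level) <= alpha)).astype(int)
    levels = disc[mask] - 1
    deps = dep[mask]
    P = np.zeros((L, 27))
    np.add.at(P, (levels, deps), 1.0)
    n_d = P.sum()
    j = np.arange(1, 28, dtype=float)  # dependence count + 1
    p_j = P.sum(axis=0)
    p_g = P.sum(axis=1)
    p = P / n_d
    nzp = p[p > 0]
    return {
        "gldm/small_dependence_emphasis": float((p_j / j**2).sum() / n_d),
        "gldm/large_dependence_emphasis": float((p_j * j**2).sum() / n_d),
        "gldm/dependence_nonuniformity": float((p_j**2).sum() / n_d),
        "gldm/gray_level_nonuniformity": float((p_g**2).sum() / n_d),
        "gldm/dependence_entropy": float(-(nzp * np.log2(nzp)).sum()),
    }
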