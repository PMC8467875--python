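"""Shape features of a binary segmentation.

Volume is voxel-counting volume; surface area counts exposed voxel faces;
the maximum 3D diameter is the largest pairwise distance between voxel
corner vertices of the surface (computed on the convex hull for speed).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from ..grid import SegmentationMask

__all__ = ["SHAPE_NAMES", "shape_features"]

SHAPE_NAMES = tuple(
    f"shape/{n}"
    for n in (
        "voxel_volume",
        "surface_area",
        "sphericity",
        "max_3d_diameter",
        "elongation",
        "flatness",
    )
)


def _surface_area(m: np.ndarray, spacing: np.ndarray) -> float:
    """Total area of voxel faces between foreground and background/outside."""
    area = 0.0
    for axis in range(3):
        face = spacing[(axis + 1) % 3] * spacing[(axis + 2) % 3]
        padded = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = padded.astype(np.int8)
        exposed = np.abs(np.diff(diff, axis=axis)).sum()
        area += float(exposed) * face
    return area


def _max_diameter(coords: np.ndarray, spacing: np.ndarray) -> float:
    """Max pairwise distance between corner vertices of the given voxels."""
    half = spacing / 2.0
    corners = []
    for signs in itertools.product((-1.0, 1.0), repeat=3):
        corners.append(coords + np.asarray(signs) * half)
    pts = np.unique(np.concatenate(corners, axis=0), axis=0)
    if len(pts) > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar) cloud: brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).max())


def shape_features(mask: SegmentationMask) -> dict[str, float]:
    m = mask.values
    if not m.any():
        raise ValueError("mask is empty")
    spacing = np.asarray(mask.spacing_mm)
    voxel_vol = float(np.prod(spacing))
    n = int(m.sum())
    volume = n * voxel_vol
    area = _surface_area(m, spacing)
    sphericity = (np.pi ** (1.0 / 3.0)) * (6.0 * volume) ** (2.0 / 3.0) / area

    idx = np.argwhere(m)
    coords = (idx + 0.5) * spacing

    # surface voxels: any face-neighbour missing
    from scipy.ndimage import binary_erosion

    eroded = binary_erosion(m) if n > 1 else np.zeros_like(m)
    surf = m & ~eroded
    surf_coords = (np.argwhere(surf) + 0.5) * spacing
    diameter = _max_diameter(surf_coords, spacing)

    if n > 1:
        cov = np.cov(coords, rowvar=False, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    else:
        elongation, flatness = 1.0, 1.0

    return {
        "shape/voxel_volume": volume,
        "shape/surface_area": area,
        "shape/sphericity": float(sphericity),
        "shape/max_3d_diameter": diameter,
        "shape/elongation": elongation,
        "shape/flatness": flatness,
    }
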