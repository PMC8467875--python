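"""Image preprocessing: isotropic resampling, intensity rescaling, binning.

The preprocessing chain mirrors a standardized radiomics workflow: spatial
resampling to an isotropic grid with degree-5 Lagrange polynomial
interpolation (nearest neighbour for masks), relative intensity rescaling
(in-mask z-normalization times a fixed scale), and fixed-bin-size intensity
discretization anchored at the in-mask minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grid import SegmentationMask, VolumeGrid

__all__ = [
    "PreprocessConfig",
    "resample_isotropic",
    "rescale_intensity",
    "discretize",
]

_ALLOWED_ORDERS = (0, 1, 3, 5)


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the preprocessing chain.

    ``rescale_scale`` is the target in-mask standard deviation after
    z-normalization; ``bin_width`` is in the (possibly rescaled) intensity
    units. ``apply_rescale`` exposes rescaling as a switch since some
    workflows discretize raw HU directly.
    """

    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    interp_order: int = 5
    rescale_scale: float = 500.0
    bin_width: float = 25.0
    apply_rescale: bool = True

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.interp_order not in _ALLOWED_ORDERS:
            raise ValueError(f"interp_order must be one of {_ALLOWED_ORDERS}")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")


def _lagrange_matrix(x: np.ndarray, n_in: int, order: int) -> np.ndarray:
    """Dense interpolation matrix W (n_out x n_in) of Lagrange weights.

    Each output sample at input-index coordinate ``x`` uses an
    ``order + 1``-point stencil clamped inside the domain, so polynomial
    fields up to the given degree are reproduced exactly, including at the
    boundaries.
    """
    order = min(order, n_in - 1)
    npts = order + 1
    if order == 0:
        w = np.zeros((len(x), n_in))
        idx = np.clip(np.rint(x).astype(int), 0, n_in - 1)
        w[np.arange(len(x)), idx] = 1.0
        return w
    base = np.floor(x).astype(int) - (npts // 2 - 1)
    base = np.clip(base, 0, n_in - npts)
    nodes = base[:, None] + np.arange(npts)[None, :]
    weights = np.ones((len(x), npts))
    for j in range(npts):
        for m in range(npts):
            if m == j:
                continue
            weights[:, j] *= (x - nodes[:, m]) / (nodes[:, j] - nodes[:, m])
    w = np.zeros((len(x), n_in))
    rows = np.repeat(np.arange(len(x)), npts)
    np.add.at(w, (rows, nodes.ravel()), weights.ravel())
    return w


def _resample_axis(arr: np.ndarray, w: np.ndarray, axis: int) -> np.ndarray:
    out = np.tensordot(w, arr, axes=(1, axis))
    return np.moveaxis(out, 0, axis)


def resample_isotropic(
    volume: VolumeGrid,
    mask: SegmentationMask,
    config: PreprocessConfig | None = None,
) -> tuple[VolumeGrid, SegmentationMask]:
    """Resample a volume/mask pair onto the target isotropic grid.

    The volume is interpolated separably with Lagrange polynomials of the
    configured degree; the mask with nearest neighbour. The output grid spans
    the same physical extent, center-aligned with the input. If the input is
    already at the target spacing, both inputs are returned unchanged.
    """
    config = config or PreprocessConfig()
    if not volume.same_geometry(mask):
        raise ValueError("volume and mask geometries differ")
    s_in = np.asarray(volume.spacing_mm)
    s_out = np.asarray(config.target_spacing_mm)
    if np.allclose(s_in, s_out):
        return volume, mask

    n_in = np.asarray(volume.shape)
    extent = n_in * s_in
    n_out = np.maximum(np.rint(extent / s_out).astype(int), 1)
    origin_in = np.asarray(volume.origin_mm)
    origin_out = origin_in + (extent - n_out * s_out) / 2.0

    vol = volume.values
    msk = mask.values.astype(float)
    for axis in range(3):
        pos = origin_out[axis] + (np.arange(n_out[axis]) + 0.5) * s_out[axis]
        x = (pos - origin_in[axis]) / s_in[axis] - 0.5
        w_vol = _lagrange_matrix(x, n_in[axis], config.interp_order)
        w_nn = _lagrange_matrix(x, n_in[axis], 0)
        vol = _resample_axis(vol, w_vol, axis)
        msk = _resample_axis(msk, w_nn, axis)

    mask_out = SegmentationMask(
        msk > 0.5, spacing_mm=tuple(s_out), origin_mm=tuple(origin_out)
    )
    if mask_out.n_voxels == 0:
        raise ValueError("mask is empty after resampling")
    vol_out = VolumeGrid(vol, spacing_mm=tuple(s_out), origin_mm=tuple(origin_out))
    return vol_out, mask_out


def rescale_intensity(
    volume: VolumeGrid, mask: SegmentationMask, scale: float = 500.0
) -> VolumeGrid:
    """Relative intensity rescaling: in-mask z-normalization times ``scale``.

    In-mask voxels map to ``scale * (x - mean) / std`` (population std);
    voxels outside the mask are left untouched (they are excluded from all
    downstream feature computations anyway).
    """
    if not volume.same_geometry(mask):
        raise ValueError("volume and mask geometries differ")
    vals = volume.values[mask.values]
    if vals.size == 0:
        raise ValueError("mask is empty")
    mu = vals.mean()
    sd = vals.std()
    if sd == 0:
        raise ValueError("degenerate intensity distribution (zero in-mask std)")
    out = volume.values.copy()
    out[mask.values] = scale * (out[mask.values] - mu) / sd
    return VolumeGrid(out, spacing_mm=volume.spacing_mm, origin_mm=volume.origin_mm)


def discretize(
    volume: VolumeGrid, mask: SegmentationMask, bin_width: float = 25.0
) -> tuple[np.ndarray, int]:
    """Fixed-bin-size discretization anchored at the in-mask minimum.

    In-mask voxel with value ``x`` gets bin index
    ``floor(x / w) - floor(min / w) + 1``; out-of-mask voxels get 0.
    Returns the integer lattice and the number of levels (max bin index).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not volume.same_geometry(mask):
        raise ValueError("volume and mask geometries differ")
    m = mask.values
    if not m.any():
        raise ValueError("mask is empty")
    vals = volume.values[m]
    base = np.floor(vals.min() / bin_width)
    disc = np.zeros(volume.shape, dtype=np.int64)
    disc[m] = np.floor(vals / bin_width).astype(np.int64) - int(base) + 1
    return disc, int(disc[m].max())
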