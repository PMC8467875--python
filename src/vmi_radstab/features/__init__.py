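"""Radiomic feature extraction.

An IBSI-style catalogue of 51 features across seven families (first order,
shape, GLCM, GLRLM, GLSZM, NGTDM, GLDM), extracted from a volume/mask pair
after a standardized preprocessing chain: isotropic resampling (degree-5
Lagrange interpolation), relative intensity rescaling (in-mask
z-normalization x 500), and fixed-bin-size discretization (bin width 25).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grid import SegmentationMask, VolumeGrid
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .preprocess import (
    PreprocessConfig,
    discretize,
    rescale_intensity,
    resample_isotropic,
)
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "PreprocessConfig",
    "resample_isotropic",
    "rescale_intensity",
    "discretize",
    "first_order_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "extract_all",
]

#: the full, fixed feature catalogue (name-spaced ``family/feature``)
FEATURE_NAMES: tuple[str, ...] = (
    FIRSTORDER_NAMES
    + SHAPE_NAMES
    + GLCM_NAMES
    + GLRLM_NAMES
    + GLSZM_NAMES
    + NGTDM_NAMES
    + GLDM_NAMES
)


@dataclass
class FeatureVector:
    """Named feature values for one object under one acquisition condition."""

    object_id: str
    condition: object = None
    values: dict[str, float] = field(default_factory=dict)


def extract_all(
    volume: VolumeGrid,
    mask: SegmentationMask,
    config: PreprocessConfig | None = None,
) -> dict[str, float]:
    """Run the full preprocessing + extraction pipeline.

    Order: resample -> rescale -> discretize -> the seven family extractors.
    Deterministic: two runs on identical input give bit-identical values.
    """
    config = config or PreprocessConfig()
    vol, msk = resample_isotropic(volume, mask, config)
    if msk.n_voxels < 27:
        raise ValueError(
            f"mask has {msk.n_voxels} voxels; at least 27 required for "
            "3D texture matrices"
        )
    if config.apply_rescale:
        vol = rescale_intensity(vol, msk, config.rescale_scale)
    disc, n_levels = discretize(vol, msk, config.bin_width)

    out: dict[str, float] = {}
    out.update(first_order_features(vol, disc, msk))
    out.update(shape_features(msk))
    m = msk.values
    out.update(glcm_features(disc, m, n_levels))
    out.update(glrlm_features(disc, m, n_levels))
    out.update(glszm_features(disc, m, n_levels))
    out.update(ngtdm_features(disc, m, n_levels))
    out.update(gldm_features(disc, m, n_levels))

    missing = set(FEATURE_NAMES) - set(out)
    if missing:  # pragma: no cover - catalogue is fixed
        raise RuntimeError(f"extractor returned incomplete catalogue: {missing}")
    return {k: out[k] for k in FEATURE_NAMES}
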