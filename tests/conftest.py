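"""Shared fixtures: phantom scenes and extracted feature tables.

Expensive artefacts (full-catalogue feature tables from the default phantom)
are session-scoped so repeatability, subset and classification tests reuse
one extraction pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vmi_radstab.features import FEATURE_NAMES, extract_all
from vmi_radstab.grid import SegmentationMask, VolumeGrid
from vmi_radstab.synthetic import (
    AcquisitionCondition,
    ObjectSpec,
    PhantomSpec,
    default_phantom_spec,
    generate_phantom_volume,
)


@pytest.fixture(scope="session")
def phantom_spec():
    return default_phantom_spec(seed=0)


@pytest.fixture(scope="session")
def class_labels(phantom_spec):
    return pd.Series(
        {o.object_id: o.class_label for o in phantom_spec.objects}, name="class_label"
    )


@pytest.fixture(scope="session")
def fine_phantom_spec():
    """Four ellipsoids on a half-millimetre grid (radii ~11 voxels), used for
    voxelization-tolerance checks where boundary aliasing must be small."""
    objs = tuple(
        ObjectSpec(f"obj{i}", "A", (x * 0.5, y * 0.5, 16.0), (6.0, 5.5, 5.0), 0.0)
        for i, (x, y) in enumerate([(16, 16), (16, 48), (48, 16), (48, 48)])
    )
    return PhantomSpec(
        grid_shape=(64, 64, 64), spacing_mm=(0.5, 0.5, 0.5), objects=objs, seed=1
    )


def extract_table(spec, condition):
    vol, masks = generate_phantom_volume(spec, condition)
    rows = {oid: extract_all(vol, m) for oid, m in masks.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_NAMES)]


@pytest.fixture(scope="session")
def tables_190kev(phantom_spec):
    """Test and retest feature tables at 190 keV / DSDE / 15 mGy."""
    test = extract_table(phantom_spec, AcquisitionCondition(190, 15, "DSDE", 0))
    retest = extract_table(phantom_spec, AcquisitionCondition(190, 15, "DSDE", 1))
    return test, retest


def small_volume(values, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(values, dtype=float)
    return VolumeGrid(arr, spacing_mm=spacing)


def full_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return SegmentationMask(np.ones(shape, dtype=bool), spacing_mm=spacing)
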