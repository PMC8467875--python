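"""Synthetic multi-energy CT phantom and feature-table generators.

This module stands in for an ex-vivo dual-energy CT experiment: a phantom of
16 ellipsoidal objects in 4 texture classes (attenuation values chosen to
resemble fruits spanning fat- to soft-tissue-like HU), imaged as virtual
monoenergetic images (VMI) at 5 energies, 2 dose levels and 2 scanner modes,
with a test scan and a repositioned retest scan.

Two independent generators are provided:

* :func:`generate_phantom_volume` / :func:`simulate_repeat` — voxelized
  volumes plus exact per-object masks, for exercising the full feature
  extraction pipeline.
* :func:`generate_feature_table` — feature tables with *controlled*
  test–retest repeatability (a target concordance correlation coefficient per
  feature), for parameter-recovery checks of the stability statistics.

All randomness flows from explicit seeds: one scene seed (geometry and the
per-object texture seeds), and one noise seed per (condition, repeat).
Texture is a stable property of object identity — the same object carries the
same correlated texture field in every condition and repeat, rigidly moved
along with the object on repositioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .grid import SegmentationMask, VolumeGrid

__all__ = [
    "ENERGIES_KEV",
    "DOSES_MGY",
    "SCANNERS",
    "ObjectSpec",
    "AcquisitionCondition",
    "PhantomSpec",
    "FeatureTableSpec",
    "energy_transform",
    "noise_sigma",
    "generate_phantom_volume",
    "simulate_repeat",
    "generate_feature_table",
    "generate_energy_graded_tables",
    "default_phantom_spec",
]

ENERGIES_KEV: tuple[int, ...] = (40, 50, 75, 120, 190)
DOSES_MGY: tuple[int, ...] = (5, 15)
SCANNERS: tuple[str, ...] = ("DSDE", "SFDE")

BACKGROUND_HU = -1000.0

# Iodine-like contrast boost k(E) in HU per unit iodine fraction. Tabulated,
# strictly decreasing in energy, anchored at k(75 keV) = 100 HU. The shape
# follows the qualitative behaviour of iodinated structures in VMI series
# (strong enhancement at 40 keV, little above 120 keV); it is a one-parameter
# contrast law, not a beam-hardening model.
_IODINE_K: dict[int, float] = {40: 260.0, 50: 195.0, 75: 100.0, 120: 55.0, 190: 35.0}

# Energy-dependent noise multiplier g(E), minimised at 75 keV where VMI noise
# is typically lowest, rising towards both ends of the energy range.
_NOISE_G: dict[int, float] = {40: 2.0, 50: 1.5, 75: 1.0, 120: 1.15, 190: 1.35}

# Base noise level sigma0 (HU) at 75 keV / 15 mGy per scanner mode. The
# split-filter system (SFDE) is noisier than the dual-source one (DSDE).
_SIGMA0: dict[str, float] = {"DSDE": 8.0, "SFDE": 12.0}

# Spatial correlation (voxels of Gaussian smoothing) of the noise field per
# scanner; SFDE noise is slightly correlated, DSDE noise is white.
_NOISE_CORR_VOX: dict[str, float] = {"DSDE": 0.0, "SFDE": 0.6}

# VMIs at different energies are synthesized from one acquisition, so their
# noise is correlated, decorrelating as the basis-material weighting changes
# with energy. Modelled as a rotation between two base noise fields shared by
# all energies of a scan: corr(E_a, E_b) = cos(theta_a - theta_b), which
# decreases monotonically with the energy-level gap.
_VMI_NOISE_ANGLE_DEG: dict[int, float] = {40: 0.0, 50: 18.0, 75: 38.0, 120: 58.0, 190: 78.0}


@dataclass(frozen=True)
class ObjectSpec:
    """One ellipsoidal phantom object.

    ``base_hu`` is the class mean attenuation at the 75 keV reference energy;
    ``iodine_frac`` scales the energy-sensitive contrast component;
    ``texture_corr_len`` / ``texture_amp`` parameterize the object's
    stationary Gaussian texture field (mm correlation length, HU amplitude).
    """

    object_id: str
    class_label: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    base_hu: float
    iodine_frac: float = 0.0
    texture_corr_len: float = 2.0
    texture_amp: float = 0.0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"radii must be positive, got {self.radii}")
        if self.texture_amp < 0:
            raise ValueError("texture_amp must be >= 0")
        if self.iodine_frac < 0:
            raise ValueError("iodine_frac must be >= 0")


@dataclass(frozen=True)
class AcquisitionCondition:
    """A VMI reconstruction setting plus the test/retest repeat index."""

    energy_kev: int
    dose_mgy: int
    scanner: str
    repeat_id: int = 0

    def __post_init__(self) -> None:
        if self.energy_kev not in ENERGIES_KEV:
            raise ValueError(
                f"energy {self.energy_kev} keV unsupported; allowed: {ENERGIES_KEV}"
            )
        if self.dose_mgy not in DOSES_MGY:
            raise ValueError(f"dose {self.dose_mgy} mGy unsupported; allowed: {DOSES_MGY}")
        if self.scanner not in SCANNERS:
            raise ValueError(f"scanner {self.scanner!r} unsupported; allowed: {SCANNERS}")
        if self.repeat_id < 0:
            raise ValueError("repeat_id must be >= 0")

    @property
    def key(self) -> str:
        return f"{self.scanner}_{self.dose_mgy}mGy_{self.energy_kev}keV_r{self.repeat_id}"

    @property
    def condition_key(self) -> str:
        """Key ignoring the repeat index (a scan condition, not a scan)."""
        return f"{self.scanner}_{self.dose_mgy}mGy_{self.energy_kev}keV"


@dataclass(frozen=True)
class PhantomSpec:
    """Scene description: the voxel grid and the objects it contains."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    objects: tuple[ObjectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [o.object_id for o in self.objects]
        if len(set(ids)) != len(ids):
            raise ValueError("object_ids must be unique")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)


@dataclass(frozen=True)
class FeatureTableSpec:
    """Controlled-repeatability feature-table generator settings.

    Per feature ``f`` the generator draws a latent per-object value
    ``class_effect_f * class_code + N(0, tau_f^2)`` and observes it twice with
    independent noise ``N(0, sigma_f^2)``, where ``tau^2 + sigma^2 = 1`` and
    ``tau^2 / (tau^2 + sigma^2) = target_ccc``. Test and retest share the
    latent values, not the noise.
    """

    n_objects: int = 16
    n_classes: int = 4
    n_features: int = 50
    target_ccc: float | tuple[float, ...] = 0.9
    class_effect: float | tuple[float, ...] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects % self.n_classes != 0:
            raise ValueError("n_objects must be divisible by n_classes")
        ccc = np.atleast_1d(np.asarray(self.target_ccc, dtype=float))
        if np.any(ccc <= 0) or np.any(ccc > 1):
            raise ValueError("target_ccc must lie in (0, 1]")


def energy_transform(base_hu: float, iodine_frac: float, energy_kev: int) -> float:
    """Mean attenuation of a material at a given VMI energy.

    Returns ``base_hu + iodine_frac * k(E)`` with the tabulated, strictly
    decreasing contrast law ``k`` (``k(75) = 100`` HU). Attenuation is
    therefore non-increasing in energy whenever an energy-sensitive
    component is present.
    """
    if energy_kev not in _IODINE_K:
        raise ValueError(
            f"energy {energy_kev} keV unsupported; allowed: {tuple(_IODINE_K)}"
        )
    return float(base_hu) + float(iodine_frac) * _IODINE_K[energy_kev]


def noise_sigma(condition: AcquisitionCondition) -> float:
    """Voxel noise standard deviation (HU) for an acquisition condition.

    ``sigma = sigma0(scanner) * g(energy) * sqrt(15 / dose)``: noise follows
    the inverse-square-root dose law, is lowest at 75 keV, and is higher for
    the split-filter (SFDE) than for the dual-source (DSDE) mode.
    """
    return (
        _SIGMA0[condition.scanner]
        * _NOISE_G[condition.energy_kev]
        * math.sqrt(15.0 / condition.dose_mgy)
    )


# ---------------------------------------------------------------------------
# scene geometry
# ---------------------------------------------------------------------------


def _repeat_transform(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded rigid repositioning for the retest scan.

    Returns ``(R, pivot, shift)`` such that a canonical scene point ``p`` maps
    to ``R @ (p - pivot) + pivot + shift``. Translation is bounded by 2 mm in
    plane / 1 mm axially and rotation by 3 degrees about z — a plausible
    manual repositioning, safely inside the 5 mm / 5 degree contract.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7001]))
    shift = np.array(
        [rng.uniform(-2.0, 2.0), rng.uniform(-2.0, 2.0), rng.uniform(-1.0, 1.0)]
    )
    theta = math.radians(rng.uniform(-3.0, 3.0))
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    pivot = spec.extent_mm / 2.0
    return rot, pivot, shift


_IDENTITY = (np.eye(3), np.zeros(3), np.zeros(3))


def _transform_points(pts: np.ndarray, tf) -> np.ndarray:
    rot, pivot, shift = tf
    return (pts - pivot) @ rot.T + pivot + shift


def _inv_transform_points(pts: np.ndarray, tf) -> np.ndarray:
    rot, pivot, shift = tf
    return (pts - pivot - shift) @ rot + pivot


def _object_texture_seed(spec: PhantomSpec, obj_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([spec.seed, 1000 + obj_index])


_TEXTURE_MARGIN_VOX = 6


def _texture_block(
    spec: PhantomSpec, obj_index: int, obj: ObjectSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical unit-variance Gaussian texture field around an object.

    The block is anchored in the scene's canonical (repeat-0) frame; its
    world origin is returned alongside. Smoothing a white field with a
    Gaussian kernel of width ``texture_corr_len`` yields a stationary field
    with that correlation length.
    """
    spacing = np.asarray(spec.spacing_mm)
    lo = np.floor((np.asarray(obj.center) - np.asarray(obj.radii)) / spacing).astype(int)
    hi = np.ceil((np.asarray(obj.center) + np.asarray(obj.radii)) / spacing).astype(int)
    lo -= _TEXTURE_MARGIN_VOX
    hi += _TEXTURE_MARGIN_VOX
    shape = tuple(hi - lo + 1)
    rng = np.random.default_rng(_object_texture_seed(spec, obj_index))
    white = rng.standard_normal(shape)
    sigma_vox = np.asarray(obj.texture_corr_len) / spacing
    fld = gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = fld.std()
    if sd > 0:
        fld = fld / sd
    origin = lo * spacing
    return fld, origin


def _check_inside_grid(spec: PhantomSpec, obj: ObjectSpec, tf) -> None:
    """Error if the (transformed) ellipsoid's bounding box leaves the grid."""
    center = _transform_points(np.asarray(obj.center)[None, :], tf)[0]
    rot = tf[0]
    # axis-aligned half-extent of a rotated ellipsoid: |R diag(r)| row norms
    half = np.sqrt(((rot * np.asarray(obj.radii)) ** 2).sum(axis=1))
    extent = spec.extent_mm
    if np.any(center - half < 0) or np.any(center + half > extent):
        raise ValueError(
            f"object {obj.object_id!r} extends outside the grid "
            f"(center {np.round(center, 2).tolist()} mm, half-extent "
            f"{np.round(half, 2).tolist()} mm, grid extent {extent.tolist()} mm)"
        )


def _voxel_centers(spec: PhantomSpec, sl: tuple[slice, slice, slice]) -> np.ndarray:
    """World coordinates (voxel centers) of a subgrid, shape (..., 3)."""
    spacing = np.asarray(spec.spacing_mm)
    axes = [
        (np.arange(s.start, s.stop) + 0.5) * spacing[i] for i, s in enumerate(sl)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def _noise_seed(
    spec: PhantomSpec,
    condition: AcquisitionCondition,
    seed: int | None,
    channel: int,
) -> np.random.SeedSequence:
    """Seed for one base noise field of a scan.

    Deliberately independent of energy: all VMI energies of one
    (scanner, dose, repeat) acquisition share the same two base fields."""
    base = spec.seed if seed is None else seed
    return np.random.SeedSequence(
        [
            base,
            DOSES_MGY.index(condition.dose_mgy),
            SCANNERS.index(condition.scanner),
            condition.repeat_id,
            9000 + channel,
        ]
    )


def generate_phantom_volume(
    spec: PhantomSpec,
    condition: AcquisitionCondition,
    seed: int | None = None,
    noise_scale: float = 1.0,
) -> tuple[VolumeGrid, dict[str, SegmentationMask]]:
    """Voxelize the phantom scene under one acquisition condition.

    In-object voxels receive the class mean from :func:`energy_transform`,
    plus the object's correlated texture field (a stable property of object
    identity), plus independent acquisition noise of standard deviation
    :func:`noise_sigma`. Background is air (−1000 HU). Masks are the exact
    ellipsoid membership of each object; for ``repeat_id == 1`` the whole
    scene is rigidly repositioned first (see :func:`simulate_repeat`).

    ``seed`` overrides the noise seed base (defaults to ``spec.seed``);
    geometry and texture always derive from ``spec.seed`` alone.
    ``noise_scale`` multiplies the noise standard deviation (0 renders a
    noise-free scene, useful for validating means and masks).
    """
    tf = _repeat_transform(spec) if condition.repeat_id >= 1 else _IDENTITY
    return _render(spec, condition, tf, seed, noise_scale)


def simulate_repeat(
    spec: PhantomSpec,
    condition: AcquisitionCondition,
    seed: int | None = None,
    noise_scale: float = 1.0,
) -> tuple[VolumeGrid, dict[str, SegmentationMask]]:
    """Retest scan: rigid scene repositioning, then fresh acquisition noise.

    Object identity (hence each object's texture field) is preserved; only
    the scene pose and the noise realization change.
    """
    if condition.repeat_id != 1:
        raise ValueError("simulate_repeat requires condition.repeat_id == 1")
    return _render(spec, condition, _repeat_transform(spec), seed, noise_scale)


def _render(
    spec: PhantomSpec,
    condition: AcquisitionCondition,
    tf,
    seed: int | None,
    noise_scale: float = 1.0,
) -> tuple[VolumeGrid, dict[str, SegmentationMask]]:
    if not spec.objects:
        raise ValueError("phantom has no objects")
    for obj in spec.objects:
        _check_inside_grid(spec, obj, tf)

    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm)
    vol = np.full(shape, BACKGROUND_HU, dtype=float)
    masks: dict[str, SegmentationMask] = {}
    claimed = np.zeros(shape, dtype=bool)

    for idx, obj in enumerate(spec.objects):
        # transformed bounding box of the ellipsoid, in voxel indices
        center_t = _transform_points(np.asarray(obj.center)[None, :], tf)[0]
        half = np.sqrt(((tf[0] * np.asarray(obj.radii)) ** 2).sum(axis=1))
        lo = np.maximum(np.floor((center_t - half) / spacing).astype(int) - 1, 0)
        hi = np.minimum(
            np.ceil((center_t + half) / spacing).astype(int) + 1, np.asarray(shape)
        )
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        pts = _voxel_centers(spec, sl)
        canon = _inv_transform_points(pts.reshape(-1, 3), tf)
        rel = (canon - np.asarray(obj.center)) / np.asarray(obj.radii)
        inside = (rel**2).sum(axis=1) <= 1.0
        inside_box = inside.reshape(pts.shape[:-1])

        if claimed[sl][inside_box].any():
            raise ValueError(f"object {obj.object_id!r} overlaps a previous object")
        claimed[sl][inside_box] = True

        mean_hu = energy_transform(obj.base_hu, obj.iodine_frac, condition.energy_kev)
        values = np.full(inside.shape, np.nan)
        values[inside] = mean_hu
        if obj.texture_amp > 0:
            block, block_origin = _texture_block(spec, idx, obj)
            coords = (canon[inside] - block_origin) / spacing - 0.5
            tex = map_coordinates(block, coords.T, order=1, mode="nearest")
            values[inside] += obj.texture_amp * tex
        box = vol[sl]
        box[inside_box] = values.reshape(inside_box.shape)[inside_box]
        vol[sl] = box

        mvol = np.zeros(shape, dtype=bool)
        mvol[sl] = inside_box
        masks[obj.object_id] = SegmentationMask(
            mvol, spacing_mm=spec.spacing_mm, origin_mm=(0.0, 0.0, 0.0)
        )

    sigma = noise_sigma(condition) * noise_scale
    if sigma > 0:
        fields = []
        corr = _NOISE_CORR_VOX[condition.scanner]
        for channel in (0, 1):
            rng = np.random.default_rng(_noise_seed(spec, condition, seed, channel))
            f = rng.standard_normal(shape)
            if corr > 0:
                f = gaussian_filter(f, sigma=corr, mode="wrap")
                f /= f.std()
            fields.append(f)
        theta = math.radians(_VMI_NOISE_ANGLE_DEG[condition.energy_kev])
        noise = math.cos(theta) * fields[0] + math.sin(theta) * fields[1]
        vol += sigma * noise

    volume = VolumeGrid(vol, spacing_mm=spec.spacing_mm, origin_mm=(0.0, 0.0, 0.0))
    return volume, masks


# ---------------------------------------------------------------------------
# default phantom
# ---------------------------------------------------------------------------

# Class mean attenuations (HU at the 75 keV reference) resemble fat-, water-
# and soft-tissue-like produce; iodine fractions, shapes and texture scales
# are free design parameters chosen to give four visually and statistically
# distinct classes.
_CLASS_DEFAULTS = {
    # label: (base_hu, iodine_frac, radii_mm, corr_len_mm, amp_hu)
    # four clearly distinct shape/texture archetypes: a near-sphere with
    # medium-grain flesh, a strongly oblate layered bulb, a large sphere with
    # fine pith texture, and a prolate berry with coarse high-contrast flesh
    "apple": (-179.0, 0.2, (5.0, 4.9, 4.7), 3.0, 18.0),
    "onion": (-29.0, 0.4, (5.6, 5.4, 3.6), 4.5, 25.0),
    "orange": (-5.0, 0.6, (5.5, 5.5, 5.5), 1.2, 30.0),
    "kiwifruit": (45.0, 0.8, (5.6, 4.0, 4.0), 1.8, 40.0),
}


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """16 objects (4 per class) on a 4x4 lattice in a 64 mm cube at 1 mm.

    Within-class shape variability is a seeded ±4% jitter of the class radii,
    mimicking natural size variation among objects of the same kind.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 42]))
    centers_1d = (9.5, 24.5, 39.5, 54.5)
    labels = list(_CLASS_DEFAULTS)
    objects: list[ObjectSpec] = []
    positions = [(x, y) for x in centers_1d for y in centers_1d]
    for i, (x, y) in enumerate(positions):
        label = labels[i % 4]
        base_hu, iodine, radii, corr, amp = _CLASS_DEFAULTS[label]
        jit = 1.0 + rng.uniform(-0.04, 0.04, size=3)
        objects.append(
            ObjectSpec(
                object_id=f"{label}_{i // 4}",
                class_label=label,
                center=(x, y, 32.0),
                radii=tuple(float(r * j) for r, j in zip(radii, jit)),
                base_hu=base_hu,
                iodine_frac=iodine,
                texture_corr_len=corr,
                texture_amp=amp,
            )
        )
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        spacing_mm=(1.0, 1.0, 1.0),
        objects=tuple(objects),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# controlled-repeatability feature tables
# ---------------------------------------------------------------------------


def _spec_arrays(spec: FeatureTableSpec) -> tuple[np.ndarray, np.ndarray]:
    ccc = np.broadcast_to(
        np.asarray(spec.target_ccc, dtype=float), (spec.n_features,)
    ).copy()
    eff = np.broadcast_to(
        np.asarray(spec.class_effect, dtype=float), (spec.n_features,)
    ).copy()
    return ccc, eff


def _class_codes(n_objects: int, n_classes: int) -> tuple[np.ndarray, pd.Series]:
    per = n_objects // n_classes
    idx = np.repeat(np.arange(n_classes), per)
    labels = pd.Series(
        [f"class_{chr(ord('A') + k)}" for k in idx],
        index=[f"obj_{i:04d}" for i in range(n_objects)],
        name="class_label",
    )
    codes = (idx - idx.mean()) / idx.std()  # standardized class code
    return codes, labels


def generate_feature_table(
    spec: FeatureTableSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Test and retest feature tables with controlled repeatability.

    Latent per-object values are shared between test and retest; repeat noise
    is independent. With total unit variance split as
    ``tau^2 = target_ccc`` (between objects) and ``sigma^2 = 1 - target_ccc``
    (within repeats), the population CCC of a feature equals its target.
    A nonzero ``class_effect`` adds a standardized between-class shift on top
    of the latent variance (raising the realized CCC above the target).

    Returns ``(test, retest, class_labels)``; tables are objects x features.
    """
    ccc, eff = _spec_arrays(spec)
    tau = np.sqrt(ccc)
    sig = np.sqrt(1.0 - ccc)
    codes, labels = _class_codes(spec.n_objects, spec.n_classes)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2024]))
    latent = eff[None, :] * codes[:, None] + tau[None, :] * rng.standard_normal(
        (spec.n_objects, spec.n_features)
    )
    noise_t = sig[None, :] * rng.standard_normal(latent.shape)
    noise_r = sig[None, :] * rng.standard_normal(latent.shape)
    cols = [f"synth/f{j:03d}" for j in range(spec.n_features)]
    test = pd.DataFrame(latent + noise_t, index=labels.index, columns=cols)
    retest = pd.DataFrame(latent + noise_r, index=labels.index, columns=cols)
    return test, retest, labels


def generate_energy_graded_tables(
    spec: FeatureTableSpec,
    n_levels: int = 5,
    drift_sd: float = 0.35,
) -> tuple[dict[int, pd.DataFrame], pd.Series]:
    """Feature tables whose agreement decays with energy-level separation.

    Condition-to-condition drift is a per-feature Gaussian random walk across
    the ordered energy levels (step s.d. ``drift_sd`` in latent units), so
    the expected concordance between two levels decreases monotonically with
    their separation — the energy-gap reproducibility gradient seen in VMI
    series. Returns ``{level_index: table}`` plus class labels.
    """
    ccc, eff = _spec_arrays(spec)
    tau = np.sqrt(ccc)
    sig = np.sqrt(1.0 - ccc)
    codes, labels = _class_codes(spec.n_objects, spec.n_classes)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 5150]))
    latent = eff[None, :] * codes[:, None] + tau[None, :] * rng.standard_normal(
        (spec.n_objects, spec.n_features)
    )
    cols = [f"synth/f{j:03d}" for j in range(spec.n_features)]
    tables: dict[int, pd.DataFrame] = {}
    drift = np.zeros_like(latent)
    for lvl in range(n_levels):
        if lvl > 0:
            drift = drift + drift_sd * rng.standard_normal(latent.shape)
        noise = sig[None, :] * rng.standard_normal(latent.shape)
        tables[lvl] = pd.DataFrame(
            latent + drift + noise, index=labels.index, columns=cols
        )
    return tables, labels
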