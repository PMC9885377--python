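"""Synthetic data generators for every pitfall experiment.

Each generator emulates the *statistical structure* of a class of medical
imaging data — not its appearance — so that a methodological pitfall can be
demonstrated (or shown to be absent under correct handling) at desk scale:

* :func:`gen_tabular` — radiomics-like feature tables, one row per patient,
  optionally imbalanced, with a controllable class signal.
* :func:`gen_patient_patches` — many rows per patient sharing a
  patient-specific feature signature (image patches from one patient share
  characteristics such as staining and scanner settings).
* :func:`gen_ct_volume` — a CT-like volume containing two lungs, an airway,
  bowel gas, body soft tissue and exterior air, with ground-truth masks.
* :func:`gen_batch_dataset` — a two-source classification set in which the
  class label is perfectly confounded with the acquisition source, plus an
  external set that breaks the confound.
* :func:`gen_synthetic_slide` — a large RGB image with tissue-coloured
  foreground blobs on a near-white background, emulating a whole-slide image.

Noise is standard Gaussian throughout; "signals" are mean shifts along fixed
random unit directions.  Every generator is deterministic given its config:
one master ``seed`` per config, with independent sub-streams derived from it
by fixed offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .table import LabeledTable
from .volumes import BinaryMask3D, CTVolume

__all__ = [
    "TabularConfig",
    "PatchConfig",
    "Ellipsoid",
    "VolumeSpec",
    "BatchConfig",
    "SlideConfig",
    "gen_tabular",
    "gen_patient_patches",
    "gen_ct_volume",
    "gen_batch_dataset",
    "gen_synthetic_slide",
    "synthetic_volume_cohort",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Sub-stream ``stream`` of master ``seed`` (fixed-offset derivation)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _unit_direction(rng: np.random.Generator, p: int) -> np.ndarray:
    v = rng.standard_normal(p)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Tabular (radiomics-like) data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TabularConfig:
    """One feature vector per patient, with optional class imbalance and signal.

    ``signal_strength`` is the standardized mean difference between the
    class-conditional feature means (0 = pure noise, labels carry no
    information about the features).
    """

    n_patients: int = 100
    n_features: int = 10
    class_fraction: float = 0.5
    signal_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ConfigurationError("n_patients must be >= 4")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if not 0.0 < self.class_fraction < 1.0:
            raise ConfigurationError("class_fraction must lie in (0, 1)")
        if self.signal_strength < 0:
            raise ConfigurationError("signal_strength must be >= 0")


def gen_tabular(config: TabularConfig) -> LabeledTable:
    """Generate an imbalanced radiomics-like table, one sample per patient.

    Exactly ``round(class_fraction * n_patients)`` samples are positive;
    positives are shifted by ``signal_strength`` along a fixed random unit
    direction in feature space.
    """
    n, p = config.n_patients, config.n_features
    n_pos = _round_half_up(config.class_fraction * n)
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    labels = labels[_rng(config.seed, 0).permutation(n)]

    features = _rng(config.seed, 1).standard_normal((n, p))
    if config.signal_strength > 0:
        direction = _unit_direction(_rng(config.seed, 2), p)
        features[labels == 1] += config.signal_strength * direction

    patient_id = np.array([f"P{i:04d}" for i in range(n)], dtype=object)
    return LabeledTable(
        features=features,
        labels=labels,
        patient_id=patient_id,
        sample_id=patient_id.copy(),
    )


# ---------------------------------------------------------------------------
# Per-patient patch collections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchConfig:
    """Many rows per patient; rows of one patient share a signature offset.

    The signature offset is drawn once per patient from a Gaussian of SD
    ``signature_strength`` and added to all of that patient's rows, mimicking
    image characteristics shared by patches of the same slide or scan.  The
    class label is constant within a patient.  ``jitter_sigma`` is the SD used
    when these rows are later augmented; it is stored here so an experiment
    config fully describes the data conditions.
    """

    n_patients: int = 20
    patches_per_patient: int = 30
    n_features: int = 10
    signature_strength: float = 3.0
    class_signal: float = 0.0
    jitter_sigma: float = 0.1
    class_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ConfigurationError("n_patients must be >= 4")
        if self.patches_per_patient < 1:
            raise ConfigurationError("patches_per_patient must be >= 1")
        if self.signature_strength < 0 or self.class_signal < 0:
            raise ConfigurationError("signal magnitudes must be >= 0")
        if not 0.0 < self.class_fraction < 1.0:
            raise ConfigurationError("class_fraction must lie in (0, 1)")


def gen_patient_patches(config: PatchConfig) -> LabeledTable:
    """Generate patch-level rows with patient-level labels and signatures."""
    n_pat, k, p = config.n_patients, config.patches_per_patient, config.n_features
    n_pos = _round_half_up(config.class_fraction * n_pat)
    patient_labels = np.zeros(n_pat, dtype=int)
    patient_labels[:n_pos] = 1
    patient_labels = patient_labels[_rng(config.seed, 0).permutation(n_pat)]

    signatures = _rng(config.seed, 1).normal(
        0.0, config.signature_strength, size=(n_pat, p)
    )
    direction = _unit_direction(_rng(config.seed, 2), p)
    noise = _rng(config.seed, 3).standard_normal((n_pat * k, p))

    features = np.empty((n_pat * k, p))
    labels = np.empty(n_pat * k, dtype=int)
    patient_id = np.empty(n_pat * k, dtype=object)
    for i in range(n_pat):
        rows = slice(i * k, (i + 1) * k)
        features[rows] = (
            noise[rows]
            + signatures[i]
            + config.class_signal * patient_labels[i] * direction
        )
        labels[rows] = patient_labels[i]
        patient_id[rows] = f"P{i:04d}"

    sample_id = np.array(
        [f"P{i:04d}.{j}" for i in range(n_pat) for j in range(k)], dtype=object
    )
    return LabeledTable(
        features=features, labels=labels, patient_id=patient_id, sample_id=sample_id
    )


# ---------------------------------------------------------------------------
# CT-like volumes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in coordinates normalised to [-1, 1] per axis."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains(self, coords: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """Boolean mask of points inside the ellipsoid shrunk by ``scale``."""
        q = np.zeros(coords.shape[:-1])
        for ax in range(3):
            q += ((coords[..., ax] - self.center[ax]) / (self.semi_axes[ax] * scale)) ** 2
        return q <= 1.0


def _default_lungs() -> tuple[Ellipsoid, Ellipsoid]:
    return (
        Ellipsoid(center=(-0.40, 0.0, 0.18), semi_axes=(0.26, 0.40, 0.48)),
        Ellipsoid(center=(0.40, 0.0, 0.18), semi_axes=(0.26, 0.40, 0.48)),
    )


@dataclass(frozen=True)
class VolumeSpec:
    """Geometry and intensity model of a synthetic CT volume.

    The body is an ellipsoid of soft tissue surrounded by exterior air; the
    two lungs are air-filled ellipsoids inside it.  Non-lung internal air (an
    airway tube between the lungs and bowel-gas pockets low in the body) is
    sized relative to the lung volume via ``airway_fraction`` and
    ``bowel_gas_fraction``.  Default intensities — tissue 40 ± 20 HU, air
    −1000 ± 30 HU, noise clipped at ±5 SD — keep air and tissue separated by
    far more than 3 SD on either side of the −400 HU air threshold.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    hu_tissue: float = 40.0
    hu_tissue_sd: float = 20.0
    hu_air: float = -1000.0
    hu_air_sd: float = 30.0
    body: Ellipsoid = field(default_factory=lambda: Ellipsoid((0.0, 0.0, 0.0), (0.85, 0.85, 0.92)))
    lungs: tuple[Ellipsoid, Ellipsoid] = field(default_factory=_default_lungs)
    airway_fraction: float = 0.05
    bowel_gas_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be >= 8 per axis")
        if self.airway_fraction < 0 or self.bowel_gas_fraction < 0:
            raise ConfigurationError("air fractions must be >= 0")
        lo = self.hu_air + 5 * self.hu_air_sd
        hi = self.hu_tissue - 5 * self.hu_tissue_sd
        if not (lo < -400.0 - 3 * self.hu_air_sd and hi > -400.0 + 3 * self.hu_tissue_sd):
            raise ConfigurationError(
                "air and tissue HU distributions must be separated from -400 "
                "by at least 3 SD each"
            )


def _grid_coords(shape: tuple[int, int, int]) -> np.ndarray:
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _take_nearest(
    candidate: np.ndarray, distance: np.ndarray, target: int
) -> np.ndarray:
    """Keep the ``target`` candidate voxels with smallest ``distance``.

    Ties are broken by flat voxel index, so the result is deterministic.
    """
    flat_idx = np.flatnonzero(candidate.ravel())
    if target > flat_idx.size:
        raise ConfigurationError(
            f"air pocket needs {target} voxels but only {flat_idx.size} fit; "
            "reduce the fraction or enlarge the grid"
        )
    order = np.lexsort((flat_idx, distance.ravel()[flat_idx]))
    chosen = flat_idx[order[:target]]
    out = np.zeros(candidate.size, dtype=bool)
    out[chosen] = True
    return out.reshape(candidate.shape)


def gen_ct_volume(
    spec: VolumeSpec,
) -> tuple[CTVolume, BinaryMask3D, BinaryMask3D]:
    """Generate a CT-like volume plus lung and internal-air ground truths.

    Returns ``(volume, lung_truth, internal_air_truth)`` with
    ``lung_truth ⊆ internal_air_truth``.  The non-lung internal air totals
    ``(airway_fraction + bowel_gas_fraction) × |lung|`` voxels exactly (up to
    rounding), so overlap scores of the internal-air proxy against the lung
    truth have a closed form in the voxel counts.  By construction the set
    ``{HU < −400}`` inside the body equals the internal-air truth exactly, and
    no internal air voxel touches the exterior air.
    """
    coords = _grid_coords(spec.grid_shape)
    body = spec.body.contains(coords)
    # tissue shell: internal air must stay clear of the body surface
    body_core = spec.body.contains(coords, scale=0.9)

    lungs = np.zeros(spec.grid_shape, dtype=bool)
    for lung in spec.lungs:
        lungs |= lung.contains(coords)
    if lungs.sum() == 0:
        raise ConfigurationError("lung geometry produced no voxels")
    if (lungs & ~body_core).any():
        raise ConfigurationError("lungs must lie strictly inside the body")

    n_lung = int(lungs.sum())

    # airway: thin tube on the midline between the lungs, above body centre
    x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]
    radial = np.sqrt(x**2 + y**2)
    airway_candidate = body_core & ~lungs & (radial < 0.22) & (z > -0.05) & (z < 0.75)
    airway = _take_nearest(
        airway_candidate, radial, _round_half_up(spec.airway_fraction * n_lung)
    )

    # bowel gas: pocket low in the body
    bowel_center = np.array([0.0, 0.0, -0.55])
    d_bowel = np.sqrt(((coords - bowel_center) ** 2).sum(axis=-1))
    bowel_candidate = body_core & ~lungs & ~airway & (d_bowel < 0.38)
    bowel = _take_nearest(
        bowel_candidate, d_bowel, _round_half_up(spec.bowel_gas_fraction * n_lung)
    )

    internal_air = lungs | airway | bowel
    air = internal_air | ~body

    rng = _rng(spec.seed, 0)
    noise = np.clip(rng.standard_normal(spec.grid_shape), -5.0, 5.0)
    hu = np.where(
        air,
        spec.hu_air + spec.hu_air_sd * noise,
        spec.hu_tissue + spec.hu_tissue_sd * noise,
    )

    volume = CTVolume(hu=hu, spacing=spec.spacing)
    return (
        volume,
        BinaryMask3D(lungs, spacing=spec.spacing),
        BinaryMask3D(internal_air, spacing=spec.spacing),
    )


def synthetic_volume_cohort(
    n_volumes: int, seed: int = 0, base: VolumeSpec | None = None
) -> list[tuple[CTVolume, BinaryMask3D, BinaryMask3D]]:
    """A cohort of volumes whose non-lung air burden varies across patients.

    The total extra-air fraction is drawn uniformly in [0.08, 0.26] of the
    lung volume (split 40/60 between airway and bowel gas), so the cohort's
    internal-air proxy Dice scores spread around ≈0.92 while every volume
    still contains non-lung air.
    """
    if n_volumes < 1:
        raise ConfigurationError("n_volumes must be >= 1")
    base = base or VolumeSpec()
    rng = _rng(seed, 100)
    cohort = []
    for i in range(n_volumes):
        extra = rng.uniform(0.08, 0.26)
        spec = replace(
            base,
            airway_fraction=0.4 * extra,
            bowel_gas_fraction=0.6 * extra,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append(gen_ct_volume(spec))
    return cohort


# ---------------------------------------------------------------------------
# Batch-effect data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BatchConfig:
    """Two-source dataset with the class label confounded with the source.

    The internal dataset takes every class-0 sample from source A and every
    class-1 sample from source B; each source adds its own signature offset of
    magnitude ``signature_strength`` to the features.  The two signature
    directions are orthogonal, so the centroid separation the parameter
    induces is ``signature_strength·√2`` regardless of seed.  With
    ``intrinsic_signal = 0`` the label carries no information beyond the
    source signature, so a classifier can only learn the batch effect.  The
    external dataset contains class-0 samples bearing source B's signature:
    it breaks the confound the way normal pediatric radiographs break a
    pneumonia-children / normal-adults confound.
    """

    n_per_source: int = 500
    n_features: int = 10
    signature_strength: float = 3.0
    intrinsic_signal: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_source < 2:
            raise ConfigurationError("n_per_source must be >= 2")
        if self.signature_strength < 0 or self.intrinsic_signal < 0:
            raise ConfigurationError("signal magnitudes must be >= 0")


def gen_batch_dataset(config: BatchConfig) -> tuple[LabeledTable, LabeledTable]:
    """Generate ``(internal, external)`` tables with a perfect source/label confound."""
    n, p = config.n_per_source, config.n_features
    dir_rng = _rng(config.seed, 0)
    u = _unit_direction(dir_rng, p)
    v = _unit_direction(dir_rng, p)
    v -= (v @ u) * u  # orthogonal source signatures: separation is exactly s·√2
    v /= np.linalg.norm(v)
    sig_a = config.signature_strength * u
    sig_b = config.signature_strength * v
    class_dir = _unit_direction(dir_rng, p)

    noise = _rng(config.seed, 1).standard_normal((3 * n, p))
    feats_a0 = noise[:n] + sig_a  # internal: source A, class 0
    feats_b1 = noise[n : 2 * n] + sig_b + config.intrinsic_signal * class_dir
    feats_ext = noise[2 * n :] + sig_b  # external: source B, class 0

    internal = LabeledTable(
        features=np.vstack([feats_a0, feats_b1]),
        labels=np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)]),
        patient_id=np.array(
            [f"A{i:04d}" for i in range(n)] + [f"B{i:04d}" for i in range(n)],
            dtype=object,
        ),
        source_id=np.array(["A"] * n + ["B"] * n, dtype=object),
    )
    external = LabeledTable(
        features=feats_ext,
        labels=np.zeros(n, dtype=int),
        patient_id=np.array([f"X{i:04d}" for i in range(n)], dtype=object),
        source_id=np.array(["B"] * n, dtype=object),
    )
    return internal, external


# ---------------------------------------------------------------------------
# Slide-like RGB images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SlideConfig:
    """Slide-like RGB image: tissue-coloured blobs on a near-white background."""

    n_images: int = 1
    image_shape: tuple[int, int] = (512, 512)
    foreground_fraction: float = 0.5
    background_color: tuple[int, int, int] = (245, 245, 245)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 0:
            raise ConfigurationError("n_images must be >= 0")
        if any(s < 8 for s in self.image_shape):
            raise ConfigurationError("image_shape must be >= 8 per axis")
        if not 0.0 <= self.foreground_fraction <= 1.0:
            raise ConfigurationError("foreground_fraction must lie in [0, 1]")


_TISSUE_BASE = np.array([168.0, 96.0, 156.0])  # hematoxylin-eosin-ish purple/pink


def gen_synthetic_slide(
    config: SlideConfig, image_index: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one slide-like RGB uint8 image and its foreground truth mask.

    Random tissue-coloured disks are stamped onto a near-white background
    until the covered fraction reaches ``foreground_fraction``; the achieved
    fraction overshoots by at most one disk's area.  ``image_index`` selects
    an independent sub-stream so a collection of slides shares one config.
    """
    h, w = config.image_shape
    rng = _rng(config.seed, 1000 + image_index)
    mask = np.zeros((h, w), dtype=bool)
    target = config.foreground_fraction * h * w

    if config.foreground_fraction >= 1.0:
        mask[:] = True
    elif config.foreground_fraction > 0.0:
        rows, cols = np.mgrid[0:h, 0:w]
        min_dim = min(h, w)
        for _ in range(100_000):
            if mask.sum() >= target:
                break
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            radius = rng.uniform(0.04, 0.09) * min_dim
            mask |= (rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2

    image = np.empty((h, w, 3))
    image[:] = np.array(config.background_color, dtype=float)
    image += rng.normal(0.0, 2.0, size=image.shape)
    blob_tint = rng.normal(0.0, 12.0, size=3)
    tissue = _TISSUE_BASE + blob_tint + rng.normal(0.0, 8.0, size=(h, w, 3))
    image[mask] = np.clip(tissue, 0, 205)[mask]
    return np.clip(np.rint(image), 0, 255).astype(np.uint8), mask
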