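"""Synthetic Dixon phantoms and paired cohorts with known ground truth.

The phantom emulates the segmented upper-airway anatomy on a small voxel
grid: an air-filled pharyngeal tube flanked by lateral-wall slabs and
parapharyngeal fat-pad lobes, a tongue and tongue-base ellipsoid pair
anterior to it, and a soft-palate ellipsoid at the top of the airway.
Each tissue carries a uniform ground-truth fat fraction f (percent); its
channel signals follow the two-point Dixon model

    water    = A * (1 - f/100)
    fat      = A * f/100
    in-phase = fat + water,   out-of-phase = |water - fat|

with amplitude A and, optionally, Rician noise of scale sigma applied
independently per channel (magnitude-MRI noise: the modulus of the signal
plus complex Gaussian noise). Airway and background voxels carry zero
signal, so the fat fraction is undefined there at threshold 0.

Paired cohorts are drawn from a per-metric bivariate normal over
(baseline, follow-up), parameterised by the baseline mean/SD, the mean
change, and either the change SD plus pre/post correlation or the
follow-up SD. Ground-truth records accompany every generator output so
recovery can be tested end to end. All outputs are bit-reproducible under
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_stats import PairedCohortTable
from .errors import PhantomSpecError
from .volume_io import DixonSet, LabelMask, VolumeImage
from .volumetrics import AirwayLandmarks

#: Overlap priority, highest first: a voxel claimed by several geometries is
#: assigned to the highest-priority structure, keeping masks disjoint.
STRUCTURE_PRIORITY = (
    "airway",
    "fat_pads",
    "lat_wall_velo",
    "lat_wall_oro",
    "soft_palate",
    "tongue_base",
    "tongue",
)


# ---------------------------------------------------------------------------
# Geometry primitives (coordinates and sizes in mm)


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def scale(self, volume_factor: float) -> "Ellipsoid":
        s = volume_factor ** (1.0 / 3.0)
        return Ellipsoid(self.center, tuple(r * s for r in self.radii))

    def voxelize(self, shape, spacing) -> np.ndarray:
        coords = _grids(shape, spacing)
        q = sum(((c - c0) / r) ** 2 for c, c0, r in zip(coords, self.center, self.radii))
        return q <= 1.0


@dataclass(frozen=True)
class Box:
    center: tuple[float, float, float]
    half_sizes: tuple[float, float, float]

    def scale(self, volume_factor: float) -> "Box":
        s = volume_factor ** (1.0 / 3.0)
        return Box(self.center, tuple(h * s for h in self.half_sizes))

    def voxelize(self, shape, spacing) -> np.ndarray:
        coords = _grids(shape, spacing)
        inside = np.ones(shape, dtype=bool)
        for c, c0, h in zip(coords, self.center, self.half_sizes):
            inside &= np.abs(c - c0) <= h
        return inside


@dataclass(frozen=True)
class Tube:
    """Axial cylinder: in-plane circle over an inclusive slice range."""

    center_xy: tuple[float, float]
    radius: float
    slice_range: tuple[int, int]

    def scale(self, volume_factor: float) -> "Tube":
        # slice extent is anatomically pinned; shrinkage acts in-plane
        return Tube(self.center_xy, self.radius * volume_factor**0.5, self.slice_range)

    def voxelize(self, shape, spacing) -> np.ndarray:
        x, y, _ = _grids(shape, spacing)
        inplane = (x - self.center_xy[0]) ** 2 + (y - self.center_xy[1]) ** 2 <= self.radius**2
        inside = np.zeros(shape, dtype=bool)
        lo, hi = self.slice_range
        inside[:, :, lo : hi + 1] = inplane  # disc has singleton z; broadcasts over slices
        return inside


Shape3D = Ellipsoid | Box | Tube


def _grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


# ---------------------------------------------------------------------------
# Phantom specification


def _default_geometry() -> dict[str, tuple[Shape3D, ...]]:
    """Stylised upper-airway anatomy on a 64 mm cube.

    x: left-right, y: anterior-posterior (posterior = large y),
    z: axial, superior (slice 0) to inferior.
    """
    return {
        "airway": (Tube(center_xy=(32.0, 42.0), radius=4.0, slice_range=(10, 54)),),
        "tongue": (Ellipsoid(center=(32.0, 24.0, 20.0), radii=(14.0, 12.0, 10.0)),),
        "tongue_base": (Ellipsoid(center=(32.0, 28.0, 36.0), radii=(12.0, 10.0, 8.0)),),
        "soft_palate": (Ellipsoid(center=(32.0, 36.0, 14.0), radii=(8.0, 5.0, 6.0)),),
        "lat_wall_velo": (
            Box(center=(22.0, 42.0, 18.0), half_sizes=(4.0, 5.0, 6.0)),
            Box(center=(42.0, 42.0, 18.0), half_sizes=(4.0, 5.0, 6.0)),
        ),
        "lat_wall_oro": (
            Box(center=(22.0, 42.0, 31.0), half_sizes=(4.0, 5.0, 7.0)),
            Box(center=(42.0, 42.0, 31.0), half_sizes=(4.0, 5.0, 7.0)),
        ),
        "fat_pads": (
            Ellipsoid(center=(14.0, 42.0, 22.0), radii=(4.0, 4.0, 6.0)),
            Ellipsoid(center=(50.0, 42.0, 22.0), radii=(4.0, 4.0, 6.0)),
        ),
    }


#: Ground-truth tissue fat fractions (%). Muscular tissues sit in the
#: 20-30% range typical of obese upper-airway cohorts; the parapharyngeal
#: fat pads are adipose, hence high.
DEFAULT_FAT_FRACTIONS: dict[str, float] = {
    "tongue": 30.0,
    "tongue_base": 23.0,
    "soft_palate": 30.0,
    "lat_wall_velo": 20.0,
    "lat_wall_oro": 20.0,
    "fat_pads": 80.0,
}

DEFAULT_LANDMARKS = AirwayLandmarks(12, 24, 38, 52)


@dataclass(frozen=True)
class PhantomSpec:
    """Full specification of one synthetic Dixon scan session."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    geometry: Mapping[str, tuple[Shape3D, ...]] = field(default_factory=_default_geometry)
    fat_fractions: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FAT_FRACTIONS))
    amplitude: float = 100.0
    sigma: float = 0.0
    landmarks: AirwayLandmarks = DEFAULT_LANDMARKS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise PhantomSpecError(f"noise sigma must be >= 0, got {self.sigma}")
        if self.amplitude <= 0:
            raise PhantomSpecError(f"signal amplitude must be > 0, got {self.amplitude}")
        for name, f in self.fat_fractions.items():
            if not 0.0 <= f <= 100.0:
                raise PhantomSpecError(f"fat fraction for {name!r} must be in [0, 100], got {f}")
        unknown = set(self.geometry) - set(STRUCTURE_PRIORITY)
        if unknown:
            raise PhantomSpecError(f"unknown structures in geometry: {sorted(unknown)}")
        for name in self.geometry:
            if name != "airway" and name not in self.fat_fractions:
                raise PhantomSpecError(f"no fat fraction specified for tissue {name!r}")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth recorded at generation time for recovery tests."""

    voxel_counts: dict[str, int]
    volumes_cm3: dict[str, float]
    fat_fractions: dict[str, float]
    amplitude: float
    sigma: float
    landmarks: AirwayLandmarks
    label_table: dict[str, int]


def rasterize_labels(spec: PhantomSpec) -> LabelMask:
    """Voxelize the geometry into a disjoint label mask.

    Structures are painted lowest priority first; higher-priority
    structures overwrite, so a contested voxel belongs to the
    highest-priority claimant.
    """
    labels = np.zeros(spec.shape, dtype=np.int16)
    label_table = {name: i + 1 for i, name in enumerate(STRUCTURE_PRIORITY) if name in spec.geometry}
    for name in reversed(STRUCTURE_PRIORITY):
        if name not in spec.geometry:
            continue
        claimed = np.zeros(spec.shape, dtype=bool)
        for shape3d in spec.geometry[name]:
            claimed |= shape3d.voxelize(spec.shape, spec.spacing)
        if not claimed.any():
            raise PhantomSpecError(f"structure {name!r} voxelizes to zero voxels")
        labels[claimed] = label_table[name]
    return LabelMask(labels=labels, label_table=label_table, spacing=spec.spacing)


def add_rician_noise(
    volume: VolumeImage, sigma: float, seed: int | np.random.Generator = 0
) -> VolumeImage:
    """Apply magnitude-MRI (Rician) noise: s -> sqrt((s+g1)^2 + g2^2).

    g1, g2 are independent zero-mean Gaussians of SD sigma; sigma = 0 is
    the identity.
    """
    if sigma < 0:
        raise PhantomSpecError(f"noise sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return volume
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g1 = rng.normal(0.0, sigma, volume.shape)
    g2 = rng.normal(0.0, sigma, volume.shape)
    noisy = np.sqrt((volume.data + g1) ** 2 + g2**2)
    return VolumeImage(data=noisy, spacing=volume.spacing)


def generate_phantom(spec: PhantomSpec) -> tuple[DixonSet, LabelMask, PhantomTruth]:
    """Generate one synthetic Dixon session with its mask and ground truth."""
    mask = rasterize_labels(spec)
    fat = np.zeros(spec.shape, dtype=np.float64)
    water = np.zeros(spec.shape, dtype=np.float64)
    for name, label in mask.label_table.items():
        if name == "airway":
            continue  # air column: zero signal on every channel
        sel = mask.labels == label
        f = spec.fat_fractions[name] / 100.0
        fat[sel] = spec.amplitude * f
        water[sel] = spec.amplitude * (1.0 - f)
    in_phase = fat + water
    out_phase = np.abs(water - fat)
    channels = {"in_phase": in_phase, "out_phase": out_phase, "fat": fat, "water": water}
    if spec.sigma > 0:
        streams = np.random.SeedSequence(spec.seed).spawn(len(channels))
        for (name, data), ss in zip(channels.items(), streams):
            noisy = add_rician_noise(
                VolumeImage(data, spec.spacing), spec.sigma, np.random.default_rng(ss)
            )
            channels[name] = noisy.data
    dixon = DixonSet(
        **{name: VolumeImage(data, spec.spacing) for name, data in channels.items()}
    )
    counts = {name: mask.voxel_count(name) for name in mask.label_table}
    voxel_cm3 = mask.voxel_volume_mm3 / 1000.0
    truth = PhantomTruth(
        voxel_counts=counts,
        volumes_cm3={name: c * voxel_cm3 for name, c in counts.items()},
        fat_fractions=dict(spec.fat_fractions),
        amplitude=spec.amplitude,
        sigma=spec.sigma,
        landmarks=spec.landmarks,
        label_table=dict(mask.label_table),
    )
    return dixon, mask, truth


def generate_paired_phantom_subject(
    spec: PhantomSpec,
    volume_factors: Mapping[str, float] | float = 1.0,
    fat_fraction_changes: Mapping[str, float] | float = 0.0,
    seed: int | None = None,
) -> tuple[tuple[DixonSet, LabelMask, PhantomTruth], tuple[DixonSet, LabelMask, PhantomTruth]]:
    """Generate a baseline/follow-up phantom pair for one subject.

    ``volume_factors`` multiplies each tissue's volume (geometry scaled
    isotropically, in-plane for the airway tube); ``fat_fraction_changes``
    adds to each tissue's true fat fraction in percentage points (a
    reduction is negative). Scalars apply to every structure. The two
    sessions use distinct noise substreams derived from ``seed``.
    """
    if not isinstance(volume_factors, Mapping):
        volume_factors = {name: float(volume_factors) for name in spec.geometry}
    if not isinstance(fat_fraction_changes, Mapping):
        fat_fraction_changes = {name: float(fat_fraction_changes) for name in spec.fat_fractions}
    bad = [n for n, v in volume_factors.items() if v <= 0]
    if bad:
        raise PhantomSpecError(f"volume factors must be > 0; offending structures: {bad}")

    geometry_fu = {
        name: tuple(s.scale(volume_factors.get(name, 1.0)) for s in shapes)
        for name, shapes in spec.geometry.items()
    }
    fat_fu = {
        name: f + fat_fraction_changes.get(name, 0.0) for name, f in spec.fat_fractions.items()
    }
    bad = [n for n, f in fat_fu.items() if not 0.0 <= f <= 100.0]
    if bad:
        raise PhantomSpecError(f"follow-up fat fractions outside [0, 100] for: {bad}")

    base_seed = spec.seed if seed is None else seed
    seed_b, seed_f = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(base_seed).spawn(2)]
    spec_baseline = replace(spec, seed=seed_b)
    spec_followup = replace(spec, geometry=geometry_fu, fat_fractions=fat_fu, seed=seed_f)
    return generate_phantom(spec_baseline), generate_phantom(spec_followup)


# ---------------------------------------------------------------------------
# Paired cohorts


@dataclass(frozen=True)
class MetricSpec:
    """Distributional specification of one paired metric.

    Provide the baseline mean/SD and the mean change, plus either
    ``followup_sd`` (with ``change_sd`` or ``correlation`` fixing the
    joint law) or ``change_sd`` with ``correlation``. The joint law is
    bivariate normal over (baseline, follow-up); the identity
    SD_change^2 = SD_pre^2 + SD_post^2 - 2 r SD_pre SD_post ties the
    parameterisations together.
    """

    baseline_mean: float
    baseline_sd: float
    change_mean: float
    change_sd: float | None = None
    followup_sd: float | None = None
    correlation: float | None = None

    def resolve(self) -> tuple[float, float, float]:
        """Return (followup_sd, correlation, change_sd), filling the gap."""
        s1 = self.baseline_sd
        if s1 < 0 or (self.change_sd is not None and self.change_sd < 0):
            raise PhantomSpecError("SDs must be non-negative")
        if self.followup_sd is not None and self.change_sd is not None:
            s2, sc = self.followup_sd, self.change_sd
            denom = 2.0 * s1 * s2
            r = 0.0 if denom == 0 else (s1**2 + s2**2 - sc**2) / denom
            if not -1.0 <= r <= 1.0:
                raise PhantomSpecError(
                    f"inconsistent SDs: implied pre/post correlation {r:.3f} outside [-1, 1]"
                )
            return s2, r, sc
        if self.correlation is None:
            raise PhantomSpecError(
                "need either (followup_sd and change_sd) or a correlation to fix the joint law"
            )
        r = self.correlation
        if not -1.0 <= r <= 1.0:
            raise PhantomSpecError(f"correlation must be in [-1, 1], got {r}")
        if self.followup_sd is not None:
            s2 = self.followup_sd
            sc = float(np.sqrt(s1**2 + s2**2 - 2.0 * r * s1 * s2))
            return s2, r, sc
        if self.change_sd is None:
            raise PhantomSpecError("need change_sd or followup_sd")
        sc = self.change_sd
        disc = (r * s1) ** 2 - s1**2 + sc**2
        if disc < 0:
            raise PhantomSpecError(
                f"change SD {sc} too small for baseline SD {s1} at correlation {r}"
            )
        s2 = r * s1 + float(np.sqrt(disc))
        return s2, r, sc

    @property
    def true_d_z(self) -> float:
        _, _, sc = self.resolve()
        if sc == 0:
            return float("inf") if self.change_mean != 0 else 0.0
        return self.change_mean / sc


def default_cohort_metrics() -> dict[str, MetricSpec]:
    """Metric specifications matching a bariatric weight-loss cohort.

    Baseline and follow-up moments mirror the study magnitudes: tongue and
    tongue-base volumes shrink ~10%, intra-tissue fat percent drops ~5
    points in tongue and soft palate, the velopharyngeal airway enlarges,
    and parapharyngeal fat-pad volume decreases modestly.
    """
    return {
        "tongue/tissue_volume_cm3": MetricSpec(89.2, 18.2, -9.0, change_sd=7.0, followup_sd=13.2),
        "tongue/fat_percent": MetricSpec(30.4, 6.1, -5.0, change_sd=3.2, followup_sd=6.3),
        "tongue_base/tissue_volume_cm3": MetricSpec(28.5, 6.7, -3.2, change_sd=2.4, followup_sd=6.1),
        "soft_palate/fat_percent": MetricSpec(29.6, 6.0, -4.8, change_sd=5.4, followup_sd=7.1),
        "airway/velopharynx_volume_cm3": MetricSpec(4.2, 1.4, 1.1, change_sd=1.7, followup_sd=1.8),
        "fat_pads/tissue_volume_cm3": MetricSpec(6.9, 2.0, -0.7, change_sd=1.7, followup_sd=2.2),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a paired synthetic cohort."""

    n_subjects: int = 18
    metrics: Mapping[str, MetricSpec] = field(default_factory=default_cohort_metrics)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise PhantomSpecError(f"need >= 2 subjects, got {self.n_subjects}")
        for spec in self.metrics.values():
            spec.resolve()  # validates


@dataclass(frozen=True)
class CohortTruth:
    """True per-metric population parameters of a generated cohort."""

    change_mean: dict[str, float]
    change_sd: dict[str, float]
    percent_change_mean: dict[str, float]
    d_z: dict[str, float]
    correlation: dict[str, float]


def generate_paired_cohort(spec: CohortSpec) -> tuple[PairedCohortTable, CohortTruth]:
    """Draw a paired cohort from the per-metric bivariate-normal laws."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    subjects = [f"S{i + 1:03d}" for i in range(spec.n_subjects)]
    truth_change, truth_sd, truth_pct, truth_dz, truth_r = {}, {}, {}, {}, {}
    for metric, mspec in spec.metrics.items():
        s2, r, sc = mspec.resolve()
        z = rng.standard_normal((spec.n_subjects, 2))
        pre = mspec.baseline_mean + mspec.baseline_sd * z[:, 0]
        post = (
            mspec.baseline_mean
            + mspec.change_mean
            + s2 * (r * z[:, 0] + np.sqrt(max(0.0, 1.0 - r**2)) * z[:, 1])
        )
        for subject, b, f in zip(subjects, pre, post):
            rows.append({"subject": subject, "session": "baseline", "metric": metric, "value": b})
            rows.append({"subject": subject, "session": "followup", "metric": metric, "value": f})
        truth_change[metric] = mspec.change_mean
        truth_sd[metric] = sc
        truth_pct[metric] = 100.0 * mspec.change_mean / mspec.baseline_mean
        truth_dz[metric] = mspec.true_d_z
        truth_r[metric] = r
    table = PairedCohortTable(pd.DataFrame(rows))
    truth = CohortTruth(
        change_mean=truth_change,
        change_sd=truth_sd,
        percent_change_mean=truth_pct,
        d_z=truth_dz,
        correlation=truth_r,
    )
    return table, truth
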