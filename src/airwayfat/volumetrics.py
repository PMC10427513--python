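"""Structure volumes, airway subdivision, cross-sectional areas, length.

The upper airway is subdivided along the axial axis by four anatomical
landmark slices into the velopharynx (hard palate to uvula tip), oropharynx
(uvula tip to epiglottis base), and hypopharynx (epiglottis base to vocal
folds). Slice intervals are half-open with the final boundary closed, so
the three regions partition the airway over the landmark span exactly.

Airway length is the centre-to-centre distance between the first and last
occupied slice of a region, so a single-slice region has length 0. Note
this differs from the (occupied slice count) x spacing convention by one
slice thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyStructureError, LandmarkError
from .volume_io import LabelMask

AIRWAY_REGIONS = ("velopharynx", "oropharynx", "hypopharynx")


@dataclass(frozen=True)
class AirwayLandmarks:
    """Axial landmark slice indices (0-based) bounding the airway regions.

    Must be strictly increasing: hard palate, uvula tip, epiglottis base,
    vocal folds, ordered superior to inferior.
    """

    hard_palate_slice: int
    uvula_tip_slice: int
    epiglottis_base_slice: int
    vocal_fold_slice: int

    def __post_init__(self) -> None:
        seq = self.as_tuple()
        if any(not isinstance(s, (int, np.integer)) for s in seq):
            raise LandmarkError(f"landmark slices must be integers, got {seq}")
        if not (seq[0] < seq[1] < seq[2] < seq[3]):
            raise LandmarkError(f"landmark slices must be strictly increasing, got {seq}")
        if seq[0] < 0:
            raise LandmarkError(f"landmark slices must be non-negative, got {seq}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.hard_palate_slice,
            self.uvula_tip_slice,
            self.epiglottis_base_slice,
            self.vocal_fold_slice,
        )

    def check_range(self, n_slices: int) -> None:
        if self.vocal_fold_slice >= n_slices:
            raise LandmarkError(
                f"vocal fold slice {self.vocal_fold_slice} outside volume with {n_slices} slices"
            )

    def region_slices(self, region: str) -> tuple[int, int]:
        """Half-open [start, stop) slice bounds of a region.

        The hypopharynx includes its closing vocal-fold slice, so its stop
        is ``vocal_fold_slice + 1``.
        """
        bounds = {
            "velopharynx": (self.hard_palate_slice, self.uvula_tip_slice),
            "oropharynx": (self.uvula_tip_slice, self.epiglottis_base_slice),
            "hypopharynx": (self.epiglottis_base_slice, self.vocal_fold_slice + 1),
        }
        try:
            return bounds[region]
        except KeyError:
            raise LandmarkError(f"unknown airway region {region!r}") from None


@dataclass(frozen=True)
class AirwayRegionMetrics:
    """Volume, cross-sectional area summary and length for one airway region."""

    region: str
    volume_cm3: float
    mean_csa_mm2: float
    min_csa_mm2: float
    length_mm: float


@dataclass(frozen=True, eq=False)
class CrossSectionProfile:
    """Per-axial-slice in-plane areas of a structure, in mm^2.

    ``areas_mm2[k]`` is the area on slice k (0 where the structure is
    absent); mean and minimum are taken over occupied slices only, so an
    empty slice inside the span does not force the minimum to zero.
    """

    areas_mm2: np.ndarray
    mean_csa_mm2: float
    min_csa_mm2: float
    occupied_slices: np.ndarray


def structure_volume(mask: LabelMask, structure: str) -> float:
    """Volume of a structure in cm^3: labelled voxel count x voxel volume."""
    return mask.voxel_count(structure) * mask.voxel_volume_mm3 / 1000.0


def subdivide_airway(mask: LabelMask, landmarks: AirwayLandmarks) -> dict[str, LabelMask]:
    """Split the airway label into the three regional masks.

    Returns one single-structure LabelMask per region; the regions are
    disjoint and their union is the airway restricted to the landmark span
    [hard palate, vocal folds].
    """
    landmarks.check_range(mask.shape[2])
    airway_label = mask.label_of("airway")
    airway = mask.labels == airway_label
    regions: dict[str, LabelMask] = {}
    for region in AIRWAY_REGIONS:
        start, stop = landmarks.region_slices(region)
        regional = np.zeros_like(airway)
        regional[:, :, start:stop] = airway[:, :, start:stop]
        regions[region] = LabelMask(
            labels=regional.astype(np.int16) * airway_label,
            label_table={"airway": airway_label},
            spacing=mask.spacing,
        )
    return regions


def cross_sectional_areas(mask: LabelMask, structure: str) -> CrossSectionProfile:
    """Per-slice cross-sectional areas of a structure.

    Slice area = in-plane labelled voxel count x pixel area. Mean and
    minimum are over slices containing at least one labelled voxel.
    """
    sel = mask.labels == mask.label_of(structure)
    counts = sel.sum(axis=(0, 1))
    pixel_area = float(mask.spacing[0]) * float(mask.spacing[1])
    areas = counts * pixel_area
    occupied = np.flatnonzero(counts > 0)
    if occupied.size == 0:
        raise EmptyStructureError(f"structure {structure!r} has no labelled voxels")
    return CrossSectionProfile(
        areas_mm2=areas.astype(np.float64),
        mean_csa_mm2=float(areas[occupied].mean()),
        min_csa_mm2=float(areas[occupied].min()),
        occupied_slices=occupied,
    )


def airway_length(regional_mask: LabelMask, structure: str = "airway") -> float:
    """Centre-to-centre distance (mm) between first and last occupied slice."""
    sel = regional_mask.labels == regional_mask.label_of(structure)
    occupied = np.flatnonzero(sel.any(axis=(0, 1)))
    if occupied.size == 0:
        raise EmptyStructureError(f"structure {structure!r} occupies no slices")
    return float((occupied[-1] - occupied[0]) * regional_mask.spacing[2])


def airway_region_metrics(
    mask: LabelMask, landmarks: AirwayLandmarks
) -> dict[str, AirwayRegionMetrics]:
    """Volume, CSA and length for the three airway regions plus the total.

    ``total`` covers the whole airway label (all slices), matching the
    total-airway volume convention; regions cover the landmark span.
    """
    out: dict[str, AirwayRegionMetrics] = {}
    for region, regional in subdivide_airway(mask, landmarks).items():
        profile = cross_sectional_areas(regional, "airway")
        out[region] = AirwayRegionMetrics(
            region=region,
            volume_cm3=structure_volume(regional, "airway"),
            mean_csa_mm2=profile.mean_csa_mm2,
            min_csa_mm2=profile.min_csa_mm2,
            length_mm=airway_length(regional),
        )
    profile = cross_sectional_areas(mask, "airway")
    out["total"] = AirwayRegionMetrics(
        region="total",
        volume_cm3=structure_volume(mask, "airway"),
        mean_csa_mm2=profile.mean_csa_mm2,
        min_csa_mm2=profile.min_csa_mm2,
        length_mm=airway_length(mask),
    )
    return out
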