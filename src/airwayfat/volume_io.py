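"""Volume I/O: NIfTI reading/writing, Dixon channel sets, and label masks.

All images are 3-D scalar grids. The third array axis is the axial
(head-foot) direction, with slice index increasing superior to inferior.
Volumes of one session are assumed co-registered (the four Dixon channels
come out of a single acquisition); spatial header orientation beyond axis
identification is deliberately ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml

from .errors import CoRegistrationError, DataError, LabelError, VolumeFormatError

#: Controlled vocabulary of segmented structures. ``airway`` is the air
#: column; the remaining six are the soft-tissue compartments surrounding it.
STRUCTURE_NAMES = (
    "airway",
    "soft_palate",
    "tongue",
    "tongue_base",
    "lat_wall_velo",
    "lat_wall_oro",
    "fat_pads",
)

#: Soft-tissue structures for which intra-tissue fat is meaningful.
TISSUE_NAMES = tuple(n for n in STRUCTURE_NAMES if n != "airway")


@dataclass(frozen=True, eq=False)
class VolumeImage:
    """A 3-D scalar image with per-axis voxel spacing in millimetres."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeFormatError(f"volume must be 3-D, got {data.ndim}-D")
        if min(data.shape) < 1:
            raise VolumeFormatError(f"degenerate volume shape {data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise VolumeFormatError(f"voxel spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        """Number of axial slices (extent along the third axis)."""
        return self.data.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeImage | LabelMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass(frozen=True, eq=False)
class DixonSet:
    """The four co-registered mDixon channel volumes of one scan session.

    ``in_phase`` and ``out_phase`` are the anatomical (chemical-shift
    combined) images; ``fat`` and ``water`` are the saturated magnitude
    images used for fat quantification.
    """

    in_phase: VolumeImage
    out_phase: VolumeImage
    fat: VolumeImage
    water: VolumeImage

    def __post_init__(self) -> None:
        channels = {
            "in_phase": self.in_phase,
            "out_phase": self.out_phase,
            "fat": self.fat,
            "water": self.water,
        }
        ref_name, ref = next(iter(channels.items()))
        for name, vol in channels.items():
            if not ref.same_grid(vol):
                raise CoRegistrationError(
                    f"channel {name!r} grid {vol.shape}/{vol.spacing} does not match "
                    f"{ref_name!r} grid {ref.shape}/{ref.spacing}"
                )
        for name in ("fat", "water"):
            if np.any(channels[name].data < 0):
                raise DataError(f"{name} channel contains negative values; magnitude image expected")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.in_phase.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.in_phase.spacing


@dataclass(frozen=True, eq=False)
class LabelMask:
    """Integer-labelled volume naming disjoint anatomical structures.

    Voxel value 0 is background; every nonzero value must appear in
    ``label_table`` (structure name -> positive integer). One label per
    voxel: structures are mutually exclusive by construction.
    """

    labels: np.ndarray
    label_table: Mapping[str, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise VolumeFormatError(f"label mask must be 3-D, got {labels.ndim}-D")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.array_equal(labels, labels.astype(np.int64)):
                raise LabelError("label mask contains non-integer voxel values")
            labels = labels.astype(np.int64)
        table = dict(self.label_table)
        for name, value in table.items():
            if name not in STRUCTURE_NAMES:
                raise LabelError(
                    f"unknown structure name {name!r}; expected one of {STRUCTURE_NAMES}"
                )
            if int(value) <= 0:
                raise LabelError(f"label for {name!r} must be a positive integer, got {value}")
        values = set(table.values())
        if len(values) != len(table):
            raise LabelError("label table assigns the same integer to two structures")
        present = set(np.unique(labels).tolist()) - {0}
        unknown = present - values
        if unknown:
            raise LabelError(f"mask contains voxel values {sorted(unknown)} absent from label table")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise VolumeFormatError(f"voxel spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "label_table", table)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def label_of(self, structure: str) -> int:
        try:
            return int(self.label_table[structure])
        except KeyError:
            raise LabelError(
                f"structure {structure!r} not in label table {sorted(self.label_table)}"
            ) from None

    def voxel_count(self, structure: str) -> int:
        return int(np.count_nonzero(self.labels == self.label_of(structure)))

    def structures(self) -> tuple[str, ...]:
        """Structure names present in the table, in table order."""
        return tuple(self.label_table)


def _spacing_from_header(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(path: str | Path) -> VolumeImage:
    """Read a 3-D NIfTI volume.

    The axial axis is taken to be the third array axis; header spatial
    orientation is otherwise ignored (grids are assumed co-registered).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    spacing = _spacing_from_header(img)
    if any(s <= 0 for s in spacing):
        raise VolumeFormatError(f"{path}: non-positive voxel spacing {spacing}")
    return VolumeImage(data=data, spacing=spacing)


def write_volume(volume: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with a diagonal affine built from spacing."""
    path = Path(path)
    affine = np.diag([*volume.spacing, 1.0])
    data = volume.data
    if data.dtype == np.bool_:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def load_dixon_set(
    in_phase: str | Path,
    out_phase: str | Path,
    fat: str | Path,
    water: str | Path,
) -> DixonSet:
    """Load and validate the four Dixon channels of one session.

    Raises :class:`CoRegistrationError` if any two channels disagree in
    shape or spacing, and :class:`DataError` if the fat or water magnitude
    images contain negative values.
    """
    return DixonSet(
        in_phase=read_volume(in_phase),
        out_phase=read_volume(out_phase),
        fat=read_volume(fat),
        water=read_volume(water),
    )


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a YAML/JSON sidecar mapping structure names to label integers."""
    path = Path(path)
    if not path.exists():
        raise LabelError(f"label table file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise LabelError(f"{path}: label table must be a mapping of name -> integer")
    return {str(k): int(v) for k, v in raw.items()}


def write_label_table(table: Mapping[str, int], path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps({k: int(v) for k, v in table.items()}, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump({k: int(v) for k, v in table.items()}, sort_keys=False))
    return path


def load_label_mask(
    path: str | Path,
    reference: VolumeImage,
    label_table: Mapping[str, int] | str | Path,
) -> LabelMask:
    """Load a label-mask volume and validate it against a reference grid.

    ``label_table`` may be an in-memory mapping or the path of a YAML/JSON
    sidecar. Every nonzero voxel value must be named in the table.
    """
    vol = read_volume(path)
    if not reference.same_grid(vol):
        raise CoRegistrationError(
            f"label mask grid {vol.shape}/{vol.spacing} does not match reference "
            f"{reference.shape}/{reference.spacing}"
        )
    if not isinstance(label_table, Mapping):
        label_table = read_label_table(label_table)
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(data, rounded):
            raise LabelError(f"{path}: label mask contains non-integer voxel values")
        data = rounded.astype(np.int64)
    return LabelMask(labels=data, label_table=label_table, spacing=vol.spacing)


def write_label_mask(mask: LabelMask, path: str | Path, table_path: str | Path | None = None) -> Path:
    """Write the mask volume as NIfTI plus its label-table sidecar."""
    path = Path(path)
    write_volume(VolumeImage(mask.labels.astype(np.int16), mask.spacing), path)
    if table_path is None:
        stem = path.name
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        table_path = path.with_name(stem + ".labels.yaml")
    write_label_table(mask.label_table, table_path)
    return path
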