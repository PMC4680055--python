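"""Label-volume data model, NIfTI I/O, label-scheme merging, and component masks.

Two label schemes are used throughout the package:

* **raw** — the 8-structure reference annotation: cortical gray matter (1),
  basal ganglia (2), white matter (3), white matter lesions (4), peripheral
  cerebrospinal fluid (5), lateral ventricles (6), cerebellum (7), and
  brainstem (8); 0 is background.
* **tissue** — the merged 3-class scheme that is actually scored: gray
  matter (1), white matter (2), cerebrospinal fluid (3); 0 is background.

Cerebellum and brainstem (raw labels 7/8) are excluded from all evaluation:
voxels carrying those labels in the *reference* are masked out of both the
reference and the candidate before any metric is computed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Scheme",
    "Component",
    "LabelVolume",
    "ComponentMask",
    "RAW_TO_TISSUE",
    "EXCLUDED_RAW_LABELS",
    "read_label_volume",
    "write_label_volume",
    "merge_to_tissue",
    "component_mask",
]


class Scheme(enum.Enum):
    """Label scheme of a volume."""

    RAW = "raw"
    TISSUE = "tissue"


class Component(enum.Enum):
    """Anatomical components that masks can be built for.

    GM, WM and CSF are the scored tissue classes; BRAIN is GM + WM and ICV
    (intracranial volume) is GM + WM + CSF. WML identifies white matter
    lesion voxels (raw label 4) and is used only for lesion sensitivity.
    """

    GM = "GM"
    WM = "WM"
    CSF = "CSF"
    BRAIN = "brain"
    ICV = "ICV"
    WML = "WML"


#: Components evaluated per case, in report order.
EVALUATED_COMPONENTS = (
    Component.GM,
    Component.WM,
    Component.CSF,
    Component.BRAIN,
    Component.ICV,
)

#: raw label -> tissue label (index = raw label).
RAW_TO_TISSUE = np.array([0, 1, 1, 2, 2, 3, 3, 0, 0], dtype=np.int16)

#: Raw labels removed from the evaluation entirely (cerebellum, brainstem).
EXCLUDED_RAW_LABELS = (7, 8)

#: tissue labels making up each component.
_COMPONENT_TISSUE_LABELS = {
    Component.GM: (1,),
    Component.WM: (2,),
    Component.CSF: (3,),
    Component.BRAIN: (1, 2),
    Component.ICV: (1, 2, 3),
}

_SCHEME_MAX_LABEL = {Scheme.RAW: 8, Scheme.TISSUE: 3}


class SchemeError(ValueError):
    """A volume's labels or declared scheme are inconsistent."""


@dataclass
class LabelVolume:
    """A 3D integer label grid with physical voxel spacing.

    Voxel ``(i, j, k)`` has physical center ``(i*dx, j*dy, k*dz)`` in mm.
    Orientation beyond spacing is ignored: candidate and reference are
    assumed to live on a common registered grid.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    scheme: Scheme

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError(f"grid must be 3D with size >= 1 per axis, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("grid must hold integer labels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        _check_labels(self.grid, self.scheme)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class ComponentMask:
    """Boolean mask of one anatomical component on a label grid."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    component: Component

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def count(self) -> int:
        """Number of voxels in the mask."""
        return int(self.grid.sum())

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


def _check_labels(grid: np.ndarray, scheme: Scheme) -> None:
    lo, hi = int(grid.min()), int(grid.max())
    if lo < 0 or hi > _SCHEME_MAX_LABEL[scheme]:
        raise SchemeError(
            f"labels [{lo}, {hi}] outside {scheme.value} scheme range 0..{_SCHEME_MAX_LABEL[scheme]}"
        )


def read_label_volume(path: str | Path, scheme: Scheme | None = None) -> LabelVolume:
    """Read a NIfTI label map.

    Spacing is taken from the header pixel dimensions. Float-stored labels
    are accepted if within 1e-6 of integers (a common NIfTI dialect issue).
    If *scheme* is not given it is inferred from the label set: a maximum
    label above 3 implies the raw 8-structure scheme, otherwise tissue.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label map, got shape {data.shape}")
    data = np.asarray(data, dtype=np.float64)
    rounded = np.rint(data)
    if np.abs(data - rounded).max() > 1e-6:
        raise ValueError(f"{path}: voxel values are not integer labels (beyond 1e-6 tolerance)")
    grid = rounded.astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if scheme is None:
        scheme = Scheme.RAW if grid.max() > 3 else Scheme.TISSUE
    return LabelVolume(grid=grid, spacing=spacing, scheme=scheme)


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a label volume as NIfTI-1 with a diagonal spacing affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.grid.astype(np.int16), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def merge_to_tissue(raw: LabelVolume) -> tuple[LabelVolume, ComponentMask]:
    """Merge the 8-structure annotation into the 3-class tissue scheme.

    Cortical GM and basal ganglia become GM; WM and WM lesions become WM;
    peripheral CSF and lateral ventricles become CSF. Cerebellum and
    brainstem voxels become background and are returned as the exclusion
    mask to be applied to both reference and candidate.
    """
    if raw.scheme is not Scheme.RAW:
        raise SchemeError("merge_to_tissue expects a raw-scheme volume")
    tissue_grid = RAW_TO_TISSUE[raw.grid]
    excluded = np.isin(raw.grid, EXCLUDED_RAW_LABELS)
    tissue = LabelVolume(grid=tissue_grid, spacing=raw.spacing, scheme=Scheme.TISSUE)
    excl_mask = ComponentMask(grid=excluded, spacing=raw.spacing, component=Component.ICV)
    return tissue, excl_mask


def component_mask(
    tissue: LabelVolume,
    component: Component,
    excluded: ComponentMask | None = None,
) -> ComponentMask:
    """Boolean mask of one evaluated component of a tissue-scheme volume.

    GM = {1}, WM = {2}, CSF = {3}, brain = GM ∪ WM, ICV = GM ∪ WM ∪ CSF,
    each minus the excluded (cerebellum/brainstem) voxels.
    """
    if tissue.scheme is not Scheme.TISSUE:
        raise SchemeError("component_mask expects a tissue-scheme volume")
    if component not in _COMPONENT_TISSUE_LABELS:
        raise ValueError(f"cannot build a tissue mask for component {component}")
    mask = np.isin(tissue.grid, _COMPONENT_TISSUE_LABELS[component])
    if excluded is not None:
        if excluded.shape != tissue.shape:
            raise ValueError("exclusion mask shape does not match the volume")
        mask &= ~excluded.grid
    return ComponentMask(grid=mask, spacing=tissue.spacing, component=component)


def as_tissue(volume: LabelVolume) -> LabelVolume:
    """Return *volume* in tissue scheme, merging raw-scheme input if needed."""
    if volume.scheme is Scheme.TISSUE:
        return volume
    tissue, _ = merge_to_tissue(volume)
    return tissue
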