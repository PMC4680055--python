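"""The three segmentation evaluation measures, boundary extraction, and
white-matter-lesion sensitivity.

The measures compare a candidate segmentation A against a reference G:

* Dice overlap  D = 2|A ∩ G| / (|A| + |G|) · 100  (percent),
* 95th-percentile Hausdorff distance  H95 = max(h95(A,G), h95(G,A))  where
  the directed h95 is the K-th ranked minimum Euclidean distance between
  boundary point sets with K/N = 95% (robust to boundary outliers, unlike
  the conventional maximum Hausdorff distance),
* absolute volume difference  AVD = |V_a − V_g| / V_g · 100  (percent).

All distances are in physical millimetres: voxel indices are scaled by the
header spacing, which matters on the strongly anisotropic grids this
framework targets (e.g. 0.96 × 0.96 × 3.00 mm voxels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import Component, ComponentMask, LabelVolume, Scheme, as_tissue

__all__ = [
    "BoundaryPointSet",
    "MetricTriple",
    "UndefinedMetricError",
    "dice",
    "extract_boundary",
    "directed_h95",
    "h95",
    "avd",
    "wml_sensitivity",
]

#: 6-connectivity structuring element (face neighbors only).
FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)

#: Label carried by white matter lesions in the raw annotation scheme.
WML_RAW_LABEL = 4
#: Tissue label for white matter.
WM_TISSUE_LABEL = 2


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. empty masks)."""


@dataclass
class BoundaryPointSet:
    """Physical-coordinate centers of the boundary voxels of one component."""

    points: np.ndarray  # (N, 3) float, mm

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size and self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")

    @property
    def count(self) -> int:
        return 0 if self.points.size == 0 else self.points.shape[0]


@dataclass
class MetricTriple:
    """Dice (%), H95 (mm), AVD (%) for one component of one case.

    ``h95_defined`` is False when either boundary set was empty (degenerate
    candidate); ``h95`` is then NaN and downstream aggregation/ranking must
    treat the case explicitly rather than propagate the NaN silently.
    """

    dice: float
    h95: float
    avd: float
    h95_defined: bool = True


def _check_compatible(a: ComponentMask, g: ComponentMask) -> None:
    if a.shape != g.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {g.shape}")
    if not np.allclose(a.spacing, g.spacing, atol=1e-6):
        raise ValueError(f"mask spacings differ: {a.spacing} vs {g.spacing}")


def dice(a: ComponentMask, g: ComponentMask) -> float:
    """Dice overlap of candidate mask *a* and reference mask *g*, in percent."""
    _check_compatible(a, g)
    na, ng = a.count, g.count
    if na + ng == 0:
        raise UndefinedMetricError("Dice undefined: both masks are empty")
    inter = int(np.logical_and(a.grid, g.grid).sum())
    return 2.0 * inter / (na + ng) * 100.0


def extract_boundary(mask: ComponentMask) -> BoundaryPointSet:
    """Boundary voxels of a mask, as physical voxel-center coordinates.

    A voxel is a boundary point iff it is in the mask and at least one of
    its 6 face neighbors is outside the mask or outside the image (the
    image border counts as outside, so erosion uses border_value=0).
    """
    if mask.count == 0:
        raise UndefinedMetricError("cannot extract the boundary of an empty mask")
    interior = ndimage.binary_erosion(mask.grid, structure=FACE_STRUCTURE, border_value=0)
    boundary = mask.grid & ~interior
    idx = np.argwhere(boundary).astype(float)
    idx *= np.asarray(mask.spacing)
    return BoundaryPointSet(points=idx)


def _h95_rank(n: int) -> int:
    # K-th order statistic (1-based) with K = ceil(0.95 * N); ceil keeps
    # K/N >= 95% for every N, and K >= 1.
    return max(1, math.ceil(0.95 * n))


def directed_h95(a: BoundaryPointSet, g: BoundaryPointSet) -> float:
    """Directed 95th-percentile Hausdorff distance from *a* to *g*, in mm.

    For every point of *a* the minimum Euclidean distance to *g* is taken;
    the K-th ranked of those N_a minima, with K = ceil(0.95 · N_a), is
    returned (order statistic, no interpolation).
    """
    if a.count == 0 or g.count == 0:
        raise UndefinedMetricError("directed h95 undefined for an empty boundary set")
    tree = cKDTree(g.points)
    dists, _ = tree.query(a.points, k=1)
    dists = np.sort(np.atleast_1d(dists))
    return float(dists[_h95_rank(a.count) - 1])


def h95(a: BoundaryPointSet, g: BoundaryPointSet) -> float:
    """Symmetric 95th-percentile Hausdorff distance, max of both directions."""
    return max(directed_h95(a, g), directed_h95(g, a))


def avd(a: ComponentMask, g: ComponentMask) -> float:
    """Absolute volume difference |V_a − V_g| / V_g · 100, in percent.

    Volumes are voxel count times voxel volume; with a shared grid the
    voxel volume cancels, so counts suffice.
    """
    _check_compatible(a, g)
    ng = g.count
    if ng == 0:
        raise UndefinedMetricError("AVD undefined: reference mask is empty")
    return abs(a.count - ng) / ng * 100.0


def wml_sensitivity(
    candidates: list[LabelVolume], references: list[LabelVolume]
) -> float:
    """Percentage of white-matter-lesion voxels the candidates label as WM.

    Lesion voxels are those with raw reference label 4; the numerator and
    denominator are pooled over all candidate/reference pairs. Lesions
    should be segmented as white matter, so this sensitivity measures
    robustness against ageing-related pathology.
    """
    if len(candidates) != len(references):
        raise ValueError("candidates and references must be paired lists")
    hit = total = 0
    for cand, ref in zip(candidates, references):
        if ref.scheme is not Scheme.RAW:
            raise ValueError("references must be raw-scheme (lesions need label 4)")
        if cand.shape != ref.shape:
            raise ValueError("candidate/reference shape mismatch")
        lesion = ref.grid == WML_RAW_LABEL
        total += int(lesion.sum())
        hit += int((as_tissue(cand).grid[lesion] == WM_TISSUE_LABEL).sum())
    if total == 0:
        raise UndefinedMetricError("no white matter lesion voxels in any reference")
    return 100.0 * hit / total


def mask_metrics(a: ComponentMask, g: ComponentMask) -> MetricTriple:
    """Dice, H95 and AVD of a candidate mask against a reference mask.

    Degenerate candidates are handled without crashing: an empty candidate
    yields Dice 0 and AVD 100 directly from the formulas, while H95 is
    recorded as undefined (NaN, ``h95_defined=False``) so aggregation and
    ranking can treat the case explicitly.
    """
    d = dice(a, g)
    v = avd(a, g)
    if a.count == 0 or g.count == 0:
        return MetricTriple(dice=d, h95=float("nan"), avd=v, h95_defined=False)
    h = h95(extract_boundary(a), extract_boundary(g))
    return MetricTriple(dice=d, h95=h, avd=v)
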