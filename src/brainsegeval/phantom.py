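"""Synthetic raw-scheme brain-like label volumes and controlled corruptions.

The phantom is a nested-ellipsoid head: an intracranial ellipsoid whose
outermost shell is peripheral CSF (5), then a cortical GM shell (1), and a
WM core (3); two lateral-ventricle ellipsoids (6) sit inside the WM with
basal-ganglia blobs (2) adjacent to them, white-matter-lesion blobs (4) are
scattered strictly inside the WM, and an inferior blob outside the
intracranial ellipsoid is split into cerebellum (7) and brainstem (8).

The geometry is deliberately ellipsoidal rather than anatomical: the
evaluation mathematics is geometry-agnostic, and what the tests need is the
topology (nesting, adjacency, all eight labels present) on a realistically
anisotropic grid. The default grid is 128 × 128 × 48 voxels at
0.96 × 0.96 × 3.00 mm, the thick-slice geometry the framework targets, so
anisotropy bugs surface in tests.

Everything is deterministic given the seed in the spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .metrics import FACE_STRUCTURE
from .volumes import LabelVolume, Scheme

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "perturb_relabel",
    "perturb_shift",
    "perturb_dilate",
    "analytic_icv_volume",
]


@dataclass
class PhantomSpec:
    """Geometry and randomness of one synthetic head phantom.

    Semi-axes are physical millimetres; centers are fractions of the grid
    extent. The nested semi-axes must strictly decrease from the
    intracranial shell through the GM shell to the WM core so each shell
    has positive thickness.
    """

    dims: tuple[int, int, int] = (128, 128, 48)
    spacing: tuple[float, float, float] = (0.96, 0.96, 3.0)
    center_frac: tuple[float, float, float] = (0.5, 0.5, 0.62)
    icv_semiaxes: tuple[float, float, float] = (52.0, 56.0, 46.0)
    gm_semiaxes: tuple[float, float, float] = (48.0, 52.0, 42.0)
    wm_semiaxes: tuple[float, float, float] = (38.0, 42.0, 33.0)
    ventricle_semiaxes: tuple[float, float, float] = (7.0, 18.0, 9.0)
    ventricle_offset_mm: float = 11.0  # lateral (±x) shift of each ventricle
    basal_ganglia_semiaxes: tuple[float, float, float] = (6.0, 11.0, 8.0)
    basal_ganglia_offset_mm: float = 22.0
    n_wml: int = 4
    wml_radius_mm: tuple[float, float] = (3.0, 6.0)
    hindbrain_semiaxes: tuple[float, float, float] = (26.0, 20.0, 16.0)
    hindbrain_center_frac: tuple[float, float, float] = (0.5, 0.38, 0.17)
    seed: int = 0

    def validate(self) -> None:
        if min(self.dims) < 8:
            raise ValueError("grid too small for a nested phantom")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for outer, inner in ((self.icv_semiaxes, self.gm_semiaxes),
                             (self.gm_semiaxes, self.wm_semiaxes)):
            if not all(o > i for o, i in zip(outer, inner)):
                raise ValueError("nested semi-axes must strictly decrease (ICV > GM > WM)")
        extent = [n * s for n, s in zip(self.dims, self.spacing)]
        center = [f * e for f, e in zip(self.center_frac, extent)]
        for ax, (c, a, e) in enumerate(zip(center, self.icv_semiaxes, extent)):
            if c - a < 0 or c + a > e:
                raise ValueError(f"ICV ellipsoid exceeds the grid on axis {ax}")
        if not (0 < self.wml_radius_mm[0] <= self.wml_radius_mm[1]):
            raise ValueError("WML radius range must be positive and ordered")
        if self.n_wml < 1:
            raise ValueError("at least one WML blob is required")


def _physical_coords(dims, spacing):
    axes = [np.arange(n) * s for n, s in zip(dims, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    q = sum(((x - c) / a) ** 2 for x, c, a in zip(coords, center, semiaxes))
    return q <= 1.0


def analytic_icv_volume(spec: PhantomSpec) -> float:
    """Volume (mm^3) of the intracranial ellipsoid implied by the spec."""
    a, b, c = spec.icv_semiaxes
    return 4.0 / 3.0 * math.pi * a * b * c


def generate_phantom(spec: PhantomSpec | None = None) -> LabelVolume:
    """Generate a deterministic raw-scheme phantom from *spec*.

    All eight structure labels are present; GM/WM/CSF nesting and the
    exclusion blob placement follow the class docstring above.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    coords = _physical_coords(spec.dims, spec.spacing)
    extent = [n * s for n, s in zip(spec.dims, spec.spacing)]
    center = [f * e for f, e in zip(spec.center_frac, extent)]

    grid = np.zeros(spec.dims, dtype=np.int16)
    grid[_ellipsoid(coords, center, spec.icv_semiaxes)] = 5   # peripheral CSF shell
    grid[_ellipsoid(coords, center, spec.gm_semiaxes)] = 1    # cortical GM shell
    wm = _ellipsoid(coords, center, spec.wm_semiaxes)
    grid[wm] = 3                                              # WM core

    # lateral ventricles: mirrored ±x ellipsoids inside the WM core
    for sx in (-1.0, 1.0):
        vc = (center[0] + sx * spec.ventricle_offset_mm, center[1], center[2])
        vent = _ellipsoid(coords, vc, spec.ventricle_semiaxes) & wm
        grid[vent] = 6
    # basal ganglia: blobs lateral to the ventricles, still inside WM
    for sx in (-1.0, 1.0):
        bc = (center[0] + sx * spec.basal_ganglia_offset_mm, center[1], center[2])
        bg = _ellipsoid(coords, bc, spec.basal_ganglia_semiaxes) & (grid == 3)
        grid[bg] = 2

    # WM lesions: spherical blobs drawn inside the WM core, relabeling only
    # voxels that are still plain WM so lesions never clobber other structures
    wm_margin = tuple(a - spec.wml_radius_mm[1] for a in spec.wm_semiaxes)
    for _ in range(spec.n_wml):
        r = rng.uniform(*spec.wml_radius_mm)
        # rejection-sample a center well inside the WM ellipsoid
        cand = center
        for _attempt in range(1000):
            u = rng.uniform(-1, 1, size=3)
            trial = [c + ui * (m * 0.9) for c, ui, m in zip(center, u, wm_margin)]
            if sum(((x - c) / a) ** 2 for x, c, a in zip(trial, center, wm_margin)) <= 1.0:
                cand = trial
                break
        blob = _ellipsoid(coords, cand, (r, r, r)) & (grid == 3)
        grid[blob] = 4
    if not (grid == 4).any():
        # degenerate draw (every blob swallowed by ventricles/basal ganglia):
        # place one lesion at the head center, which is always plain WM
        r = spec.wml_radius_mm[0]
        grid[_ellipsoid(coords, center, (r, r, r)) & (grid == 3)] = 4

    # cerebellum + brainstem: one inferior blob outside the ICV ellipsoid,
    # split along z (upper part cerebellum 7, lower part brainstem 8)
    hc = [f * e for f, e in zip(spec.hindbrain_center_frac, extent)]
    hind = _ellipsoid(coords, hc, spec.hindbrain_semiaxes) & (grid == 0)
    grid[hind & (coords[2] >= hc[2])] = 7
    grid[hind & (coords[2] < hc[2])] = 8

    missing = set(range(1, 9)) - set(np.unique(grid).tolist())
    if missing:
        raise ValueError(f"phantom spec produced no voxels for labels {sorted(missing)}")
    return LabelVolume(grid=grid, spacing=spec.spacing, scheme=Scheme.RAW)


def perturb_relabel(
    volume: LabelVolume, from_label: int, to_label: int, fraction: float, seed: int = 0
) -> LabelVolume:
    """Relabel a uniformly chosen fraction of one label's voxels.

    Exactly ``round(fraction * count(from_label))`` voxels are switched;
    deterministic for a given seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    grid = volume.grid.copy()
    idx = np.flatnonzero(grid == from_label)
    k = int(round(fraction * idx.size))
    if k:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(idx, size=k, replace=False)
        grid.flat[chosen] = to_label
    return LabelVolume(grid=grid, spacing=volume.spacing, scheme=volume.scheme)


def perturb_shift(volume: LabelVolume, offset: tuple[int, int, int]) -> LabelVolume:
    """Translate all labeled voxels by an integer voxel offset per axis.

    Vacated voxels become background; shifting any labeled voxel off the
    grid is an error (content must not be clipped).
    """
    grid = volume.grid
    out = np.zeros_like(grid)
    src = []
    dst = []
    for n, off in zip(grid.shape, offset):
        if abs(off) >= n:
            raise ValueError("offset larger than the grid")
        src.append(slice(max(0, -off), n - max(0, off)))
        dst.append(slice(max(0, off), n + min(0, off)))
    out[tuple(dst)] = grid[tuple(src)]
    if np.count_nonzero(out) != np.count_nonzero(grid):
        raise ValueError("shift would clip labeled voxels at the grid border")
    return LabelVolume(grid=out, spacing=volume.spacing, scheme=volume.scheme)


def perturb_dilate(
    volume: LabelVolume,
    label: int,
    iterations: int,
    overwrite_others: bool = False,
) -> LabelVolume:
    """Grow one label into face-adjacent voxels, one layer per iteration.

    By default growth claims only background voxels; with
    ``overwrite_others`` it also overwrites neighboring structure labels.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return LabelVolume(
            grid=volume.grid.copy(), spacing=volume.spacing, scheme=volume.scheme
        )
    mask = volume.grid == label
    grown = ndimage.binary_dilation(mask, structure=FACE_STRUCTURE, iterations=iterations)
    grid = volume.grid.copy()
    target = grown & ~mask
    if not overwrite_others:
        target &= volume.grid == 0
    grid[target] = label
    return LabelVolume(grid=grid, spacing=volume.spacing, scheme=volume.scheme)
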