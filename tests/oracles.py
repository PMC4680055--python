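"""Independent brute-force oracles the fast implementations are checked
against. Deliberately naive: per-voxel neighbor scans and O(N^2) all-pairs
distances, no shared code with the package internals."""

import math

import numpy as np


def boundary_points_bruteforce(grid: np.ndarray, spacing) -> set[tuple[float, float, float]]:
    """Per-voxel 6-neighbor scan; the image border counts as outside."""
    nx, ny, nz = grid.shape
    pts = set()
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not grid[i, j, k]:
                    continue
                on_boundary = False
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                        on_boundary = True
                        break
                    if not grid[ii, jj, kk]:
                        on_boundary = True
                        break
                if on_boundary:
                    pts.add((i * spacing[0], j * spacing[1], k * spacing[2]))
    return pts


def directed_h95_bruteforce(a_points: np.ndarray, g_points: np.ndarray) -> float:
    """All-pairs minimum distances, sorted; K-th order statistic with
    K = ceil(0.95 * N_a)."""
    mins = []
    for a in a_points:
        best = min(math.dist(a, g) for g in g_points)
        mins.append(best)
    mins.sort()
    k = max(1, math.ceil(0.95 * len(mins)))
    return mins[k - 1]


def directed_h95_allpairs(a_points: np.ndarray, g_points: np.ndarray) -> float:
    """Same K-th order statistic computed from the full distance matrix
    (chunked so large boundary sets stay in memory)."""
    a = np.asarray(a_points, dtype=float)
    g = np.asarray(g_points, dtype=float)
    mins = np.empty(len(a))
    for start in range(0, len(a), 512):
        chunk = a[start : start + 512]
        d2 = ((chunk[:, None, :] - g[None, :, :]) ** 2).sum(-1)
        mins[start : start + 512] = np.sqrt(d2.min(axis=1))
    mins.sort()
    k = max(1, math.ceil(0.95 * len(mins)))
    return float(mins[k - 1])


def h95_bruteforce(a_points: np.ndarray, g_points: np.ndarray) -> float:
    return max(
        directed_h95_bruteforce(a_points, g_points),
        directed_h95_bruteforce(g_points, a_points),
    )


def h95_allpairs(a_points: np.ndarray, g_points: np.ndarray) -> float:
    return max(
        directed_h95_allpairs(a_points, g_points),
        directed_h95_allpairs(g_points, a_points),
    )
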