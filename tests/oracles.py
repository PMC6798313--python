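"""Brute-force reference implementations used only by the tests.

Each oracle re-derives a quantity by naive enumeration, independent of the
library's vectorized code paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_dft2(image: np.ndarray) -> np.ndarray:
    """O(N^4) double-loop 2-D DFT (unshifted, same convention as fft2)."""
    n, m = image.shape
    out = np.zeros((n, m), dtype=complex)
    for u in range(n):
        for v in range(m):
            acc = 0.0 + 0.0j
            for x in range(n):
                for yy in range(m):
                    acc += image[x, yy] * np.exp(-2j * np.pi * (u * x / n + v * yy / m))
            out[u, v] = acc
    return out


def naive_wedge_average(spectrum: np.ndarray, orientation: str) -> dict[int, float]:
    """Per-pixel loop radial binning within a 90-degree double wedge."""
    n = spectrum.shape[0]
    center = n // 2
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i in range(n):
        for j in range(n):
            dr = i - center
            dc = j - center
            r = int(round(math.hypot(dr, dc)))
            if r < 1 or r > n // 2:
                continue
            in_vertical = abs(dc) <= abs(dr)
            if orientation.startswith("vertical") != in_vertical:
                continue
            sums[r] = sums.get(r, 0.0) + spectrum[i, j]
            counts[r] = counts.get(r, 0) + 1
    return {r: sums[r] / counts[r] for r in sums}


def _circumcircle(p1, p2, p3):
    """Center and squared radius of the circle through three points."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    r2 = (ax - ux) ** 2 + (ay - uy) ** 2
    return (ux, uy), r2


def brute_delaunay_neighbors(points: np.ndarray) -> list[set[int]]:
    """Delaunay adjacency by the empty-circumcircle test over all triples.

    A triangle is Delaunay iff no other point lies strictly inside its
    circumcircle; its edges are then Delaunay edges.  O(n^4), fine for
    n <= 50.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i, j, k in itertools.combinations(range(n), 3):
        cc = _circumcircle(pts[i], pts[j], pts[k])
        if cc is None:
            continue
        (ux, uy), r2 = cc
        d2 = (pts[:, 0] - ux) ** 2 + (pts[:, 1] - uy) ** 2
        d2[[i, j, k]] = np.inf
        if np.all(d2 > r2 * (1.0 - 1e-12)):
            neighbors[i].update((j, k))
            neighbors[j].update((i, k))
            neighbors[k].update((i, j))
    return neighbors


def brute_prominence(values: np.ndarray, peak_index: int) -> float:
    """Larger one-sided drop from a peak to its flanking bases, by scanning.

    Each base is the minimum value between the peak and the nearest point
    exceeding the peak value (or the array boundary).
    """
    v = np.asarray(values, dtype=float)
    drops = []
    for step in (-1, 1):
        base = v[peak_index]
        i = peak_index + step
        while 0 <= i < v.size and v[i] <= v[peak_index]:
            base = min(base, v[i])
            i += step
        drops.append(v[peak_index] - base)
    return max(drops)


def grid_search_exp1(r: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Two-stage grid search for v ~ A*exp(B*r), minimizing SSE."""
    best = (np.inf, 1.0, 0.0)
    a_grid = np.linspace(max(v.max(), 1e-6) * 0.2, max(v.max(), 1e-6) * 3.0, 60)
    b_grid = np.linspace(-0.5, 0.1, 121)
    for _ in range(3):
        for a in a_grid:
            pred = a * np.exp(np.outer(b_grid, r))
            sse = np.sum((pred - v) ** 2, axis=1)
            k = int(np.argmin(sse))
            if sse[k] < best[0]:
                best = (float(sse[k]), float(a), float(b_grid[k]))
        _, a0, b0 = best
        a_grid = np.linspace(a0 * 0.9, a0 * 1.1, 60)
        b_grid = np.linspace(b0 - 0.02, b0 + 0.02, 121)
    return best[1], best[2]
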