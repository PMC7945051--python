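"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (pure-Python loops, exact rational
arithmetic) and shares no code with the package.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction

import numpy as np


def otsu_exhaustive(values, counts) -> int:
    """Smallest threshold maximising between-class variance, in exact rationals.

    Foreground is strictly greater than the threshold; candidates are the
    observed values except the largest.
    """
    values = [int(v) for v in values]
    counts = [int(c) for c in counts]
    best_t = None
    best_var = None
    for i in range(len(values) - 1):
        n0 = sum(counts[: i + 1])
        s0 = sum(v * c for v, c in zip(values[: i + 1], counts[: i + 1]))
        n1 = sum(counts[i + 1 :])
        s1 = sum(v * c for v, c in zip(values[i + 1 :], counts[i + 1 :]))
        mu0 = Fraction(s0, n0)
        mu1 = Fraction(s1, n1)
        var = Fraction(n0 * n1) * (mu0 - mu1) ** 2  # scale-free comparison
        if best_var is None or var > best_var:
            best_var = var
            best_t = values[i]
    return best_t


def bfs_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components of a 3D mask by flood fill; returns voxel sets."""
    if connectivity == 26:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    components = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        comp = []
        while queue:
            z, y, x = queue.popleft()
            comp.append((z, y, x))
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nx < shape[2]
                    and mask[nz, ny, nx]
                    and not seen[nz, ny, nx]
                ):
                    seen[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
        components.append(frozenset(comp))
    return components


def median_brute(mask: np.ndarray, size: int) -> np.ndarray:
    """Cubic-neighbourhood median via literal sort-and-take-middle."""
    pad = size // 2
    # edge-repeating reflection, the ndimage "reflect" boundary convention
    padded = np.pad(mask, pad, mode="symmetric")
    out = np.zeros_like(mask)
    for z in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for x in range(mask.shape[2]):
                block = padded[z : z + size, y : y + size, x : x + size]
                vals = sorted(block.ravel().tolist())
                out[z, y, x] = vals[len(vals) // 2]
    return out


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def cluster_pairwise(points: np.ndarray, d1: float, d2: float) -> list[frozenset]:
    """Spikelet partition via O(n^2) union-find over all grain pairs."""
    n = len(points)
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            dist = float(np.linalg.norm(points[i] - points[j]))
            dz = abs(float(points[i][2] - points[j][2]))
            if dist <= d1 and dz <= d2:
                uf.union(i, j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]
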