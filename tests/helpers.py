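"""Independent brute-force oracles used by the tests.

Everything here is written as plainly as possible (nested loops, explicit
enumeration) and stays independent of the library code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

PAD_MODE = {"replicate": "edge", "reflect": "reflect", "zero": "constant"}

# radius-3 Bresenham circle, clockwise from straight up (independent copy)
CIRCLE = (
    (-3, 0), (-3, 1), (-2, 2), (-1, 3), (0, 3), (1, 3), (2, 2), (3, 1),
    (3, 0), (3, -1), (2, -2), (1, -3), (0, -3), (-1, -3), (-2, -2), (-3, -1),
)


def brute_convolve3d(
    pixels: np.ndarray,
    kernel: np.ndarray,
    spatial_border: str = "replicate",
    channel_border: str = "zero",
    output_plane: str = "green",
) -> np.ndarray:
    """Triple-nested-loop 3D convolution of an H×W×3 volume."""
    m = kernel.shape[0]
    p = m // 2
    H, W, _ = pixels.shape
    x = np.pad(pixels, ((p, p), (p, p), (0, 0)), mode=PAD_MODE[spatial_border])
    x = np.pad(
        x, ((0, 0), (0, 0), (p, p)),
        mode="constant" if channel_border == "zero" else "edge",
    )
    out = np.zeros((H, W, 3))
    for i in range(H):
        for j in range(W):
            for z in range(3):
                acc = 0.0
                for s in range(m):
                    for t in range(m):
                        for u in range(m):
                            acc += kernel[s, t, u] * x[
                                i + (m - 1) - s, j + (m - 1) - t, z + (m - 1) - u
                            ]
                out[i, j, z] = acc
    if output_plane == "green":
        return out[:, :, 1]
    return out.mean(axis=2)


def brute_convolve2d(
    channel: np.ndarray, kernel: np.ndarray, spatial_border: str = "replicate"
) -> np.ndarray:
    """Nested-loop 2D convolution of one channel."""
    m = kernel.shape[0]
    p = m // 2
    H, W = channel.shape
    x = np.pad(channel, p, mode=PAD_MODE[spatial_border])
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for s in range(m):
                for t in range(m):
                    acc += kernel[s, t] * x[i + (m - 1) - s, j + (m - 1) - t]
            out[i, j] = acc
    return out


def brute_fast_brighter(channel: np.ndarray, t: float, arc: int) -> list[tuple[int, int]]:
    """Brute-force brighter-polarity FAST: for each interior pixel walk
    every rotation of the circle and look for a contiguous darker run."""
    H, W = channel.shape
    feats = []
    for r in range(3, H - 3):
        for c in range(3, W - 3):
            darker = [channel[r + dr, c + dc] < channel[r, c] - t for dr, dc in CIRCLE]
            found = False
            for start in range(16):
                if all(darker[(start + k) % 16] for k in range(arc)):
                    found = True
                    break
            if found:
                feats.append((r, c))
    return feats


def brute_single_linkage(coords: np.ndarray, cutoff: float) -> list[list[int]]:
    """Union-find over all pairs with distance <= cutoff."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if math.hypot(*(coords[i] - coords[j])) <= cutoff:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def percentile_split(values: np.ndarray, pct: float) -> tuple[np.ndarray, np.ndarray]:
    """Sort-based split: strictly above the linear-interpolation percentile."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(v)
    pos = pct / 100.0 * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    split = v[lo] + (pos - lo) * (v[hi] - v[lo])
    above = v[v > split]
    below = v[v <= split]
    return above, below


def optimal_match_count(before: np.ndarray, after: np.ndarray, radius: float) -> int:
    """Maximum-cardinality matching within a radius via the assignment
    problem on a padded cost matrix."""
    from scipy.optimize import linear_sum_assignment

    if len(before) == 0 or len(after) == 0:
        return 0
    big = 1e9
    d = np.linalg.norm(before[:, None, :] - after[None, :, :], axis=2)
    cost = np.where(d <= radius, d, big)
    ri, ci = linear_sum_assignment(cost)
    return int((cost[ri, ci] < big).sum())
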