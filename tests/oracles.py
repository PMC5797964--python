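"""Independent reference implementations used as test oracles.

Each oracle recomputes a quantity by the most literal method available
(exhaustive search, dense convolution, flood fill, all-pairs distances) and
is kept deliberately separate from the package code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def triangle_oracle(counts: np.ndarray) -> int:
    """Exhaustive triangle threshold: literal point-to-line distances."""
    counts = np.asarray(counts, dtype=float)
    nonzero = np.flatnonzero(counts)
    peak = int(np.argmax(counts))
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    tail = hi if (hi - peak) >= (peak - lo) else lo
    x1, y1 = float(peak), float(counts[peak])
    x2, y2 = float(tail), float(counts[tail])
    denom = math.hypot(y2 - y1, x2 - x1)
    best_bin, best_d = None, -1.0
    rng = range(peak, tail + 1) if tail > peak else range(tail, peak + 1)
    for b in rng:
        d = abs((y2 - y1) * b - (x2 - x1) * counts[b] + x2 * y1 - y2 * x1) / denom
        if d > best_d:
            best_d, best_bin = d, b
    return int(best_bin)


def kapur_oracle(counts: np.ndarray) -> int:
    """Exhaustive Kapur threshold: per-candidate entropies from scratch."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    best_t, best_h = None, -np.inf
    for t in range(255):
        p0 = p[: t + 1].sum()
        p1 = p[t + 1:].sum()
        if p0 <= 0 or p1 <= 0:
            continue
        q0 = p[: t + 1][p[: t + 1] > 0] / p0
        q1 = p[t + 1:][p[t + 1:] > 0] / p1
        h = -np.sum(q0 * np.log(q0)) - np.sum(q1 * np.log(q1))
        if h > best_h:
            best_h, best_t = h, t
    return int(best_t)


def random_histogram(rng: np.random.Generator) -> np.ndarray:
    """Random 256-bin histogram: Gaussian-mixture counts plus sparse noise."""
    counts = np.zeros(256, dtype=np.int64)
    for _ in range(rng.integers(1, 4)):
        mu = rng.uniform(10, 245)
        sd = rng.uniform(3, 40)
        n = int(rng.integers(200, 20000))
        samples = np.clip(rng.normal(mu, sd, size=n), 0, 255).astype(int)
        counts += np.bincount(samples, minlength=256)
    noise_bins = rng.integers(0, 256, size=rng.integers(0, 30))
    counts += np.bincount(noise_bins, minlength=256)
    if np.count_nonzero(counts) < 2:  # pragma: no cover - vanishingly rare
        counts[10] += 5
        counts[200] += 5
    return counts


def window_variance_oracle(data: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force per-window population variance with symmetric padding."""
    padded = np.pad(data, radius, mode="symmetric")
    out = np.empty_like(data, dtype=float)
    for z in range(data.shape[0]):
        for y in range(data.shape[1]):
            for x in range(data.shape[2]):
                w = padded[z: z + 2 * radius + 1,
                           y: y + 2 * radius + 1,
                           x: x + 2 * radius + 1]
                out[z, y, x] = w.var()
    return out


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Truncated sampled Gaussian kernel (truncate = 4 sigma), normalized."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def dense_gaussian_convolution(data: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian smoothing by explicit dense 1D convolutions."""
    k = gaussian_kernel_1d(sigma)
    radius = (k.size - 1) // 2
    out = data.astype(float)
    for axis in range(3):
        moved = np.moveaxis(out, axis, -1)
        padded = np.pad(moved, [(0, 0), (0, 0), (radius, radius)], mode="symmetric")
        res = np.empty_like(moved)
        for i in range(moved.shape[-1]):
            res[..., i] = np.tensordot(padded[..., i: i + k.size], k, axes=([-1], [0]))
        out = np.moveaxis(res, -1, axis)
    return out


def flood_fill_label_oracle(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """BFS 26-connected labeling of a binary grid."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in np.argwhere(mask):
        start = tuple(start)
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                q = (z + dz, y + dy, x + dx)
                if all(0 <= qi < n for qi, n in zip(q, mask.shape)):
                    if mask[q] and not labels[q]:
                        labels[q] = current
                        stack.append(q)
    return labels, current


def all_pairs_feret_oracle(
    coords_um: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """O(n^2) maximal pairwise distance over object voxel coordinates."""
    best = (None, None, -1.0)
    n = coords_um.shape[0]
    for i in range(n):
        d = np.linalg.norm(coords_um[i + 1:] - coords_um[i], axis=1)
        if d.size == 0:
            continue
        j = int(np.argmax(d))
        if d[j] > best[2]:
            best = (coords_um[i], coords_um[i + 1 + j], float(d[j]))
    return best


def random_blob_mask(rng: np.random.Generator, shape=(14, 14, 14)) -> np.ndarray:
    """Random connected-ish blob: thresholded smoothed noise, nonempty."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    mask = field > np.quantile(field, rng.uniform(0.75, 0.92))
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))
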