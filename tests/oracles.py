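"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain per-pixel Python loops
over nested lists, sharing no code path with the package: morphology as
exhaustive neighborhood min/max with explicit border clamping, features
and quality metrics as straight double loops.
"""

from __future__ import annotations

import math

import numpy as np

C1 = (0.01 * 255) ** 2
C2 = (0.03 * 255) ** 2


def _clamp(v: int, lo: int, hi: int) -> int:
    return lo if v < lo else hi if v > hi else v


def _as_lists(arr) -> list[list[float]]:
    return np.asarray(arr, dtype=float).tolist()


def oracle_erode(arr, offsets) -> np.ndarray:
    """min over x[i + s] for s in offsets; replicate border."""
    rows = _as_lists(arr)
    h, w = len(rows), len(rows[0])
    out = [[0.0] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            out[i][j] = min(
                rows[_clamp(i + dr, 0, h - 1)][_clamp(j + dc, 0, w - 1)]
                for dr, dc in offsets
            )
    return np.array(out)


def oracle_dilate(arr, offsets) -> np.ndarray:
    """max over x[i - s] for s in offsets (reflected support); replicate border."""
    rows = _as_lists(arr)
    h, w = len(rows), len(rows[0])
    out = [[0.0] * w for _ in range(h)]
    for i in range(h):
        for j in range(w):
            out[i][j] = max(
                rows[_clamp(i - dr, 0, h - 1)][_clamp(j - dc, 0, w - 1)]
                for dr, dc in offsets
            )
    return np.array(out)


def oracle_open(arr, offsets) -> np.ndarray:
    return oracle_dilate(oracle_erode(arr, offsets), offsets)


def oracle_close(arr, offsets) -> np.ndarray:
    return oracle_erode(oracle_dilate(arr, offsets), offsets)


def oracle_gradient_p(arr, offsets, which: int) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    d = oracle_dilate(arr, offsets)
    e = oracle_erode(arr, offsets)
    if which == 1:
        return d - arr
    if which == 2:
        return arr - e
    if which == 3:
        return d - e
    # p4..p6 involve opening/closing, whose border-padded compositions can
    # dip below zero for one-sided supports; clamped like the implementation
    if which == 4:
        return np.maximum(arr - oracle_open(arr, offsets), 0.0)
    if which == 5:
        return np.maximum(oracle_close(arr, offsets) - arr, 0.0)
    if which == 6:
        return np.maximum(
            oracle_close(arr, offsets) - oracle_open(arr, offsets), 0.0
        )
    raise ValueError(which)


def oracle_gradient_q(arr, offsets, which: int) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if which == 1:
        base = oracle_close(arr, offsets)
        raw = oracle_open(base, offsets) - oracle_erode(base, offsets)
    elif which == 2:
        base = oracle_open(arr, offsets)
        raw = oracle_dilate(base, offsets) - oracle_close(base, offsets)
    else:
        raise ValueError(which)
    return np.maximum(raw, 0.0)


# 3x3 neighbor offsets per label d1..d8 (d1 above center, clockwise)
NEIGHBORS = {
    1: (-1, 0), 2: (-1, 1), 3: (0, 1), 4: (1, 1),
    5: (1, 0), 6: (1, -1), 7: (0, -1), 8: (-1, -1),
}


def oracle_fine_features(arr) -> list[float]:
    rows = _as_lists(arr)
    h, w = len(rows), len(rows[0])
    l = [0.0] * 9
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            d0 = rows[i][j]
            for x, (dr, dc) in NEIGHBORS.items():
                l[x] += (d0 - rows[i + dr][j + dc]) ** 2
    return l[1:]


def oracle_axis_features(arr) -> list[float]:
    l = oracle_fine_features(arr)
    return [l[0] + l[4], l[1] + l[5], l[2] + l[6], l[3] + l[7]]


def oracle_mse(a, b) -> float:
    ra, rb = _as_lists(a), _as_lists(b)
    total = 0.0
    n = 0
    for row_a, row_b in zip(ra, rb):
        for va, vb in zip(row_a, row_b):
            total += (va - vb) ** 2
            n += 1
    return total / n


def oracle_psnr(a, b, peak_power: float = 65536.0) -> float:
    err = oracle_mse(a, b)
    if err == 0:
        return math.inf
    return 10.0 * math.log10(peak_power / err)


def oracle_ssim_global(a, b) -> float:
    ra, rb = _as_lists(a), _as_lists(b)
    n = len(ra) * len(ra[0])
    ma = sum(sum(row) for row in ra) / n
    mb = sum(sum(row) for row in rb) / n
    va = sum((v - ma) ** 2 for row in ra for v in row) / n
    vb = sum((v - mb) ** 2 for row in rb for v in row) / n
    cov = (
        sum(
            (va_ - ma) * (vb_ - mb)
            for row_a, row_b in zip(ra, rb)
            for va_, vb_ in zip(row_a, row_b)
        )
        / n
    )
    return ((2 * ma * mb + C1) * (2 * cov + C2)) / (
        (ma**2 + mb**2 + C1) * (va + vb + C2)
    )


def oracle_ssim_windowed(a, b, window: int = 8) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    h, w = a.shape
    scores = []
    for i in range(h - window + 1):
        for j in range(w - window + 1):
            scores.append(
                oracle_ssim_global(a[i : i + window, j : j + window],
                                   b[i : i + window, j : j + window])
            )
    return float(np.mean(scores))
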