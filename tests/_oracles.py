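"""Independent brute-force oracles used to validate the fast implementations.

Every function here is a deliberately naive per-pixel / per-permutation
computation, kept free of the code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Nested-loop 2-D correlation with symmetric (reflective) padding."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(img, ((ph, ph), (pw, pw)), mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += kernel[a, b] * padded[i + a, j + b]
            out[i, j] = acc
    return out


def brute_phansalkar_threshold(
    img: np.ndarray, radius: int, k: float, r: float, p: float, q: float,
    window: str = "circular",
) -> np.ndarray:
    """Per-pixel windowed Phansalkar threshold map (not the binary mask)."""
    n0, n1 = img.shape
    padded = np.pad(img, radius, mode="symmetric")
    ax = np.arange(-radius, radius + 1)
    if window == "circular":
        foot = (ax[:, None] ** 2 + ax[None, :] ** 2) <= radius**2
    else:
        foot = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    t = np.zeros_like(img, dtype=float)
    for i in range(n0):
        for j in range(n1):
            vals = padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1][foot]
            m = vals.mean()
            s = math.sqrt(max(np.mean(vals**2) - m * m, 0.0))
            t[i, j] = m * (1.0 + p * math.exp(-q * m) + k * ((s / r) - 1.0))
    return t


def brute_distance_map(lesion: np.ndarray, pitch_um: float) -> np.ndarray:
    """O(N*M) nearest-lesion-pixel Euclidean distance, in micrometres."""
    pts = np.argwhere(lesion)
    out = np.zeros(lesion.shape, dtype=float)
    for i in range(lesion.shape[0]):
        for j in range(lesion.shape[1]):
            if lesion[i, j]:
                continue
            d2 = (pts[:, 0] - i) ** 2 + (pts[:, 1] - j) ** 2
            out[i, j] = math.sqrt(float(d2.min())) * pitch_um
    return out


def rasterize_disk(n: int, cy: float, cx: float, radius_px: float) -> np.ndarray:
    """Pixel-centre-in-circle rasterization via an independent per-pixel loop."""
    out = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if (i - cy) ** 2 + (j - cx) ** 2 <= radius_px**2:
                out[i, j] = True
    return out


def spearman_exact(x, y) -> tuple[float, float]:
    """Spearman rho with exact two-sided permutation p, by full enumeration."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)

    def rho_of(a, b):
        a = a - np.mean(a)
        b = b - np.mean(b)
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    rho = rho_of(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(rx, np.array(perm))) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total


def icc21_anova(g1, g2) -> float:
    """ICC(2,1) by the two-way random-effects ANOVA mean-squares decomposition."""
    data = np.column_stack([np.asarray(g1, float), np.asarray(g2, float)])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(
        (ms_rows - ms_err)
        / (ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)
    )
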