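"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algorithmic paths: exhaustive
path enumeration for DTW, direct discrete convolution for Gaussian
smoothing, and plain numerical differentiation for jerk.
"""

import numpy as np


def dtw_enumerate(a, b) -> float:
    """Minimal summed local cost over ALL monotone warping paths,
    enumerated recursively (exponential; lengths <= ~7 only)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = len(a), len(b)
    best = [np.inf]

    def rec(i, j, acc):
        acc = acc + float(np.hypot(a[i, 0] - b[j, 0], a[i, 1] - b[j, 1]))
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, acc)
        if i + 1 < n:
            rec(i + 1, j, acc)
        if j + 1 < m:
            rec(i, j + 1, acc)

    rec(0, 0, 0.0)
    return best[0]


def gaussian_convolve(signal, sigma, truncate=4.0) -> np.ndarray:
    """Direct discrete Gaussian convolution with reflect boundary, using
    the same kernel truncation rule as scipy's filter."""
    signal = np.asarray(signal, float)
    lw = int(truncate * sigma + 0.5)
    idx = np.arange(-lw, lw + 1)
    kernel = np.exp(-0.5 * (idx / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.concatenate([signal[lw - 1 :: -1] if lw else signal[:0],
                             signal,
                             signal[: -lw - 1 : -1] if lw else signal[:0]])
    out = np.empty_like(signal)
    for i in range(len(signal)):
        out[i] = float((padded[i : i + 2 * lw + 1] * kernel[::-1]).sum())
    return out


def jerk_rms_numeric(x, y, t) -> float:
    """RMS jerk magnitude by repeated np.gradient on one pen-down run."""
    jx = np.gradient(np.gradient(np.gradient(x, t), t), t)
    jy = np.gradient(np.gradient(np.gradient(y, t), t), t)
    return float(np.sqrt(np.mean(jx**2 + jy**2)))


def two_means_brute(points, seeds=50) -> np.ndarray:
    """Near-exhaustive 2-means on a small point set: many seeded Lloyd runs,
    keep the lowest-inertia solution."""
    points = np.asarray(points, float)
    best = None
    best_inertia = np.inf
    for s in range(seeds):
        rng = np.random.default_rng(s)
        centers = points[rng.choice(len(points), 2, replace=False)]
        for _ in range(100):
            d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
            lab = d.argmin(axis=1)
            if len(np.unique(lab)) < 2:
                break
            new = np.array([points[lab == c].mean(axis=0) for c in (0, 1)])
            if np.allclose(new, centers):
                break
            centers = new
        d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
        inertia = (d.min(axis=1) ** 2).sum()
        if inertia < best_inertia:
            best_inertia = inertia
            best = centers[np.argsort(centers[:, 0])]
    return best
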