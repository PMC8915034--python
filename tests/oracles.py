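"""Brute-force reference implementations used to cross-check the filters
and metrics. Deliberately naive: per-window loops, explicit least
squares, pairwise counting — independent of the library code paths."""

import numpy as np


def sliding_median(x: np.ndarray, window: int) -> np.ndarray:
    """Per-position sort-and-pick-middle with edge reflection."""
    half = window // 2
    padded = np.pad(x, half, mode="symmetric")
    return np.array(
        [np.sort(padded[i : i + window])[half] for i in range(len(x))]
    )


def sliding_mean(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    padded = np.pad(x, half, mode="symmetric")
    return np.array([padded[i : i + window].mean() for i in range(len(x))])


def gaussian_convolution(x: np.ndarray, sigma: float, truncate: float) -> np.ndarray:
    """Dense convolution with an explicitly built normalized kernel."""
    radius = int(truncate * sigma + 0.5)
    t = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(x, radius, mode="symmetric")
    return np.array(
        [float(padded[i : i + 2 * radius + 1] @ kernel[::-1]) for i in range(len(x))]
    )


def savgol_per_window(x: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Per-window polynomial least squares (Vandermonde solve), evaluated
    at the window center; edge values come from the fit to the first/last
    full window evaluated at the off-center positions."""
    half = window // 2
    n = len(x)
    positions = np.arange(-half, half + 1, dtype=float)
    vander = np.vander(positions, polyorder + 1, increasing=True)
    out = np.empty(n)
    for i in range(half, n - half):
        coeffs, *_ = np.linalg.lstsq(vander, x[i - half : i + half + 1], rcond=None)
        out[i] = coeffs[0]  # value of the fit at position 0
    left, *_ = np.linalg.lstsq(vander, x[:window], rcond=None)
    right, *_ = np.linalg.lstsq(vander, x[n - window :], rcond=None)
    for i in range(half):
        out[i] = np.polynomial.polynomial.polyval(i - half, left)
        out[n - 1 - i] = np.polynomial.polynomial.polyval(half - i, right)
    return out


def concordance_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Pairwise concordance probability; ties count one half."""
    pos = scores[np.asarray(y_true) == 1]
    neg = scores[np.asarray(y_true) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def tally_confusion(y_true, y_pred):
    """Element-by-element confusion tally."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn
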