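"""Independent brute-force oracles: direct per-pixel loops over the stated
definitions, kept free of the vectorized code paths they check."""

from __future__ import annotations

import numpy as np


def pad_reflect(img: np.ndarray, pad: int) -> np.ndarray:
    # symmetric = edge-inclusive reflection, the convention used throughout
    return np.pad(img, pad, mode="symmetric")


def window_mean_std(img: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and population sd over a window x window neighborhood."""
    h, w = img.shape
    half = window // 2
    padded = pad_reflect(img, half)
    mean = np.empty_like(img, dtype=float)
    std = np.empty_like(img, dtype=float)
    for i in range(h):
        for j in range(w):
            patch = padded[i : i + window, j : j + window]
            mean[i, j] = patch.mean()
            std[i, j] = patch.std()
    return mean, std


def local_enhance_bf(img, window=5, C=3.0, s=1e-4, gain_cap=5.0):
    mean, std = window_mean_std(img, window)
    out = np.empty_like(img, dtype=float)
    h, w = img.shape
    for i in range(h):
        for j in range(w):
            gain = min(C / (std[i, j] + s), gain_cap)
            out[i, j] = mean[i, j] + gain * (img[i, j] - mean[i, j])
    return np.clip(out, 0.0, 1.0)


def line_response_bf(img, offsets_per_angle, window, inside):
    """R(P) = max_theta mean(img over line offsets) - window mean, 0 outside."""
    h, w = img.shape
    pad = window
    padded = pad_reflect(img, pad)
    win_mean, _ = window_mean_std(img, window)
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            if not inside[i, j]:
                continue
            best = -np.inf
            for offsets in offsets_per_angle:
                total = 0.0
                for dr, dc in offsets:
                    total += padded[pad + i + dr, pad + j + dc]
                best = max(best, total / len(offsets))
            out[i, j] = best - win_mean[i, j]
    return out


def fuse_bf(response_arrays, igc, inside):
    """(sum of responses + igc) / (n + 1) inside the FOV, else 0."""
    h, w = igc.shape
    out = np.zeros((h, w))
    n = len(response_arrays)
    for i in range(h):
        for j in range(w):
            if inside[i, j]:
                total = igc[i, j]
                for r in response_arrays:
                    total += r[i, j]
                out[i, j] = total / (n + 1)
    return out


def confusion_bf(pred, truth, inside):
    tp = fp = tn = fn = 0
    h, w = pred.shape
    for i in range(h):
        for j in range(w):
            if not inside[i, j]:
                continue
            if pred[i, j] and truth[i, j]:
                tp += 1
            elif pred[i, j]:
                fp += 1
            elif truth[i, j]:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn
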