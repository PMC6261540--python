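"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain loops over definitions and
shares no code with the package internals it checks.
"""

import math

import numpy as np


def nearest_seed_scan(xs, ys, usable=None):
    """Exhaustive per-pixel nearest-seed assignment on the 61x61 grid.

    Pixel (i, j), 1-based, sits at degrees (x, y) = (j - 31, 31 - i); every
    seed distance is evaluated and the lowest index wins ties.
    """
    L = len(xs)
    candidates = [l for l in range(L) if usable is None or usable[l]]
    grid = np.empty((61, 61), dtype=int)
    for i in range(1, 62):
        for j in range(1, 62):
            px, py = j - 31, 31 - i
            best_l, best_d = None, math.inf
            for l in candidates:
                d = (xs[l] - px) ** 2 + (ys[l] - py) ** 2
                if d < best_d:  # strict: first (lowest) index keeps ties
                    best_d, best_l = d, l
            grid[i - 1, j - 1] = best_l
    return grid


def ap_enumeration(scores, labels):
    """AP by explicit precision-recall enumeration over unique thresholds."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    n_pos = sum(labels)
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def region_average_scan(values, assignment):
    """Per-region mean by explicit accumulation, mapped back to pixels."""
    sums, counts = {}, {}
    rows, cols = values.shape
    for i in range(rows):
        for j in range(cols):
            l = int(assignment[i, j])
            sums[l] = sums.get(l, 0.0) + float(values[i, j])
            counts[l] = counts.get(l, 0) + 1
    out = np.empty_like(values, dtype=float)
    for i in range(rows):
        for j in range(cols):
            l = int(assignment[i, j])
            out[i, j] = sums[l] / counts[l]
    return out


def f1_scan(scores, labels):
    """Exhaustive threshold scan of PPV*TPR/(PPV+TPR); smallest argmax."""
    n_pos = sum(labels)
    best_t, best_obj = None, -1.0
    for t in sorted(set(map(float, scores))):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        ppv = tp / (tp + fp)
        tpr = tp / n_pos
        obj = 0.0 if ppv + tpr == 0 else ppv * tpr / (ppv + tpr)
        if obj > best_obj + 1e-15:
            best_obj, best_t = obj, t
    return best_t


class LinearScorer:
    """Differentiable toy model O(VI) = sum(w * VI); gradient is w."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def input_gradient(self, X):
        X = np.asarray(X)
        return np.broadcast_to(self.w[None, :, :, None], X.shape).copy()
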