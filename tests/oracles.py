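"""Independent brute-force reference implementations.

These deliberately use the slowest, most transparent algorithm available
(recursive flood fill, frontier scans, exhaustive threshold search,
explicit confusion counting) so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Recursive-DFS connected-component labeling, row-major discovery order."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int64)
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                 if (dy, dx) != (0, 0)]

    def fill(y, x, lab):
        if not (0 <= y < h and 0 <= x < w):
            return
        if not mask[y, x] or labels[y, x]:
            return
        labels[y, x] = lab
        for dy, dx in neigh:
            fill(y + dy, x + dx, lab)

    n = 0
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not labels[y, x]:
                n += 1
                fill(y, x, n)
    return labels, n


def meyer_flood(elevation: np.ndarray, markers: np.ndarray,
                boundary: int = -1) -> np.ndarray:
    """Marker flooding by scanning an explicit candidate list every step.

    Same ordering contract as the fast implementation — (elevation,
    insertion counter) with row-major seeding and up/down/left/right
    neighbors — but realized with a linear scan instead of a heap.
    """
    elevation = np.asarray(elevation, dtype=float)
    labels = np.asarray(markers, dtype=np.int64).copy()
    h, w = labels.shape
    neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    candidates: list[tuple[float, int, int, int]] = []
    counter = 0

    def push_neighbors(y, x):
        nonlocal counter
        for dy, dx in neigh:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and labels[ny, nx] == 0:
                candidates.append((elevation[ny, nx], counter, ny, nx))
                counter += 1

    for y in range(h):
        for x in range(w):
            if labels[y, x] > 0:
                push_neighbors(y, x)

    while candidates:
        best = min(range(len(candidates)), key=lambda i: candidates[i][:2])
        _, _, y, x = candidates.pop(best)
        if labels[y, x] != 0:
            continue
        seen = set()
        for dy, dx in neigh:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and labels[ny, nx] > 0:
                seen.add(int(labels[ny, nx]))
        if len(seen) == 1:
            labels[y, x] = seen.pop()
            push_neighbors(y, x)
        else:
            labels[y, x] = boundary

    labels[labels == 0] = boundary
    return labels


def otsu_exhaustive(values: np.ndarray) -> int:
    """Smallest threshold maximizing between-class variance, by trying all 256."""
    values = np.asarray(values).ravel()
    n = values.size
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            var = 0.0
        else:
            w0, w1 = lo.size / n, hi.size / n
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def confusion_metrics(pred: np.ndarray, true: np.ndarray, num_classes: int = 3):
    """Per-class IoU and dice plus accuracy via explicit pixel counting."""
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    iou, dice = {}, {}
    for k in range(num_classes):
        tp = int(np.sum((pred == k) & (true == k)))
        fp = int(np.sum((pred == k) & (true != k)))
        fn = int(np.sum((pred != k) & (true == k)))
        union = tp + fp + fn
        iou[k] = tp / union if union else 1.0
        denom = 2 * tp + fp + fn
        dice[k] = 2 * tp / denom if denom else 1.0
    acc = float(np.mean(pred == true))
    return iou, dice, acc


def distance_map_bruteforce(mask: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distance to background, frame counts as background."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    bg = [(y, x) for y in range(-1, h + 1) for x in range(-1, w + 1)
          if not (0 <= y < h and 0 <= x < w) or not mask[y, x]]
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                out[y, x] = min(np.hypot(y - by, x - bx) for by, bx in bg)
    return out
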