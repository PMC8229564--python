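"""Independent brute-force reference implementations used by the test suite.

Deliberately naive (explicit Python loops, no shared code with the package)
so they can serve as oracles for the vectorised/library-backed operations.
"""

from __future__ import annotations

import heapq
import math

import numpy as np


def brute_boundary_region(mask: np.ndarray, width: int) -> np.ndarray:
    """Euclidean dilation by ``width`` minus the mask, pixel by pixel."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    pts = np.argwhere(mask)
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                continue
            for pr, pc in pts:
                if (r - pr) ** 2 + (c - pc) ** 2 <= width**2:
                    out[r, c] = True
                    break
    return out.astype(np.uint8)


def brute_face_points(region: np.ndarray, lam: np.ndarray, window: int):
    """Exhaustive window-mean search; first extremum in row-major order wins."""
    region = np.asarray(region).astype(bool)
    lam = np.asarray(lam, dtype=float)
    h, w = region.shape
    half = window // 2
    best_hi = -math.inf
    best_lo = math.inf
    hi_pt = lo_pt = None
    for r in range(h):
        for c in range(w):
            if not region[r, c]:
                continue
            vals = []
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        vals.append(lam[rr, cc])
            m = sum(vals) / len(vals)
            if m > best_hi:
                best_hi, hi_pt = m, (r, c)
            if m < best_lo:
                best_lo, lo_pt = m, (r, c)
    return hi_pt, lo_pt, best_hi, best_lo


def brute_bresenham(p0, p1):
    """Classic integer Bresenham (doubled-error form) from p0 to p1 inclusive."""
    r0, c0 = int(p0[0]), int(p0[1])
    r1, c1 = int(p1[0]), int(p1[1])
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    pts = []
    if dc >= dr:
        d = 2 * dr - dc
        r = r0
        for c in range(c0, c1 + sc, sc):
            pts.append((r, c))
            if d >= 0:
                r += sr
                d -= 2 * dc
            d += 2 * dr
    else:
        d = 2 * dc - dr
        c = c0
        for r in range(r0, r1 + sr, sr):
            pts.append((r, c))
            if d >= 0:
                c += sc
                d -= 2 * dr
            d += 2 * dc
    return pts


def brute_insulin_line(line, insulin, mask, window):
    """Max of windowed in-cell means along a line; NaN when never in-cell."""
    ins = np.asarray(insulin, dtype=float)
    mask = np.asarray(mask).astype(bool)
    h, w = ins.shape
    lo = window // 2
    hi = window - lo - 1
    best = math.nan
    for r, c in line:
        if not (0 <= r < h and 0 <= c < w) or not mask[r, c]:
            continue
        vals = []
        for dr in range(-lo, hi + 1):
            for dc in range(-lo, hi + 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    vals.append(ins[rr, cc])
        if vals:
            m = sum(vals) / len(vals)
            if math.isnan(best) or m > best:
                best = m
    return best


def brute_confusion_metrics(pred, truth):
    """Confusion counts and derived metrics by explicit pixel loop."""
    pred = np.asarray(pred).astype(bool).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    tp = fp = fn = tn = 0
    for p, t in zip(pred, truth):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    return dict(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision, recall=recall, f1=f1, accuracy=accuracy)


def brute_label_boundaries(labels: np.ndarray) -> np.ndarray:
    """4-neighbour scan for instance boundary pixels (image edge = background)."""
    labels = np.asarray(labels)
    h, w = labels.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            if labels[r, c] == 0:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                nb = labels[rr, cc] if 0 <= rr < h and 0 <= cc < w else 0
                if nb != labels[r, c]:
                    out[r, c] = 1
                    break
    return out


def brute_watershed_flood(image, markers, mask):
    """Priority flood from markers: lowest value first, FIFO on ties."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    h, w = image.shape
    labels = np.asarray(markers).copy()
    heap = []
    age = 0
    for r, c in np.argwhere(labels > 0):
        heapq.heappush(heap, (image[r, c], age, r, c))
        age += 1
    while heap:
        _, _, r, c = heapq.heappop(heap)
        lab = labels[r, c]
        for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                labels[rr, cc] = lab
                heapq.heappush(heap, (image[rr, cc], age, rr, cc))
                age += 1
    return labels
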