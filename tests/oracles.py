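"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (explicit loops, direct
formulas) of quantities the package computes with vectorized code; they
are kept separate from, and share no code with, the implementations they
check.
"""

from __future__ import annotations

import numpy as np


def bh_stepup(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adjusted[i] = min(val, 1.0)
        prev = adjusted[i]
    return np.array(adjusted)


def window_list(n_items, n_windows, overlap):
    """Window (start, stop) pairs: equal width w = round((G + o*(k-1))/k),
    step w - o, last window absorbing the remainder."""
    if n_items < n_windows:
        n_windows = max(1, n_items // 2)
        overlap = min(overlap, max(0, -(-n_items // n_windows) - 1))
    w = max(1, int(round((n_items + overlap * (n_windows - 1)) / n_windows)))
    step = w - overlap
    out = []
    for i in range(n_windows):
        start = i * step
        stop = n_items if i == n_windows - 1 else min(start + w, n_items)
        out.append((start, stop))
    return out


def rolling_median_residual_bruteforce(y, x, ids, n_windows, overlap):
    """Per-item residual of y vs the median of every window containing
    the item (windows over items sorted by (x, id))."""
    items = sorted(range(len(y)), key=lambda i: (x[i], ids[i]))
    windows = window_list(len(items), n_windows, overlap)
    expected = {}
    for i_pos, i in enumerate(items):
        meds = []
        for start, stop in windows:
            if start <= i_pos < stop:
                meds.append(float(np.median([y[j] for j in items[start:stop]])))
        expected[i] = sum(meds) / len(meds)
    return np.array([y[i] - expected[i] for i in range(len(y))])


def dm_bruteforce(cpm, gene_ids, lengths, n_windows=50, overlap=25):
    """Three-step DM: CV^2, mean-corrected residual, length correction.

    cpm is genes x samples; genes with zero CV^2 get (dataset min - 1).
    Returns DM per gene in input order.
    """
    cpm = np.asarray(cpm, dtype=float)
    means = cpm.mean(axis=1)
    cv2 = cpm.var(axis=1, ddof=1) / means**2
    ok = cv2 > 0
    idx = [i for i in range(len(cv2)) if ok[i]]
    y = [float(np.log10(cv2[i])) for i in idx]
    x = [float(np.log10(means[i])) for i in idx]
    ids = [gene_ids[i] for i in idx]
    resid = rolling_median_residual_bruteforce(y, x, ids, n_windows, overlap)
    if lengths is not None:
        lx = [float(np.log10(lengths[i])) for i in idx]
        dm_ok = rolling_median_residual_bruteforce(
            list(resid), lx, ids, n_windows, overlap
        )
    else:
        dm_ok = resid
    dm = np.empty(len(cv2))
    for pos, i in enumerate(idx):
        dm[i] = dm_ok[pos]
    if (~ok).any():
        sentinel = dm[ok].min() - 1.0 if ok.any() else -1.0
        dm[~ok] = sentinel
    return dm


def snn_jaccard_bruteforce(points, k):
    """All-pairs SNN Jaccard weights from k-nearest neighbor sets
    (Euclidean, self included, distance ties broken by index)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    neighbor_sets = []
    for i in range(n):
        dists = [(float(np.sum((points[i] - points[j]) ** 2)), j) for j in range(n)]
        dists.sort()
        neighbor_sets.append({j for _, j in dists[:k]})
    weights = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = neighbor_sets[i], neighbor_sets[j]
            weights[(i, j)] = len(a & b) / len(a | b)
    return weights


def gsea_es_bruteforce(scores, in_set):
    """Weighted KS running sum, step by step."""
    scores = [abs(float(s)) for s in scores]
    n = len(scores)
    n_hit = sum(in_set)
    n_miss = n - n_hit
    total_hit = sum(s for s, m in zip(scores, in_set) if m)
    running = 0.0
    best = 0.0
    for s, m in zip(scores, in_set):
        if m:
            running += (s / total_hit) if total_hit > 0 else (1.0 / n_hit)
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best
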