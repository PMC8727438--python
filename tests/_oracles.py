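"""Independent brute-force oracles used by the test suite.

Everything here is written as straight-line, loop-based code from the
definitions, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_sessions(timestamps, threshold=5.0):
    """Split a sorted timestamp list at every gap >= threshold."""
    sessions = []
    current = []
    prev = None
    for t in timestamps:
        if prev is not None and (t - prev) >= threshold:
            sessions.append(current)
            current = []
        current.append(t)
        prev = t
    if current:
        sessions.append(current)
    return sessions


def brute_sampen(series, m=2, r_factor=0.2, tau=1, min_len=10):
    """O(n²) template-counting sample entropy; NaN when undefined."""
    x = [float(v) for v in series]
    n = len(x)
    if n < min_len:
        return float("nan")
    n_templates = n - m * tau
    if n_templates < 2:
        return float("nan")
    mean = sum(x) / n
    r = r_factor * math.sqrt(sum((v - mean) ** 2 for v in x) / n)

    def count(length):
        total = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                dmax = 0.0
                for k in range(length):
                    d = abs(x[i + k * tau] - x[j + k * tau])
                    if d > dmax:
                        dmax = d
                if dmax <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def brute_mad(values):
    x = sorted(float(v) for v in values)
    med = _median(x)
    return _median(sorted(abs(v - med) for v in x))


def _median(sorted_x):
    n = len(sorted_x)
    mid = n // 2
    if n % 2:
        return sorted_x[mid]
    return 0.5 * (sorted_x[mid - 1] + sorted_x[mid])


def brute_summaries(values):
    """(mean, median, sample sd, unscaled MAD) via plain loops."""
    x = [float(v) for v in values if not math.isnan(v)]
    n = len(x)
    if n == 0:
        return (float("nan"),) * 4
    mean = sum(x) / n
    med = _median(sorted(x))
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1)) if n >= 2 else float("nan")
    return mean, med, sd, brute_mad(x)


def brute_ale1(predict_fn, data, feature, n_bins):
    """Loop implementation of the first-order ALE definition.

    Returns (edges, centered effect at edges).
    """
    x = np.asarray(data[feature], dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    K = len(edges) - 1
    bin_of = []
    for v in x:
        k = 0
        for b in range(K):
            lo, hi = edges[b], edges[b + 1]
            if (v > lo or (b == 0 and v >= lo)) and v <= hi:
                k = b
                break
        bin_of.append(k)
    sums = [0.0] * K
    counts = [0] * K
    for i, b in enumerate(bin_of):
        row_hi = data.iloc[[i]].copy()
        row_lo = data.iloc[[i]].copy()
        row_hi[feature] = edges[b + 1]
        row_lo[feature] = edges[b]
        sums[b] += float(predict_fn(row_hi)[0]) - float(predict_fn(row_lo)[0])
        counts[b] += 1
    effect = [0.0]
    for b in range(K):
        mean = sums[b] / counts[b] if counts[b] else 0.0
        effect.append(effect[-1] + mean)
    effect = np.array(effect)
    centered = effect - np.mean(np.interp(x, edges, effect))
    return edges, centered


def brute_ale2(predict_fn, data, f1, f2, n_bins):
    """Loop implementation of the second-order ALE definition.

    Same mathematical recipe as the package (cell-mean second differences,
    2-D accumulation, four-corner cell values, removal of count-weighted
    additive structure) but computed observation by observation, with the
    additive removal done by iterated weighted centering instead of a
    least-squares solve.  Returns (edges1, edges2, effect, counts).
    """
    x1 = np.asarray(data[f1], dtype=float)
    x2 = np.asarray(data[f2], dtype=float)
    e1 = np.unique(np.quantile(x1, np.linspace(0, 1, n_bins + 1)))
    e2 = np.unique(np.quantile(x2, np.linspace(0, 1, n_bins + 1)))
    K1, K2 = len(e1) - 1, len(e2) - 1

    def bin_of(v, edges):
        K = len(edges) - 1
        for b in range(K):
            if (v > edges[b] or (b == 0 and v >= edges[b])) and v <= edges[b + 1]:
                return b
        return K - 1

    sums = np.zeros((K1, K2))
    counts = np.zeros((K1, K2))
    for i in range(len(x1)):
        j = bin_of(x1[i], e1)
        k = bin_of(x2[i], e2)
        vals = {}
        for c1, z1 in (("l", e1[j]), ("h", e1[j + 1])):
            for c2, z2 in (("l", e2[k]), ("h", e2[k + 1])):
                row = data.iloc[[i]].copy()
                row[f1] = z1
                row[f2] = z2
                vals[c1 + c2] = float(predict_fn(row)[0])
        sums[j, k] += vals["hh"] - vals["lh"] - vals["hl"] + vals["ll"]
        counts[j, k] += 1
    M = np.zeros((K1, K2))
    for j in range(K1):
        for k in range(K2):
            if counts[j, k] > 0:
                M[j, k] = sums[j, k] / counts[j, k]
    # nearest-occupied fill for empty cells
    occ = [(j, k) for j in range(K1) for k in range(K2) if counts[j, k] > 0]
    for j in range(K1):
        for k in range(K2):
            if counts[j, k] == 0:
                best = min(occ, key=lambda jk: abs(jk[0] - j) + abs(jk[1] - k))
                M[j, k] = M[best[0], best[1]]
    S = np.zeros((K1 + 1, K2 + 1))
    for j in range(1, K1 + 1):
        for k in range(1, K2 + 1):
            S[j, k] = M[:j, :k].sum()
    W = np.zeros((K1, K2))
    for j in range(K1):
        for k in range(K2):
            W[j, k] = (S[j + 1, k + 1] + S[j, k + 1] + S[j + 1, k] + S[j, k]) / 4.0
    # iterated count-weighted row/column centering
    for _ in range(20000):
        delta = 0.0
        for j in range(K1):
            w = counts[j, :].sum()
            mean = (W[j, :] * counts[j, :]).sum() / w if w else W[j, :].mean()
            W[j, :] -= mean
            delta = max(delta, abs(mean))
        for k in range(K2):
            w = counts[:, k].sum()
            mean = (W[:, k] * counts[:, k]).sum() / w if w else W[:, k].mean()
            W[:, k] -= mean
            delta = max(delta, abs(mean))
        if delta < 1e-14:
            break
    return e1, e2, W, counts
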