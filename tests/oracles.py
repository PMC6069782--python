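"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the loess oracle fits
each query point with numpy.polyfit on explicitly enumerated neighbors,
the BH oracle is the textbook step-up procedure, and the MCC oracle is the
formula evaluated directly in floats.
"""

import math

import numpy as np


def loess_oracle(x, y, queries, span, degree):
    """Per-query tricube weighted polynomial fit via numpy.polyfit."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = math.ceil(span * n)
    out = []
    for d in queries:
        dist = np.abs(x - d)
        h = np.sort(dist)[k - 1]
        if h == 0:
            out.append(y[dist == 0].mean())
            continue
        sel = dist <= h
        w = (1 - (dist[sel] / h) ** 3) ** 3
        if w.sum() <= 0:
            nearest = dist[sel] == dist[sel].min()
            out.append(y[sel][nearest].mean())
            continue
        # polyfit weights multiply residuals, so sqrt of the WLS weights
        coeffs = np.polyfit(x[sel] - d, y[sel], degree, w=np.sqrt(w))
        out.append(coeffs[-1])
    return np.array(out)


def bh_oracle(p):
    """Benjamini-Hochberg step-up as an explicit loop: walk the sorted
    p-values from largest to smallest keeping the running minimum of
    p * n / rank; clip at 1; restore the input order."""
    p = list(map(float, p))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj_sorted = [None] * n
    running = float("inf")
    for pos in range(n - 1, -1, -1):
        rank = pos + 1
        running = min(running, p[order[pos]] * n / rank)
        adj_sorted[pos] = min(running, 1.0)
    out = [None] * n
    for pos, i in enumerate(order):
        out[i] = adj_sorted[pos]
    return np.array(out)


def mcc_oracle(tp, fp, tn, fn):
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if den == 0 else num / den
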