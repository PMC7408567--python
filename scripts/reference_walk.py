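"""Naive loop-based reference implementation of single-sample set scoring.

Shares no code with the package's engine; used to cross-check it.
"""

from __future__ import annotations

import math


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def gsva_reference(values, set_indices, bandwidth_factor=0.25, tau=1.0, kernel="gaussian"):
    """Score one gene set for every sample by direct enumeration."""
    values = [list(row) for row in values]
    p = len(values)
    n = len(values[0])
    cdf = [[0.0] * n for _ in range(p)]
    for i in range(p):
        row = values[i]
        mean = sum(row) / n
        var = sum((v - mean) ** 2 for v in row) / (n - 1)
        h = max(math.sqrt(var) * bandwidth_factor, 1e-8)
        for j in range(n):
            if kernel == "gaussian":
                cdf[i][j] = sum(_phi((row[j] - row[k]) / h) for k in range(n)) / n
            else:
                cdf[i][j] = sum(1 for k in range(n) if row[k] <= row[j]) / n
    scores = []
    inset = set(set_indices)
    k = len(inset)
    for j in range(n):
        order = sorted(range(p), key=lambda i: (-cdf[i][j], i))
        denom = sum(
            abs(p / 2.0 - (pos + 1)) ** tau for pos, i in enumerate(order) if i in inset
        )
        pos_cum = neg_cum = 0.0
        max_pos = max_neg = 0.0
        for pos, i in enumerate(order):
            if i in inset:
                pos_cum += (abs(p / 2.0 - (pos + 1)) ** tau) / denom if denom else 0.0
            else:
                neg_cum += 1.0 / (p - k)
            dev = pos_cum - neg_cum
            max_pos = max(max_pos, dev)
            max_neg = max(max_neg, -dev)
        scores.append(max_pos - max_neg)
    return scores
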