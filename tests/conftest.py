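"""Shared fixtures and the independent brute-force scoring oracle.

``gsva_reference`` is a deliberately naive, loop-based reimplementation of
the whole scoring pipeline (kernel CDF -> ranks -> walk) written without any
code shared with the engine, so engine/oracle agreement is a meaningful
cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from glycoscape.io_formats import ExpressionMatrix
from glycoscape.simulate import SimConfig, simulate_cohort


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def gsva_reference(values, set_indices, bandwidth_factor=0.25, tau=1.0, kernel="gaussian"):
    """Monolithic double-loop scoring of one gene set; returns per-sample scores."""
    values = [list(row) for row in values]
    p = len(values)
    n = len(values[0])
    # step 1: kernel CDF
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
        # step 2: decreasing-CDF ranks, ties by input gene order
        order = sorted(range(p), key=lambda i: (-cdf[i][j], i))
        # step 3: weighted walk over the ranked list
        denom = sum(abs(p / 2.0 - (pos + 1)) ** tau for pos, i in enumerate(order) if i in inset)
        pos_cum = 0.0
        neg_cum = 0.0
        max_pos = 0.0
        max_neg = 0.0
        for pos, i in enumerate(order):
            r = abs(p / 2.0 - (pos + 1)) ** tau
            if i in inset:
                pos_cum += r / denom if denom else 0.0
            else:
                neg_cum += 1.0 / (p - k)
            dev = pos_cum - neg_cum
            max_pos = max(max_pos, dev)
            max_neg = max(max_neg, -dev)
        scores.append(max_pos - max_neg)
    return scores


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_expr(rng):
    vals = np.random.default_rng(7).normal(5.0, 1.0, size=(12, 8))
    return ExpressionMatrix(
        [f"G{i}" for i in range(12)], [f"S{j}" for j in range(8)], vals
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One small 2-type cohort with planted drivers, reused across tests."""
    cfg = SimConfig(seed=11, n_cancer_types=2, n_tumor=150, n_normal=40, n_genes=120)
    return simulate_cohort(cfg)
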