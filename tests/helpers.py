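"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops straight from the defining
sums, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def icc_oracle(x: np.ndarray, form: str) -> float:
    """ICC of one (I, 2) feature from the explicit ANOVA sums, loop by loop."""
    n, k = x.shape
    m = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    si = [sum(x[i]) / k for i in range(n)]
    mj = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    bms = k * sum((s - m) ** 2 for s in si) / (n - 1)
    jms = n * sum((mu - m) ** 2 for mu in mj) / (k - 1)
    ems = sum(
        (x[i][j] - si[i] - mj[j] + m) ** 2 for i in range(n) for j in range(k)
    ) / ((n - 1) * (k - 1))
    wms = sum((x[i][j] - si[i]) ** 2 for i in range(n) for j in range(k)) / (
        n * (k - 1)
    )
    if form == "ICC(1,1)":
        return (bms - wms) / (bms + (k - 1) * wms)
    if form == "ICC(3,1)":
        return (bms - ems) / (bms + (k - 1) * ems)
    if form == "ICC(2,1)":
        return (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n)
    raise ValueError(form)


def i2c2_oracle(x: np.ndarray, demean: bool = True) -> float:
    """Trace-ratio I2C2 of an (I, 2, p) array via explicit loops."""
    n, _, p = x.shape
    w = x.astype(float).copy()
    if demean:
        for j in range(2):
            mu = sum(w[i, j] for i in range(n)) / n
            for i in range(n):
                w[i, j] = w[i, j] - mu
    trkw = sum(
        float(np.dot(w[i, 0] - w[i, 1], w[i, 0] - w[i, 1])) for i in range(n)
    ) / (2 * n)
    gbar = sum(w[i, j] for i in range(n) for j in range(2)) / (2 * n)
    trktot = sum(
        float(np.dot(w[i, j] - gbar, w[i, j] - gbar))
        for i in range(n)
        for j in range(2)
    ) / (2 * n - 1)
    return 1.0 - trkw / trktot


def signed_rank_exact_p(diff: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n signs."""
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        s = np.array(signs, dtype=bool)
        w = min(ranks[s].sum(), ranks[~s].sum())
        if w <= w_obs:
            count += 1
    return min(1.0, count / 2.0**n)


def bh_oracle(p: list[float]) -> list[float]:
    """Step-up BH adjusted values by the textbook recursion."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def dice_oracle(a: np.ndarray, b: np.ndarray, label: int) -> float:
    """Dice for one label by direct voxel counting."""
    in_a = a == label
    in_b = b == label
    return 2.0 * np.sum(in_a & in_b) / (np.sum(in_a) + np.sum(in_b))
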