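"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: dictionary
n-gram counting, linear bin scans, and label-permutation tests.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def ngram_transition_counts(symbols: str, W: int) -> Counter:
    """Count (pattern, next-symbol) pairs by explicit window enumeration."""
    counts: Counter = Counter()
    for i in range(len(symbols) - W + 1):
        window = symbols[i : i + W]
        counts[(window[:-1], window[-1])] += 1
    return counts


def bin_scan(value: float, thresholds) -> int:
    """Assign a bin index by linear scan with T_0 = 0 and T_V = +inf."""
    bounds = [0.0, *thresholds, float("inf")]
    for i in range(len(bounds) - 1):
        if bounds[i] <= value < bounds[i + 1]:
            return i
    raise AssertionError("unreachable for positive finite values")


def enumerate_thresholds(mean: float, V: int, t: float) -> list[float]:
    """Evaluate the ±t·(1+k) threshold construction by direct enumeration."""
    values = set()
    for k in range((V - 1) // 2):
        values.add(mean * (1.0 - t - t * k))
        values.add(mean * (1.0 + t + t * k))
    return sorted(values)


def ranksum_permutation_pvalue(a, b, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for the rank-sum statistic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0  # midranks not needed for continuous data
    na = a.size
    observed = abs(ranks[:na].sum() - na * (pooled.size + 1) / 2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        stat = abs(perm[:na].sum() - na * (pooled.size + 1) / 2)
        if stat >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
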