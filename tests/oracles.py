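"""Independent brute-force oracles and small construction helpers for tests.

These deliberately avoid the package's own code paths (and sklearn's metric
routines) so that metric tests compare two independent derivations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from nanorf.dependence import DependenceProfile


def auc_pairwise(scores, labels) -> float:
    """AUC by direct Mann-Whitney pair counting, ties worth 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def mcc_by_enumeration(scores, labels, t: float) -> float:
    """MCC of the rule score > t via explicit confusion counting."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    tp = fp = tn = fn = 0
    for si, yi in zip(s, y):
        if si > t:
            if yi == 1:
                tp += 1
            else:
                fp += 1
        else:
            if yi == 1:
                fn += 1
            else:
                tn += 1
    return mcc_from_counts(tp, fp, tn, fn)


def best_threshold_exhaustive(scores, labels) -> tuple[float, float]:
    """Sweep the same midpoint+sentinel grid by brute force."""
    s = np.asarray(scores, float)
    uniq = np.unique(s)
    grid = {0.0, 1.0}
    for a, b in zip(uniq[:-1], uniq[1:]):
        grid.add((a + b) / 2.0)
    best_t, best_m = None, -np.inf
    for t in sorted(grid):
        m = mcc_by_enumeration(s, labels, t)
        if m > best_m:
            best_t, best_m = t, m
    return best_t, best_m


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg by the textbook step-up recipe."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        i = order[rank_from_top]
        val = p[i] * n / (rank_from_top + 1)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def geometric_mean(values) -> float:
    v = np.asarray(values, float)
    return float(np.exp(np.mean(np.log(v))))


def profile_from_values(values: pd.DataFrame) -> DependenceProfile:
    """Wrap a raw proteins x conditions log2 matrix as a DependenceProfile."""
    counts = values.notna().astype(int)
    proteins = pd.DataFrame(
        {"gene_name": "", "is_reverse": False, "is_contaminant": False},
        index=values.index,
    )
    return DependenceProfile(proteins, values, counts)
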