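"""Independent brute-force oracles used by multiple test modules."""

import numpy as np


def _rank_with_ties(values):
    """Average ranks, computed by explicit enumeration."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = np.asarray(values)[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def brute_force_kruskal_h(groups):
    """H statistic from first principles: rank sums + tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = _rank_with_ties(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / correction
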