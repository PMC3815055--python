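"""Brute-force reference implementations used by the test suite.

Deliberately naive (nested loops, exhaustive pairwise enumeration) and
independent of the package's vectorized/numba code paths.
"""

import numpy as np


def oracle_disagreements(calls, i, j, window):
    """Opposing-homozygote count between lines i and j over window indices."""
    return sum(1 for w in window
               if calls[i, w] != -1 and calls[j, w] != -1
               and calls[i, w] != calls[j, w])


def oracle_partition(calls, marker, flank, max_dis):
    """Greedy seed-and-extend complete-linkage clustering in line order."""
    m = calls.shape[1]
    window = [w for w in range(max(0, marker - flank),
                               min(m, marker + flank + 1)) if w != marker]
    clusters = []
    for i in range(calls.shape[0]):
        for c in clusters:
            if all(oracle_disagreements(calls, i, j, window) <= max_dis
                   for j in c):
                c.append(i)
                break
        else:
            clusters.append([i])
    labels = np.empty(calls.shape[0], int)
    for k, c in enumerate(clusters):
        labels[c] = k
    return labels


def oracle_impute_column(calls, marker, labels):
    """Majority-consensus imputation of the focal column; ties stay missing."""
    col = calls[:, marker].copy()
    for k in np.unique(labels):
        members = np.flatnonzero(labels == k)
        vals = [calls[i, marker] for i in members if calls[i, marker] != -1]
        if not vals:
            continue
        n0, n2 = vals.count(0), vals.count(2)
        if n0 == n2:
            continue
        consensus = 0 if n0 > n2 else 2
        for i in members:
            if calls[i, marker] == -1:
                col[i] = consensus
    return col
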