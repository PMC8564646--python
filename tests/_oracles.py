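"""Independent brute-force oracles used to check the survival statistics.

Everything here is deliberately written from first principles (plain sums
and enumerations) and shares no code with the package implementation.
"""

from itertools import combinations

import numpy as np


def mantel_cox_statistic(times, events, labels) -> float:
    """Two-group log-rank chi-square from the defining O-E / V sums."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels, dtype=int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (labels == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (labels == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def permutation_logrank_p(times, events, labels, n_perm: int, rng) -> float:
    """Tail probability of the log-rank statistic under label permutation."""
    observed = mantel_cox_statistic(times, events, labels)
    labels = np.asarray(labels)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if mantel_cox_statistic(times, events, perm) >= observed - 1e-12:
            hits += 1
    return hits / n_perm


def mwu_enumeration_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all label splits."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(a)

    def u_of(sample_a, sample_b):
        return sum(x > y for x in sample_a for y in sample_b)

    center = n1 * len(b) / 2
    observed_dev = abs(u_of(a, b) - center)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_of(aa, bb) - center) >= observed_dev - 1e-12:
            hits += 1
    return hits / total
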