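"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — direct definitions, exhaustive
enumeration — and shares no code with the package.
"""

import math


def ecdf(sample, x):
    return sum(v <= x for v in sample) / len(sample)


def ks2_brute(a, b):
    """Sup of |ECDF_a - ECDF_b| evaluated at every pooled sample point."""
    return max(abs(ecdf(a, x) - ecdf(b, x)) for x in list(a) + list(b))


def match_brute(stake_times, payout_times):
    """Earliest-first maximum assignment of payouts to prior stakes.

    Enumerates every injective assignment (payouts processed in time order,
    each taking any unmatched stake placed at or before it, or none), then
    picks the maximum-cardinality assignment that is lexicographically
    earliest in stake indices.  Returns a tuple with one entry per payout:
    the stake index or None.
    """
    best = None

    def rec(j, used, assign):
        nonlocal best
        if j == len(payout_times):
            key = (
                -sum(a is not None for a in assign),
                tuple(math.inf if a is None else a for a in assign),
            )
            if best is None or key < best[0]:
                best = (key, tuple(assign))
            return
        for i in range(len(stake_times)):
            if i not in used and stake_times[i] <= payout_times[j]:
                rec(j + 1, used | {i}, assign + [i])
        rec(j + 1, used, assign + [None])

    rec(0, frozenset(), [])
    return best[1]


def midranks(x):
    """Average ranks (1-based), ties sharing their midrank."""
    n = len(x)
    ranks = [0.0] * n
    order = sorted(range(n), key=lambda i: x[i])
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[order[j + 1]] == x[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def spearman_brute(x, y):
    """Pearson correlation of midranks, computed from the definition."""
    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)
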