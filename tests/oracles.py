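"""Independent brute-force reference implementations.

Deliberately naive (python loops, textbook formulas) and kept free of any
fmt_engraft import so they can serve as oracles for the package's metric
and statistics code.
"""

from __future__ import annotations

import math

import scipy.stats  # only for the t / chi2 distribution functions


def average_ranks(values) -> list[float]:
    """Midrank assignment (ties share the average of their rank span)."""
    n = len(values)
    ranks = [0.0] * n
    for i, v in enumerate(values):
        less = sum(1 for w in values if w < v)
        ties = sum(1 for w in values if w == v)
        ranks[i] = less + (ties + 1) / 2.0
    return ranks


def shannon_oracle(p) -> float:
    total = sum(p)
    h = 0.0
    for x in p:
        if x > 0:
            q = x / total
            h -= q * math.log(q)
    return h


def bray_curtis_oracle(a, b) -> float:
    num = sum(abs(x - y) for x, y in zip(a, b))
    den = sum(x + y for x, y in zip(a, b))
    return num / den


def cosine_oracle(a, b) -> float:
    dot = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    return dot / (na * nb)


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def spearman_oracle(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho (Pearson on midranks) and t-approx p."""
    rx = average_ranks(list(x))
    ry = average_ranks(list(y))
    rho = pearson_oracle(rx, ry)
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 2)
    return rho, p


def kruskal_oracle(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p (k-1 df)."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = average_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r_sum = sum(ranks[start : start + len(g)])
        h += r_sum**2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    counts: dict[float, int] = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    correction = 1.0 - sum(t**3 - t for t in counts.values()) / (n**3 - n)
    h = h / correction
    p = scipy.stats.chi2.sf(h, df=len(groups) - 1)
    return h, p


def bh_oracle(p_values) -> list[float]:
    """Benjamini–Hochberg step-up with cumulative-min monotonisation."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [p_values[order[i]] * m / (i + 1) for i in range(m)]
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, q_sorted[i])
        q_sorted[i] = min(running, 1.0)
    q = [0.0] * m
    for rank, idx in enumerate(order):
        q[idx] = q_sorted[rank]
    return q
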