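"""Independent brute-force oracles used to cross-check the statistics.

These deliberately avoid the code paths (and where possible the libraries)
used by the package implementation: textbook formulas, naive loops, and
exact combinatorial enumeration.
"""

import math

from scipy.special import stdtr


def welch_t_oracle(a, b):
    """Textbook Welch t with Welch-Satterthwaite df; p from the t CDF."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * (1.0 - stdtr(df, abs(t)))
    return t, p


def bh_oracle(p_values):
    """BH step-up by the definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(indexed):
        best = min(
            p_values[indexed[j]] * m / (j + 1) for j in range(rank_pos, m)
        )
        q[i] = min(best, 1.0)
    return q


def hypergeom_tail_oracle(x, N, K, n):
    """P(X >= x) for X ~ Hypergeom(N, K, n) by exact enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k)
        for k in range(x, min(K, n) + 1)
        if n - k <= N - K
    ) / total


def all_partitions(items):
    """Every set partition of ``items`` (for brute-force modularity)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part
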