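"""Independent, deliberately naive reference implementations.

These oracles stay structurally distinct from the package code (explicit
loops, sorting-based medians, full enumerations) so that agreement is
evidence rather than tautology.
"""

from itertools import combinations
from math import comb, sqrt


def median_by_sort(xs):
    s = sorted(xs)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def modz_oracle(values, trim_k=2.0, scale_c=0.6745, saturation=10.0):
    """Literal step-by-step MAD-trimmed modified Z-score."""
    m = median_by_sort(values)
    mad = median_by_sort([abs(v - m) for v in values])
    trimmed = [v for v in values if abs(v - m) <= trim_k * mad]
    m_star = median_by_sort(trimmed)
    mad_star = median_by_sort([abs(v - m_star) for v in trimmed])
    if mad_star == 0:
        mad_star = 1.4826 * sum(abs(v - m_star) for v in trimmed) / len(trimmed)
    out = []
    for v in values:
        z = 0.0 if mad_star == 0 else scale_c * (v - m_star) / mad_star
        out.append(max(-saturation, min(saturation, z)))
    return out


def ols_slope_oracle(times, values):
    """Slope from the explicit normal equations."""
    n = len(times)
    sx = sum(times)
    sy = sum(values)
    sxx = sum(t * t for t in times)
    sxy = sum(t * v for t, v in zip(times, values))
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums P(k) over all tables with the observed margins whose probability
    does not exceed the observed table's (with a small relative slack for
    float ties, matching the conventional definition).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = prob(a)
    total = 0.0
    for k in range(0, c1 + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


def mannwhitney_permutation_oracle(x, y, rng, n_perm=2000):
    """Two-sided permutation p-value for the rank-sum statistic."""
    pooled = list(x) + list(y)
    nx = len(x)

    def ranksum(sample_idx):
        order = sorted(range(len(pooled)), key=lambda i: pooled[i])
        ranks = [0.0] * len(pooled)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return sum(ranks[i] for i in sample_idx)

    expected = nx * (len(pooled) + 1) / 2.0
    obs = abs(ranksum(range(nx)) - expected)
    hits = 0
    idx = list(range(len(pooled)))
    for _ in range(n_perm):
        perm = list(rng.permutation(idx))
        if abs(ranksum(perm[:nx]) - expected) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def quadrat_counts(x, y, width, height, quadrat):
    """Brute-force quadrat counting by nested loops over cells."""
    import math

    nx = math.ceil(width / quadrat)
    ny = math.ceil(height / quadrat)
    counts = []
    for j in range(ny):
        for i in range(nx):
            c = 0
            for px, py in zip(x, y):
                if (
                    i * quadrat <= px < (i + 1) * quadrat
                    and j * quadrat <= py < (j + 1) * quadrat
                ):
                    c += 1
            counts.append(c)
    return counts


def ward_linkage_oracle(points):
    """Naive agglomerative Ward clustering by enumerating merges.

    Clusters are merged greedily by minimum increase of within-cluster sum
    of squares; returns the merge heights in order (scipy convention:
    sqrt(2 * delta-ESS)).
    """

    def ess(cluster):
        dims = len(points[0])
        cent = [
            sum(points[i][d] for i in cluster) / len(cluster) for d in range(dims)
        ]
        return sum(
            sum((points[i][d] - cent[d]) ** 2 for d in range(dims)) for i in cluster
        )

    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            delta = ess(clusters[a] + clusters[b]) - ess(clusters[a]) - ess(clusters[b])
            if best is None or delta < best[0]:
                best = (delta, a, b)
        delta, a, b = best
        heights.append(sqrt(2.0 * delta))
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return heights
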