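"""Independent brute-force oracles used to check the package implementations.

Everything here is coded from first principles (plain recursion and
enumeration, no dynamic programming, no shared helpers with the package)
so that agreement with the package is a meaningful cross-check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, inf, log, exp

LEGAL = {"AU", "UA", "GC", "CG", "GU", "UG"}
WEIGHTS = {"GC": 3, "CG": 3, "AU": 2, "UA": 2, "GU": 1, "UG": 1}


def all_nested_structures(seq: str, min_hairpin: int = 3):
    """Every legal nested structure of ``seq`` as a list of pair tables."""
    n = len(seq)

    def rec(i, j):
        # structures of the closed interval [i, j] as lists of (a, b) pairs
        if i >= j:
            return [[]]
        out = []
        for rest in rec(i + 1, j):
            out.append(rest)
        for k in range(i + min_hairpin + 1, j + 1):
            if seq[i - 1] + seq[k - 1] not in LEGAL:
                continue
            for left in rec(i + 1, k - 1):
                for right in rec(k + 1, j):
                    out.append([(i, k)] + left + right)
        return out

    tables = []
    for pl in rec(1, n):
        pairs = [0] * (n + 1)
        for a, b in pl:
            pairs[a], pairs[b] = b, a
        tables.append(tuple(pairs))
    return tables


def structure_weight(seq: str, pairs) -> int:
    total = 0
    for i in range(1, len(seq) + 1):
        j = pairs[i]
        if j > i:
            total += WEIGHTS[seq[i - 1] + seq[j - 1]]
    return total


def max_weight_brute(seq: str, min_hairpin: int = 3, forbidden=None) -> int:
    """Maximum structure weight by exhaustive enumeration."""
    best = 0
    for pairs in all_nested_structures(seq, min_hairpin):
        if forbidden is not None:
            lo, hi = forbidden
            if any(pairs[p] != 0 for p in range(lo, hi + 1)):
                continue
        best = max(best, structure_weight(seq, pairs))
    return best


def oracle_annotate(seq: str, pairs):
    """Independent recursive loop-walk classification (1-based labels)."""
    n = len(seq)
    plist = [(i, pairs[i]) for i in range(1, n + 1) if pairs[i] > i]
    labels = [None] * (n + 1)
    for i in range(1, n + 1):
        if pairs[i]:
            labels[i] = "STEM"

    for a, b in plist:
        kids = []
        for c, d in plist:
            if not (a < c and d < b):
                continue
            if any(a < e < c and d < f < b for (e, f) in plist):
                continue
            kids.append((c, d))
        kids.sort()
        interior = [
            p
            for p in range(a + 1, b)
            if pairs[p] == 0 and not any(c < p < d for (c, d) in kids)
        ]
        if not interior:
            continue
        if len(kids) == 0:
            lab = "H_LOOP"
        elif len(kids) >= 2:
            lab = "MB_LOOP"
        else:
            (c, d) = kids[0]
            left = sum(1 for p in interior if p < c)
            right = sum(1 for p in interior if p > d)
            if left > 0 and right > 0:
                lab = "INT_LOOP"
            elif left + right == 1:
                lab = "ONE_BB"
            else:
                lab = "B_LOOP"
        for p in interior:
            labels[p] = lab

    top = sorted(
        (a, b)
        for (a, b) in plist
        if not any(e < a and b < f for (e, f) in plist)
    )
    exterior = [
        p
        for p in range(1, n + 1)
        if pairs[p] == 0 and not any(a < p < b for (a, b) in top)
    ]
    if not top:
        for p in exterior:
            labels[p] = "LOOP_5P"
    else:
        first_a, last_b = top[0][0], top[-1][1]
        for p in exterior:
            if p < first_a:
                labels[p] = "LOOP_5P"
            elif p > last_b:
                labels[p] = "LOOP_3P"
        for (a1, b1), (a2, b2) in zip(top, top[1:]):
            seg = [p for p in range(b1 + 1, a2)]
            m = len(seg)
            for p in seg[: m // 2]:
                labels[p] = "LOOP_3P"
            for p in seg[m // 2 :]:
                labels[p] = "LOOP_5P"
    return labels


def mann_whitney_u_brute(a, b) -> float:
    """U statistic for sample ``a``: pairwise wins plus half ties."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def fisher_p_enum(table) -> float:
    """Two-sided Fisher p by full enumeration at fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


def logistic_loglik(y, x, b0, b1) -> float:
    total = 0.0
    for yi, xi in zip(y, x):
        eta = b0 + b1 * xi
        # log(1 + e^eta), stable
        if eta > 30:
            lse = eta
        elif eta < -30:
            lse = 0.0
        else:
            lse = log(1.0 + exp(eta))
        total += yi * eta - lse
    return total


def logistic_grid_mle(y, x, span=6.0, stages=5, grid=61):
    """Two-parameter maximum likelihood by iteratively refined grid search."""
    c0, c1 = 0.0, 0.0
    width = span
    for _ in range(stages):
        best = (-inf, c0, c1)
        for i in range(grid):
            b0 = c0 - width + 2 * width * i / (grid - 1)
            for j in range(grid):
                b1 = c1 - width + 2 * width * j / (grid - 1)
                ll = logistic_loglik(y, x, b0, b1)
                if ll > best[0]:
                    best = (ll, b0, b1)
        _, c0, c1 = best
        width = 4 * width / (grid - 1)
    return c0, c1
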