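"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (full-matrix
scans, exhaustive path enumeration) and share no code with the package
implementations they check.
"""
from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# RQA: full-matrix line-scan


def rqa_brute_force(labels: list[str], L: int = 2) -> dict:
    """REC/DET/LAM/CORM by direct enumeration over the full N x N matrix."""
    n = len(labels)
    keyed = [f"#out{i}" if lab == "outside" else lab for i, lab in enumerate(labels)]
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and keyed[i] == keyed[j]:
                m[i, j] = 1
    R = sum(m[i, j] for i in range(n) for j in range(i + 1, n))
    rec = 100.0 * 2 * R / (n * (n - 1))
    if R == 0:
        return {"recurrence": rec, "determinism": math.nan,
                "laminarity": math.nan, "corm": math.nan, "R": 0, "n": n}

    def on_line(i, j, di, dj):
        """Length of the maximal run of 1s through (i, j) stepping (di, dj)."""
        length = 1
        a, b = i - di, j - dj
        while 0 <= a < n and 0 <= b < n and m[a, b]:
            length += 1
            a, b = a - di, b - dj
        a, b = i + di, j + dj
        while 0 <= a < n and 0 <= b < n and m[a, b]:
            length += 1
            a, b = a + di, b + dj
        return length

    diag = horiz = vert = 0
    for i in range(n):
        for j in range(i + 1, n):
            if not m[i, j]:
                continue
            if on_line(i, j, 1, 1) >= L:
                diag += 1
            if on_line(i, j, 0, 1) >= L:
                horiz += 1
            if on_line(i, j, 1, 0) >= L:
                vert += 1
    det = 100.0 * diag / R
    lam = 100.0 * (horiz + vert) / (2 * R)
    corm = 100.0 * sum((j - i) * m[i, j] for i in range(n)
                       for j in range(i + 1, n)) / ((n - 1) * R)
    return {"recurrence": rec, "determinism": det, "laminarity": lam,
            "corm": corm, "R": R, "n": n}


# ---------------------------------------------------------------------------
# MultiMatch alignment: exhaustive enumeration of monotone paths


def min_alignment_cost_exhaustive(M: np.ndarray) -> float:
    """Minimum total cost over all right/down/diagonal paths, by recursion."""
    n, m = M.shape

    memo = {}

    def best(i, j):
        if (i, j) in memo:
            return memo[(i, j)]
        if i == 0 and j == 0:
            v = M[0, 0]
        else:
            cands = []
            if i > 0:
                cands.append(best(i - 1, j))
            if j > 0:
                cands.append(best(i, j - 1))
            if i > 0 and j > 0:
                cands.append(best(i - 1, j - 1))
            v = M[i, j] + min(cands)
        memo[(i, j)] = v
        return v

    return float(best(n - 1, m - 1))


def enumerate_paths_cost(M: np.ndarray) -> float:
    """Truly exhaustive (non-DP) enumeration for tiny matrices."""
    n, m = M.shape
    best = [math.inf]

    def walk(i, j, cost):
        cost += M[i, j]
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return float(best[0])


# ---------------------------------------------------------------------------
# One-way ANOVA closed form from group summaries


def anova_from_groups(groups: dict[str, np.ndarray]) -> tuple[float, int, int]:
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    k = len(groups)
    N = len(allv)
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    F = (ssb / (k - 1)) / (ssw / (N - k))
    return F, k - 1, N - k


# ---------------------------------------------------------------------------
# Studentized-range upper tail by direct numerical quadrature


def studentized_range_sf_quadrature(q: float, k: int, df: int) -> float:
    """P(Q > q) for the studentized range, by nested quadrature.

    Uses only the defining double integral (range CDF of k standard
    normals, mixed over the scale distribution sqrt(chi2_df / df)).
    """
    from scipy import integrate
    from scipy.stats import chi2, norm

    def p_range_below(r):
        # CDF of the range of k iid standard normals
        f = lambda z: k * norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - r)) ** (k - 1)
        val, _ = integrate.quad(f, -8.5, 8.5, limit=200)
        return val

    def integrand(u):
        # u = chi2_df variate; scale s = sqrt(u / df)
        s = math.sqrt(u / df)
        return p_range_below(q * s) * chi2.pdf(u, df)

    cdf, _ = integrate.quad(integrand, 1e-9, chi2.ppf(1 - 1e-10, df), limit=200)
    return max(0.0, 1.0 - cdf)
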