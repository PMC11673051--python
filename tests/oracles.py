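"""Independent brute-force / closed-form oracles used by the tests.

Everything here is written as plain scalar loops from the textbook
definitions, deliberately sharing no code with the package, so agreement
is a genuine cross-check.
"""
from __future__ import annotations

import math

import numpy as np

MISS = -1


def pi_site(column: list[int]) -> float:
    """Mean pairwise difference at one site by explicit pair enumeration."""
    called = [a for a in column if a != MISS]
    n = len(called)
    if n < 2:
        return float("nan")
    diff = pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            diff += called[i] != called[j]
    return diff / pairs


def window_pi(alleles: np.ndarray, positions: np.ndarray, start: int, end: int, size: int) -> float:
    """Sum of per-site pi over sites in [start, end) divided by window size."""
    tot = 0.0
    for j, pos in enumerate(positions):
        if start <= pos < end:
            v = pi_site(list(alleles[:, j]))
            if not math.isnan(v):
                tot += v
    return tot / size


def tajimas_d(alleles: np.ndarray) -> float:
    """Tajima's D over a haplotype block, from the 1989 definitions."""
    n, m = alleles.shape
    S = 0
    pi_sum = 0.0
    for j in range(m):
        col = list(alleles[:, j])
        c1 = sum(col)
        if 0 < c1 < n:
            S += 1
            pi_sum += pi_site(col)
    if S == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1_ = b1 - 1.0 / a1
    c2_ = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1_ / a1
    e2 = c2_ / (a1 * a1 + a2)
    return (pi_sum - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def wc_fst(genotypesA: np.ndarray, genotypesB: np.ndarray) -> float:
    """Weighted Weir & Cockerham (1984) F_ST for two diploid samples.

    ``genotypes*`` are (n_samples, n_sites) dosage matrices (0/1/2, -1
    missing).  Scalar per-site implementation of the published a, b, c.
    """
    num = den = 0.0
    r = 2
    for j in range(genotypesA.shape[1]):
        stats = []
        for G in (genotypesA, genotypesB):
            col = [g for g in G[:, j] if g != MISS]
            if not col:
                stats = None
                break
            ni = len(col)
            pi = sum(col) / (2.0 * ni)
            hi = sum(1 for g in col if g == 1) / ni
            stats.append((ni, pi, hi))
        if stats is None:
            continue
        n_bar = sum(s[0] for s in stats) / r
        if n_bar <= 1:
            continue
        p_bar = sum(s[0] * s[1] for s in stats) / (r * n_bar)
        s2 = sum(s[0] * (s[1] - p_bar) ** 2 for s in stats) / ((r - 1) * n_bar)
        h_bar = sum(s[0] * s[2] for s in stats) / (r * n_bar)
        if (p_bar <= 0 or p_bar >= 1) and h_bar == 0:
            continue
        nc = (r * n_bar - sum(s[0] ** 2 for s in stats) / (r * n_bar)) / (r - 1)
        a = (n_bar / nc) * (
            s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
        num += a
        den += a + b + c
    return num / den


def hudson_fst(hapA: np.ndarray, hapB: np.ndarray) -> float:
    """Hudson (1992) F_ST estimator from haplotype frequencies (no missing)."""
    num = den = 0.0
    nA, nB = hapA.shape[0], hapB.shape[0]
    for j in range(hapA.shape[1]):
        p1 = hapA[:, j].mean()
        p2 = hapB[:, j].mean()
        n = (p1 - p2) ** 2 - p1 * (1 - p1) / (nA - 1) - p2 * (1 - p2) / (nB - 1)
        d = p1 * (1 - p2) + p2 * (1 - p1)
        num += n
        den += d
    return num / den


def p_distance(row_i: list[int], row_j: list[int]) -> float:
    diff = comp = 0
    for a, b in zip(row_i, row_j):
        if a != MISS and b != MISS:
            comp += 1
            diff += a != b
    return diff / comp if comp else float("nan")


def u_count(pc: list[float], pt: list[float], pdn: list[float], w: float, x: float, y: float) -> int:
    """Site-by-site U-statistic count."""
    c = 0
    for a, b, d in zip(pc, pt, pdn):
        if math.isnan(a) or math.isnan(b) or math.isnan(d):
            continue
        if d >= y and a < w and b > x:
            c += 1
    return c


def ld_prune_survivors(
    dosages: np.ndarray, snp_window: int, snp_step: int, r2: float
) -> list[int]:
    """Greedy PLINK-style pruning by explicit pair loops; returns kept indices."""

    def corr2(x, y):
        ok = [k for k in range(len(x)) if not (math.isnan(x[k]) or math.isnan(y[k]))]
        if len(ok) < 2:
            return 0.0
        xs = [x[k] for k in ok]
        ys = [y[k] for k in ok]
        mx = sum(xs) / len(xs)
        my = sum(ys) / len(ys)
        sx = math.sqrt(sum((v - mx) ** 2 for v in xs) / len(xs))
        sy = math.sqrt(sum((v - my) ** 2 for v in ys) / len(ys))
        if sx == 0 or sy == 0:
            return 0.0
        r = sum((a - mx) * (b - my) for a, b in zip(xs, ys)) / (len(xs) * sx * sy)
        return r * r

    keep = list(range(dosages.shape[1]))
    changed = True
    while changed:
        changed = False
        removed = set()
        start = 0
        while start < len(keep):
            window = keep[start : start + snp_window]
            for ii in range(len(window)):
                if window[ii] in removed:
                    continue
                for jj in range(ii + 1, len(window)):
                    if window[jj] in removed:
                        continue
                    if corr2(list(dosages[:, window[ii]]), list(dosages[:, window[jj]])) > r2:
                        removed.add(window[jj])
                        changed = True
            start += snp_step
        keep = [k for k in keep if k not in removed]
    return keep


def ils_survival(m: float, r: float, t: float) -> float:
    """Gamma(shape 2, rate r*t) survival via the incomplete-gamma series."""
    lam = r * t
    return math.exp(-lam * m) * (1 + lam * m)
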