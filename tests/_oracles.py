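"""Independent brute-force oracles used by the test suite.

Each oracle is written directly from the defining formula with explicit
loops, deliberately sharing no code with the package implementation.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.stats import nbinom, binom


def average_ranks(values):
    """1-based average ranks computed by counting (tie-aware)."""
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def tmm_brute(obs, ref, m_trim=0.30, a_trim=0.05, lib_obs=None, lib_ref=None):
    """Loop-based trimmed-mean-of-M-values factor."""
    obs = [float(x) for x in obs]
    ref = [float(x) for x in ref]
    N_o = sum(obs) if lib_obs is None else float(lib_obs)
    N_r = sum(ref) if lib_ref is None else float(lib_ref)
    pairs = [(o, r) for o, r in zip(obs, ref) if o > 0 and r > 0]
    n = len(pairs)
    if n == 0:
        return 1.0
    M = [math.log2((o / N_o) / (r / N_r)) for o, r in pairs]
    A = [0.5 * math.log2((o / N_o) * (r / N_r)) for o, r in pairs]
    rM = average_ranks(M)
    rA = average_ranks(A)
    lo_m = math.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    num = den = 0.0
    kept = 0
    for i, (o, r) in enumerate(pairs):
        if lo_m <= rM[i] <= hi_m and lo_a <= rA[i] <= hi_a:
            w = 1.0 / ((N_o - o) / (N_o * o) + (N_r - r) / (N_r * r))
            num += w * M[i]
            den += w
            kept += 1
    if kept < 10 or den == 0:
        return 1.0
    return 2.0 ** (num / den)


def bh_brute(p):
    """Step-up BH computed by the textbook recursion on the sorted vector."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q_sorted[rank - 1] = min(val, 1.0)
        prev = q_sorted[rank - 1]
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out


def exact_test_enum(y1, y2, n1, n2, phi):
    """Full conditional enumeration of the NB (or Poisson) exact test."""
    t = y1 + y2
    if t == 0:
        return 1.0
    masses = []
    for y in range(t + 1):
        if phi == 0.0:
            m = binom.pmf(y, t, n1 / (n1 + n2))
        else:
            mu = t / (n1 + n2)
            r1, m1 = n1 / phi, n1 * mu
            r2, m2 = n2 / phi, n2 * mu
            m = (nbinom.pmf(y, r1, r1 / (r1 + m1))
                 * nbinom.pmf(t - y, r2, r2 / (r2 + m2)))
        masses.append(m)
    Z = sum(masses)
    obs = masses[y1]
    p = sum(m for m in masses if m <= obs * (1.0 + 1e-9)) / Z
    return min(p, 1.0)


def hypergeom_enum(N, K, n, k):
    """P(X >= k) by exact enumeration with integer binomials."""
    denom = math.comb(N, n)
    num = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            num += math.comb(K, j) * math.comb(N - K, n - j)
    return num / denom


def truncate_walk(exons, strand, L):
    """Per-base 3'->5' walk oracle for 3'-truncation.

    *exons*: genomic (start, end) 0-based half-open, sorted by start.
    Returns the genomic interval set of the 3'-most min(L, length) bases.
    """
    bases = []
    for s, e in exons:
        bases.extend(range(s, e))
    # order bases 3' -> 5'
    bases = bases[::-1] if strand == "+" else bases
    chosen = sorted(bases[:L])
    out = []
    for b in chosen:
        if out and out[-1][1] == b:
            out[-1] = (out[-1][0], b + 1)
        else:
            out.append((b, b + 1))
    return [tuple(iv) for iv in out]
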