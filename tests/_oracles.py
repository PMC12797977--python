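"""Independent brute-force oracles used by both module and acceptance tests.

Each function is a deliberately plain, loop-level transcription of the
mathematical definition it checks, sharing no code path with the package.
"""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import rankdata


def bh_oracle(p):
    """Quadratic brute-force step-up: q_(i) = min_{j >= i} p_(j) m / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        best = 1.0
        for rank_j in range(rank_i, m + 1):
            best = min(best, p[order[rank_j - 1]] * m / rank_j)
        q[idx] = best
    return q


def pooled_median_p_oracle(data, n1):
    """Exhaustive enumeration of every label split, pooled across genes.

    Returns (observed median differences, add-one-smoothed p-values, the raw
    pooled null).
    """
    total = data.shape[1]
    null = []
    for rows in data:
        for pick in itertools.combinations(range(total), n1):
            a = [rows[i] for i in pick]
            b = [rows[i] for i in range(total) if i not in pick]
            null.append(abs(np.median(a) - np.median(b)))
    null = np.array(null)
    obs = np.median(data[:, :n1], axis=1) - np.median(data[:, n1:], axis=1)
    p = np.array([(1 + np.sum(null >= abs(o))) / (1 + null.size) for o in obs])
    return obs, p, null


def hypergeom_tail_oracle(N, K, n, k):
    """Exact upper-tail P(X >= k) by integer-arithmetic enumeration."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


def tmm_oracle(counts, trim_m=0.30, trim_a=0.05):
    """Literal plain-loop transcription of the trimmed-mean-of-M-values recipe.

    Pairwise against the reference column (scaled 75th percentile closest to
    the mean), compute M/A/delta-method weights gene by gene, drop the trim_m
    and trim_a tails by rank, take the precision-weighted mean of the
    surviving M values, exponentiate, and rescale to geometric mean one.
    """
    lib = counts.sum(axis=0)
    q75 = [np.quantile(counts[:, s] / lib[s], 0.75) for s in range(counts.shape[1])]
    ref = int(np.argmin([abs(q - np.mean(q75)) for q in q75]))

    factors = []
    for s in range(counts.shape[1]):
        if s == ref:
            factors.append(1.0)
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in range(counts.shape[0]):
            o, r = counts[g, s], counts[g, ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[s], r / lib[ref]
            m_vals.append(np.log2(po / pr))
            a_vals.append(0.5 * np.log2(po * pr))
            w_vals.append((lib[s] - o) / (lib[s] * o) + (lib[ref] - r) / (lib[ref] * r))
        m_vals, a_vals, w_vals = map(np.array, (m_vals, a_vals, w_vals))
        if np.max(np.abs(m_vals)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m_vals)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm, ra = rankdata(m_vals), rankdata(a_vals)
        num = den = 0.0
        kept = 0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += m_vals[i] / w_vals[i]
                den += 1.0 / w_vals[i]
                kept += 1
        if kept < 10:
            num = np.sum(m_vals / w_vals)
            den = np.sum(1.0 / w_vals)
        factors.append(2.0 ** (num / den))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))
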