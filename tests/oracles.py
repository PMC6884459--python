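"""Independent reference computations used to cross-check the implementation.

Each oracle recomputes a quantity by a different algorithm than the package
uses: hand step-up for BH, a subset-sum dynamic program for the rank-sum
null distribution, direct factorial-ratio summation for the hypergeometric
tail, and a gene-by-gene scipy loop for the differential-expression stage.
"""

import math
from collections import defaultdict

import numpy as np
from scipy import stats as sps


def bh_step_up_oracle(p):
    """Hand Benjamini-Hochberg: sort, scale by m/rank, enforce monotonicity."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        q[i] = running
    return q


def ranksum_dp_oracle(x, y):
    """Exact symmetric-deviation rank-sum p via dynamic programming.

    Builds the full null distribution of the group-1 rank sum with a
    subset-sum recursion, then sums probabilities of deviations at least
    as large as observed. Handles mid-rank ties exactly.
    """
    pooled = np.concatenate([x, y])
    ranks2 = (2 * sps.rankdata(pooled)).astype(int)  # doubled mid-ranks are ints
    n1, N = len(x), len(pooled)
    dp = [defaultdict(int) for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for k in range(min(n1, N), 0, -1):
            for s, c in list(dp[k - 1].items()):
                dp[k][s + r] += c
    obs2 = ranks2[:n1].sum()
    mu2 = n1 * (N + 1)
    dev = abs(obs2 - mu2)
    hits = sum(c for s, c in dp[n1].items() if abs(s - mu2) >= dev)
    return hits / math.comb(N, n1)


def hypergeom_tail_oracle(k, N, K, n):
    """Upper tail P(X >= k) of Hypergeometric(N, K, n) by direct summation."""
    total = 0.0
    for j in range(k, min(n, K) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
    return total


def de_oracle(control, mutant, alpha=0.05, min_tested_mean=1.0):
    """Gene-by-gene differential expression: scipy Welch t + hand BH."""
    tested_idx, pvals = [], []
    statuses = {}
    for i, g in enumerate(control.gene_ids):
        c, m = control.values[i], mutant.values[i]
        if not (c > 0).any() and not (m > 0).any():
            statuses[g] = "not_detected"
            continue
        lc, lm = np.log2(c + 1), np.log2(m + 1)
        if (c.mean() < min_tested_mean or m.mean() < min_tested_mean
                or (lc.var(ddof=1) == 0 and lm.var(ddof=1) == 0)):
            statuses[g] = "detected_untested"
            continue
        statuses[g] = "tested"
        tested_idx.append(i)
        pvals.append(float(sps.ttest_ind(lm, lc, equal_var=False).pvalue))
    q = bh_step_up_oracle(pvals)
    directions = {}
    for i, qi in zip(tested_idx, q):
        g = control.gene_ids[i]
        if qi < alpha:
            cm, mm = control.values[i].mean(), mutant.values[i].mean()
            directions[g] = "up" if mm > cm else ("down" if mm < cm else "none")
        else:
            directions[g] = "none"
    return statuses, directions
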