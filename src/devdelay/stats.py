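"""Statistical tests for the pipeline.

Two groups of tools live here. First, a simplified per-gene
differential-expression test — Welch's t on log2(x+1) transformed values
with Benjamini-Hochberg FDR control — that consumes gene-level expression
matrices directly; downstream stages only need (status, direction, means, q),
so a calibrated per-gene test is sufficient and no isoform-level machinery
is involved. Second, exact small-sample rank tests (rank-sum, signed-rank)
computed by full enumeration with mid-rank tie handling, plus
Kruskal-Wallis and Welch's t for the general comparisons used throughout
phenotype analyses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datamodel import (
    DETECTED_UNTESTED,
    DOWN,
    NONE,
    NOT_DETECTED,
    TESTED,
    UP,
    DEResult,
    ExpressionMatrix,
)

#: Largest pooled sample size for which rank tests enumerate exactly.
EXACT_LIMIT = 20

_EPS = 1e-12  # guards >= comparisons of enumerated statistics against float noise


@dataclass(frozen=True)
class TestOutcome:
    """Outcome of a hypothesis test: statistic, two-sided p, method label."""

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    note: str | None = None


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input.

    Each q is at least its p, at most 1, and monotone along the ranked
    p-values; thresholding q < alpha controls the expected false-discovery
    proportion at alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"sample {name!r} is empty")
    return arr


def wilcoxon_rank_sum_exact(x, y) -> TestOutcome:
    """Two-sided Wilcoxon rank-sum test for two independent samples.

    For pooled sizes up to ``EXACT_LIMIT`` the p-value is exact: all
    C(n1+n2, n1) assignments of the pooled values (mid-ranked, so ties are
    allowed) to the first group are enumerated, and p is the probability of
    a rank sum at least as far from its null mean as the observed one.
    Larger samples fall back to the normal approximation with tie
    correction.
    """
    xs = _as_sample(x, "x")
    ys = _as_sample(y, "y")
    n1, n2 = xs.size, ys.size
    pooled = np.concatenate([xs, ys])
    ranks = sps.rankdata(pooled)  # mid-ranks
    observed = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    dev = abs(observed - mu)

    if n1 + n2 <= EXACT_LIMIT:
        total = math.comb(n1 + n2, n1)
        hits = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            w = ranks[list(combo)].sum()
            if abs(w - mu) >= dev - _EPS:
                hits += 1
        p = hits / total
        method = "wilcoxon_rank_sum_exact"
    else:
        res = sps.mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "wilcoxon_rank_sum_normal_approx"
    return TestOutcome(float(observed), min(p, 1.0), method, (n1, n2))


def wilcoxon_signed_rank_exact(differences) -> TestOutcome:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded; remaining |differences| are mid-ranked.
    For up to ``EXACT_LIMIT`` nonzero differences all 2^n sign assignments
    are enumerated and p is the probability of a positive-rank sum at least
    as far from n(n+1)/4 as observed. Larger n uses the normal
    approximation.
    """
    d = _as_sample(differences, "differences")
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    dev = abs(observed - mu)

    if n <= EXACT_LIMIT:
        # Distribution of the positive-rank sum over all sign assignments.
        hits = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if abs(w - mu) >= dev - _EPS:
                hits += 1
        p = hits / 2**n
        method = "wilcoxon_signed_rank_exact"
    else:
        res = sps.wilcoxon(d, alternative="two-sided", method="approx")
        p = float(res.pvalue)
        method = "wilcoxon_signed_rank_normal_approx"
    return TestOutcome(float(observed), min(p, 1.0), method, (n,))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestOutcome:
    """Kruskal-Wallis H test across two or more groups.

    H uses mid-ranks with the standard tie correction; p comes from the
    chi-square approximation with k-1 degrees of freedom. When every pooled
    value is identical the statistic is 0 and p is 1 (no evidence of any
    group difference), rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    samples = [_as_sample(g, f"group {i}") for i, g in enumerate(groups)]
    sizes = [s.size for s in samples]
    pooled = np.concatenate(samples)
    n = pooled.size
    ranks = sps.rankdata(pooled)

    h = 0.0
    start = 0
    for size in sizes:
        r_sum = ranks[start : start + size].sum()
        h += r_sum**2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (counts**3 - counts).sum() / (n**3 - n) if n > 1 else 1.0
    if tie_term == 0.0:  # all values identical
        return TestOutcome(0.0, 1.0, "kruskal_wallis", tuple(sizes))
    h /= tie_term
    p = float(sps.chi2.sf(h, df=len(samples) - 1))
    return TestOutcome(float(h), p, "kruskal_wallis", tuple(sizes))


def welch_t(x, y) -> TestOutcome:
    """Welch's two-sided t test with Satterthwaite degrees of freedom.

    Degenerate variances follow the limit conventions: both variances zero
    with equal means gives p = 1; both zero with unequal means gives the
    p -> 0 limit, flagged in ``note``.
    """
    xs = _as_sample(x, "x")
    ys = _as_sample(y, "y")
    if xs.size < 2 or ys.size < 2:
        raise ValueError("welch_t requires at least two observations per group")
    n1, n2 = xs.size, ys.size
    v1, v2 = xs.var(ddof=1), ys.var(ddof=1)
    delta = xs.mean() - ys.mean()
    if v1 == 0.0 and v2 == 0.0:
        if delta == 0.0:
            return TestOutcome(0.0, 1.0, "welch_t", (n1, n2), note="zero variance")
        return TestOutcome(
            math.copysign(math.inf, delta),
            0.0,
            "welch_t",
            (n1, n2),
            note="zero variance in both groups with unequal means",
        )
    se2 = v1 / n1 + v2 / n2
    t = delta / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestOutcome(float(t), min(p, 1.0), "welch_t", (n1, n2))


def differential_expression(
    control: ExpressionMatrix,
    mutant: ExpressionMatrix,
    alpha: float = 0.05,
    min_tested_mean: float = 1.0,
) -> list[DEResult]:
    """Per-gene differential expression between two conditions.

    Genes with zero expression in every replicate of both conditions are
    ``not_detected``. Detected genes are testable when both condition means
    reach ``min_tested_mean`` and at least one group has nonzero variance
    on the log2(x+1) scale; testable genes get a Welch t p-value, a BH
    q-value across all tested genes, and a direction (``up``/``down``) when
    q < ``alpha``. Fold change is log2 of the (+1 pseudocounted) mean ratio,
    mutant over control.
    """
    if control.gene_ids != mutant.gene_ids:
        raise ValueError("control and mutant matrices must share gene ids and order")
    n1, n2 = control.n_replicates, mutant.n_replicates
    if n1 < 2 or n2 < 2:
        raise ValueError("differential testing requires >=2 replicates per condition")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")

    c, m = control.values, mutant.values
    mean_c, mean_m = c.mean(axis=1), m.mean(axis=1)
    detected = (c > 0).any(axis=1) | (m > 0).any(axis=1)

    lc, lm = np.log2(c + 1.0), np.log2(m + 1.0)
    v1, v2 = lc.var(axis=1, ddof=1), lm.var(axis=1, ddof=1)
    degenerate = (v1 == 0.0) & (v2 == 0.0)
    testable = (
        detected
        & (mean_c >= min_tested_mean)
        & (mean_m >= min_tested_mean)
        & ~degenerate
    )

    # Vectorized Welch t on the log scale across all testable genes.
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (lm.mean(axis=1) - lc.mean(axis=1)) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = np.full(c.shape[0], np.nan)
    p[testable] = 2.0 * sps.t.sf(np.abs(t[testable]), df[testable])
    np.clip(p, 0.0, 1.0, out=p)

    q = np.full(c.shape[0], np.nan)
    if testable.any():
        q[testable] = bh_adjust(p[testable])

    lfc = np.log2((mean_m + 1.0) / (mean_c + 1.0))

    results: list[DEResult] = []
    for i, gene in enumerate(control.gene_ids):
        if not detected[i]:
            results.append(DEResult(gene, NOT_DETECTED, 0.0, 0.0))
        elif not testable[i]:
            results.append(
                DEResult(gene, DETECTED_UNTESTED, float(mean_c[i]), float(mean_m[i]))
            )
        else:
            if q[i] < alpha and mean_m[i] > mean_c[i]:
                direction = UP
            elif q[i] < alpha and mean_m[i] < mean_c[i]:
                direction = DOWN
            else:
                direction = NONE
            results.append(
                DEResult(
                    gene,
                    TESTED,
                    float(mean_c[i]),
                    float(mean_m[i]),
                    log2_fold_change=float(lfc[i]),
                    p_value=float(p[i]),
                    q_value=float(q[i]),
                    direction=direction,
                )
            )
    return results
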