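"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: plain-Python
exhaustive search and simple per-partition EM, feasible only at small n.
"""

from __future__ import annotations

import math
from itertools import combinations


def max_order_consistent_subset(ref_order: list[str], study_order: list[str]) -> int:
    """Size of the largest shared-marker subset with agreeing relative order.

    Exhaustive over all subsets of the shared markers (use only for <= ~12).
    """
    shared = [m for m in ref_order if m in set(study_order)]
    ref_rank = {m: i for i, m in enumerate(ref_order)}
    study_rank = {m: i for i, m in enumerate(study_order)}
    best = 0
    n = len(shared)
    for mask in range(1, 1 << n):
        subset = [shared[i] for i in range(n) if mask >> i & 1]
        by_ref = sorted(subset, key=ref_rank.get)
        by_study = sorted(subset, key=study_rank.get)
        if by_ref == by_study:
            best = max(best, len(subset))
    return best


def _em_plain(xs, s2s, mu, pi, tol=1e-12, max_iter=2000):
    """Scalar-loop EM for a 1-D fixed-variance mixture; returns (mu, pi, loglik)."""
    n, k = len(xs), len(mu)
    loglik = -math.inf
    for _ in range(max_iter):
        resp = [[0.0] * k for _ in range(n)]
        new_loglik = 0.0
        for i in range(n):
            logs = [
                math.log(max(pi[j], 1e-300))
                - 0.5 * (math.log(2 * math.pi * s2s[i]) + (xs[i] - mu[j]) ** 2 / s2s[i])
                for j in range(k)
            ]
            m = max(logs)
            total = sum(math.exp(v - m) for v in logs)
            new_loglik += m + math.log(total)
            for j in range(k):
                resp[i][j] = math.exp(logs[j] - m) / total
        for j in range(k):
            wsum = sum(resp[i][j] / s2s[i] for i in range(n))
            if wsum > 0:
                mu[j] = sum(resp[i][j] * xs[i] / s2s[i] for i in range(n)) / wsum
            pi[j] = max(sum(resp[i][j] for i in range(n)) / n, 1e-6)
        z = sum(pi)
        pi = [p / z for p in pi]
        if abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            break
        loglik = new_loglik
    return mu, pi, loglik


def mixture_loglik_oracle(positions, sigmas, k) -> float:
    """Global max log-likelihood by EM from every contiguous partition start.

    Clusters of an optimal hard assignment are contiguous in 1-D, so seeding
    EM from every contiguous partition of the sorted data explores every
    basin that matters.
    """
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    xs = [positions[i] for i in order]
    s2s = [sigmas[i] ** 2 for i in order]
    n = len(xs)
    best = -math.inf
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0,) + cuts + (n,)
        mu, pi = [], []
        for a, b in zip(bounds, bounds[1:]):
            w = [1.0 / s2s[i] for i in range(a, b)]
            mu.append(sum(wi * xs[i] for wi, i in zip(w, range(a, b))) / sum(w))
            pi.append((b - a) / n)
        _, _, ll = _em_plain(xs, s2s, mu, pi)
        best = max(best, ll)
    return best


def select_k_oracle(positions, sigmas, k_max=10) -> tuple[int, float]:
    """(K, loglik) minimising AIC = -2 lnL + 2(2K-1); ties toward smaller K."""
    n = len(positions)
    best_k, best_ll, best_aic = None, None, math.inf
    for k in range(1, min(k_max, n) + 1):
        ll = mixture_loglik_oracle(positions, sigmas, k)
        aic = -2 * ll + 2 * (2 * k - 1)
        if aic < best_aic - 1e-12:
            best_k, best_ll, best_aic = k, ll, aic
    return best_k, best_ll


def overlap_oracle(set_a, set_b):
    """Quadratic pairwise-intersection + merge oracle; returns (chrom, start, end) triples."""
    pieces = []
    for _, a in set_a:
        for _, b in set_b:
            if a.chromosome == b.chromosome and a.start <= b.end and b.start <= a.end:
                pieces.append((a.chromosome, max(a.start, b.start), min(a.end, b.end)))
    pieces.sort()
    merged = []
    for chrom, s, e in pieces:
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((chrom, s, e))
    return merged
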