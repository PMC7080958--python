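"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive each quantity from first principles (literal
filter application, per-bp scans, direct Poisson log-likelihoods) and
share no code with the implementation they check.
"""

import math

import numpy as np
from scipy import stats


def breakpoints_bruteforce(segments, zones, delta_thr=0.4, min_seg=10_000):
    """Literal filter-then-compare breakpoint extraction on one chromosome.

    ``segments``: list of (start, end, log2) sorted by start.
    ``zones``: list of (start, end) exclusion intervals.
    Returns list of (position, delta).
    """
    kept = [s for s in segments if s[1] - s[0] >= min_seg]
    out = []
    for left, right in zip(kept, kept[1:]):
        delta = abs(right[2] - left[2])
        if delta <= delta_thr:
            continue
        if right[0] <= left[1]:
            pos = left[1]
        else:
            pos = (left[1] + right[0]) // 2
        if any(zs <= pos < ze for zs, ze in zones):
            continue
        out.append((pos, delta))
    return out


def bin_states_bruteforce(segments, chrom_len, bin_width,
                          gain_thr=0.2, loss_thr=-0.2):
    """Per-bp majority bin states for one sample on one chromosome.

    Fills a per-bp state array (+1 gain, -1 loss, 0 neutral) and calls a
    bin gain/loss when that state covers the strict majority of the bin
    AND more than half its length.
    """
    bp = np.zeros(chrom_len, dtype=np.int8)
    for s, e, log2 in segments:
        state = 1 if log2 > gain_thr else (-1 if log2 < loss_thr else 0)
        bp[s:e] = state
    n_bins = -(-chrom_len // bin_width)
    out = np.zeros(n_bins, dtype=np.int8)
    for i in range(n_bins):
        chunk = bp[i * bin_width : min((i + 1) * bin_width, chrom_len)]
        gain = int((chunk == 1).sum())
        loss = int((chunk == -1).sum())
        half = len(chunk) / 2
        if gain > loss and gain > half:
            out[i] = 1
        elif loss > gain and loss > half:
            out[i] = -1
    return out


def clustering_lr_bruteforce(k, L, N, G):
    """Direct two-model Poisson log-likelihood difference, via logpmf.

    Clustered model: rate k/L inside the region, (N-k)/(G-L) outside.
    Homogeneous model: rate N/G everywhere.  Likelihoods are evaluated on
    the observed inside/outside counts.
    """
    if k == 0 or k / L == N / G:
        return 0.0
    lam0 = N / G
    ll_clustered = stats.poisson.logpmf(k, k)  # mean lam1*L = k
    ll_homog = stats.poisson.logpmf(k, lam0 * L)
    if G > L:
        rest = N - k
        ll_clustered += stats.poisson.logpmf(rest, rest)
        ll_homog += stats.poisson.logpmf(rest, lam0 * (G - L))
    return float((ll_clustered - ll_homog) / math.log(10))


def poisson_upper_tail_bruteforce(observed, mean, max_terms=4000):
    """P(X >= observed) for X ~ Poisson(mean) by direct summation."""
    log_terms = []
    for x in range(observed, observed + max_terms):
        log_terms.append(x * math.log(mean) - mean - math.lgamma(x + 1))
    m = max(log_terms)
    return math.exp(m) * sum(math.exp(t - m) for t in log_terms)


def fisher_p_bruteforce(a, b, c, d):
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {
        x: math.exp(
            math.lgamma(row1 + 1) - math.lgamma(x + 1) - math.lgamma(row1 - x + 1)
            + math.lgamma(n - row1 + 1) - math.lgamma(col1 - x + 1)
            - math.lgamma(n - row1 - col1 + x + 1)
            + math.lgamma(col1 + 1) + math.lgamma(n - col1 + 1) - math.lgamma(n + 1)
        )
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
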