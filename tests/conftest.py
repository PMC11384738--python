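"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use the dumbest correct algorithm (per-base
scans, all-pairs loops, exact rational arithmetic, exhaustive enumeration)
so they share no code path with the implementation they check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from tfrewire.intervals import GenomicInterval, RegionSet

SEED = 42  # suite-wide seed, fixed up front


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


# ---------------------------------------------------------------------------
# interval oracles (toy genomes, <= 10 kb)
# ---------------------------------------------------------------------------

def covered_bases_oracle(intervals) -> set[tuple[str, int]]:
    """Set of (chrom, base) covered by any interval. Per-base scan."""
    out = set()
    for iv in intervals:
        for b in range(iv.start, iv.end):
            out.add((iv.chrom, b))
    return out


def overlap_pairs_oracle(a, b, min_bp=1, min_frac=0.0, frac_side="a"):
    """All-pairs O(n*m) overlap scan."""
    out = []
    for iva in a:
        for ivb in b:
            ov = iva.overlap_bp(ivb)
            ref = iva if frac_side == "a" else ivb
            if ov >= min_bp and ov / ref.length >= min_frac:
                out.append((iva, ivb, ov))
    out.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1].start, t[1].end))
    return out


def random_region_set(rng, n, genome_len=10_000, label="", max_len=400, chroms=("chr1",)):
    ivs = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, genome_len - 1))
        length = int(rng.integers(1, max_len + 1))
        end = min(genome_len, start + length)
        ivs.append(GenomicInterval(chrom, start, end, name=f"{label}{i}"))
    return RegionSet(label=label, intervals=tuple(ivs))


# ---------------------------------------------------------------------------
# statistical oracles
# ---------------------------------------------------------------------------

def hypergeom_tail_exact(N, K, n, k) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    num = sum(comb(K, j) * comb(N - K, n - j)
              for j in range(k, min(K, n) + 1) if n - j <= N - K)
    return Fraction(num, comb(N, n))


def rank_sum_p_oracle(a, b, alternative="two-sided"):
    """Exhaustive rank-sum p over all assignments of pooled tie-free values."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle needs tie-free input"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n, m = len(a), len(b)
    r_obs = sum(ranks[v] for v in a)
    u_obs = r_obs - n * (n + 1) / 2
    centre = n * m / 2
    us = []
    for combo in itertools.combinations(range(n + m), n):
        r = sum(i + 1 for i in combo)
        us.append(r - n * (n + 1) / 2)
    us = np.array(us)
    if alternative == "greater":
        p = np.mean(us >= u_obs)
    elif alternative == "less":
        p = np.mean(us <= u_obs)
    else:
        p = np.mean(np.abs(us - centre) >= abs(u_obs - centre))
    return float(p)


def signed_rank_p_oracle(diffs, alternative="two-sided"):
    """Exhaustive signed-rank p over all 2^n sign patterns (tie-free |d|)."""
    d = [x for x in diffs if x != 0]
    mags = sorted(abs(x) for x in d)
    assert len(set(mags)) == len(mags), "oracle needs tie-free |differences|"
    rank = {m: i + 1 for i, m in enumerate(mags)}
    n = len(d)
    w_obs = sum(rank[abs(x)] for x in d if x > 0)
    centre = n * (n + 1) / 4
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(rank[abs(d[i])] for i in range(n) if signs[i]))
    ws = np.array(ws)
    if alternative == "greater":
        p = np.mean(ws >= w_obs)
    elif alternative == "less":
        p = np.mean(ws <= w_obs)
    else:
        p = np.mean(np.abs(ws - centre) >= abs(w_obs - centre))
    return float(p)


def subset_mean_tail_oracle(values, target_idx, direction):
    """Exact tail of the size-matched subset-mean null by full enumeration."""
    values = np.asarray(values, dtype=float)
    k = len(target_idx)
    obs = values[list(target_idx)].mean()
    hits = total = 0
    for combo in itertools.combinations(range(len(values)), k):
        m = values[list(combo)].mean()
        total += 1
        if direction == "greater":
            hits += m >= obs - 1e-12
        else:
            hits += m <= obs + 1e-12
    return hits / total
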