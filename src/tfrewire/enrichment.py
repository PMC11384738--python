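"""Hypergeometric overlap enrichment against explicit background universes.

The background universe is the urn of the test: a merged, non-overlapping
region set representing everything that *could* have been overlapped (for
TF-peak/enhancer overlaps: all detected open-chromatin regions merged with
the enhancer lists). Counting is done in universe-region space so the
hypergeometric urn is well-defined even when one raw peak touches several
universe regions: N universe regions, K overlapped by set A, n overlapped
by set B, k overlapped by both, and the reported p-value is the upper tail
P(X >= k). Overlap *fractions*, by contrast, are reported on raw peak
counts, matching how Venn-style percentages are usually quoted.

The same statistic serves gene-set enrichment (query vs target within a
gene universe).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, RegionSet, merge, overlap_pairs

__all__ = [
    "BackgroundUniverse",
    "OverlapEnrichment",
    "build_background",
    "hypergeom_upper_tail",
    "region_overlap_enrichment",
    "gene_set_enrichment",
]

_TINY = float(np.nextafter(0, 1))


@dataclass(frozen=True)
class BackgroundUniverse:
    """Merged, non-overlapping region universe with provenance labels."""

    regions: RegionSet
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.regions) == 0:
            raise ValueError("background universe is empty")
        if not self.regions.is_disjoint():
            raise ValueError("background universe must be non-overlapping")

    @property
    def size(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class OverlapEnrichment:
    """Hypergeometric overlap result for two sets on one universe."""

    set_a: str
    set_b: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    fraction_a_in_b: float
    fraction_b_in_a: float

    def as_dict(self) -> dict:
        return {
            "set_a": self.set_a,
            "set_b": self.set_b,
            "N": self.N,
            "K": self.K,
            "n": self.n,
            "k": self.k,
            "p_value": self.p_value,
            "frac_a_in_b": self.fraction_a_in_b,
            "frac_b_in_a": self.fraction_b_in_a,
        }


def build_background(sets: Sequence[RegionSet]) -> BackgroundUniverse:
    """Merge region sets into one background universe, recording provenance."""
    if not sets or all(len(s) == 0 for s in sets):
        raise ValueError("need at least one non-empty region set")
    ivs: list[GenomicInterval] = []
    for s in sets:
        ivs.extend(s.intervals)
    merged = merge(ivs)
    return BackgroundUniverse(
        regions=merged.relabel("background"),
        provenance=tuple(s.label for s in sets),
    )


def hypergeom_upper_tail(N: int, K: int, n: int, k: int, lower: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= k), X ~ HG(N, K, n).

    With ``lower=True`` returns the depletion tail P(X <= k) instead. The
    result is clipped into (0, 1] so a p-value of exactly 0 is never
    reported.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N (N={N}, K={K}, n={n})")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n) (K={K}, n={n}, k={k})")
    if lower:
        p = float(stats.hypergeom.cdf(k, N, K, n))
    else:
        # sf(k-1) = P(X >= k); exact 1.0 at k = 0
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(_TINY, p))


def _regions_hit(universe: BackgroundUniverse, query: RegionSet, min_bp: int) -> set[int]:
    """Indices of universe regions overlapped by >= min_bp by any query interval."""
    pairs = overlap_pairs(universe.regions, query, min_bp=min_bp)
    index = {iv: i for i, iv in enumerate(universe.regions)}
    return {index[u] for u, _q, _ov in pairs}


def region_overlap_enrichment(
    set_a: RegionSet,
    set_b: RegionSet,
    universe: BackgroundUniverse,
    min_bp: int = 1,
    lower: bool = False,
) -> OverlapEnrichment:
    """Overlap enrichment of two region sets on a background universe.

    K, n and k are counts of universe regions overlapped (by >= ``min_bp``)
    by A, by B, and by both; the p-value is the hypergeometric upper tail
    (or lower with ``lower=True``). The fractions are computed on raw peak
    counts: the fraction of A intervals overlapping any B interval, and
    vice versa. The fractions are therefore independent of the universe;
    the p-value is not.
    """
    if universe.size == 0:
        raise ValueError("empty universe")
    hit_a = _regions_hit(universe, set_a, min_bp)
    hit_b = _regions_hit(universe, set_b, min_bp)
    N = universe.size
    K, n = len(hit_a), len(hit_b)
    k = len(hit_a & hit_b)
    p = hypergeom_upper_tail(N, K, n, k, lower=lower)
    pairs_ab = overlap_pairs(set_a, set_b, min_bp=min_bp)
    a_hit = len({a for a, _b, _ov in pairs_ab})
    b_hit = len({b for _a, b, _ov in pairs_ab})
    frac_a = a_hit / len(set_a) if len(set_a) else 0.0
    frac_b = b_hit / len(set_b) if len(set_b) else 0.0
    return OverlapEnrichment(
        set_a=set_a.label,
        set_b=set_b.label,
        N=N,
        K=K,
        n=n,
        k=k,
        p_value=p,
        fraction_a_in_b=frac_a,
        fraction_b_in_a=frac_b,
    )


def gene_set_enrichment(
    query: AbstractSet[str],
    target: AbstractSet[str],
    universe: AbstractSet[str],
    labels: tuple[str, str] = ("query", "target"),
) -> OverlapEnrichment:
    """Hypergeometric enrichment of a query gene set in a target gene set.

    Both sets must be subsets of the gene universe (e.g. all genes linked
    to accessible chromatin, or all detected genes). The upper-tail
    p-value is for the observed intersection size or larger.
    """
    query, target, universe = set(query), set(target), set(universe)
    if not query <= universe:
        raise ValueError("query is not a subset of the universe")
    if not target <= universe:
        raise ValueError("target is not a subset of the universe")
    N, K, n = len(universe), len(target), len(query)
    k = len(query & target)
    p = hypergeom_upper_tail(N, K, n, k)
    return OverlapEnrichment(
        set_a=labels[0],
        set_b=labels[1],
        N=N,
        K=K,
        n=n,
        k=k,
        p_value=p,
        fraction_a_in_b=k / n if n else 0.0,
        fraction_b_in_a=k / K if K else 0.0,
    )
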