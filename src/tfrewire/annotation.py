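"""Peak-to-gene assignment and gene-level target groups.

Each peak is assigned to the gene with the nearest transcription start site
(TSS) on the same chromosome. Distances are signed relative to gene
orientation: 0 if the peak spans the TSS, positive downstream of the TSS,
negative upstream. A peak is a promoter peak when its signed distance falls
inside the promoter window (default -3000..+3000 bp, the conventional
ChIP-annotation default). Gene-level target groups (condition-1-specific /
condition-2-specific / shared) are then derived from per-category
assignments with an explicit, documented resolution rule.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .intervals import GenomicInterval, RegionSet

__all__ = [
    "GeneModel",
    "PeakGeneAssignment",
    "TargetGroups",
    "read_genes_tsv",
    "write_genes_tsv",
    "assign_peaks_to_genes",
    "classify_promoter_fraction",
    "derive_target_groups",
]


@dataclass(frozen=True, order=True)
class GeneModel:
    """Minimal gene model: identifier, chromosome, strand and TSS position."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass(frozen=True)
class PeakGeneAssignment:
    """A peak assigned to its nearest-TSS gene with a signed distance."""

    peak: GenomicInterval
    gene_id: str
    distance: int
    is_promoter: bool


@dataclass(frozen=True)
class TargetGroups:
    """Pairwise-disjoint gene-id sets per binding category."""

    cond1_specific: frozenset[str]
    cond2_specific: frozenset[str]
    shared: frozenset[str]

    def __post_init__(self) -> None:
        if (
            self.cond1_specific & self.cond2_specific
            or self.cond1_specific & self.shared
            or self.cond2_specific & self.shared
        ):
            raise ValueError("target groups must be pairwise disjoint")

    @property
    def all_targets(self) -> frozenset[str]:
        return self.cond1_specific | self.cond2_specific | self.shared

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {
            "cond1_specific": self.cond1_specific,
            "cond2_specific": self.cond2_specific,
            "shared": self.shared,
        }

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.as_dict().items()}


def read_genes_tsv(path: str | Path) -> list[GeneModel]:
    """Read a gene table with columns gene_id, chrom, strand, tss."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    genes = [
        GeneModel(row.gene_id, row.chrom, row.strand, int(row.tss))
        for row in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in gene table")
    return genes


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _signed_distance(peak: GenomicInterval, gene: GeneModel) -> int:
    """Signed peak-to-TSS distance respecting gene orientation."""
    if peak.start <= gene.tss < peak.end:
        return 0
    if peak.start > gene.tss:
        genomic = peak.start - gene.tss  # peak right of TSS
    else:
        genomic = (peak.end - 1) - gene.tss  # peak left of TSS (negative)
    return genomic if gene.strand == "+" else -genomic


def assign_peaks_to_genes(
    peaks: RegionSet,
    genes: Sequence[GeneModel],
    promoter_window: tuple[int, int] = (-3000, 3000),
    max_distance: int | None = None,
) -> tuple[list[PeakGeneAssignment], list[GenomicInterval]]:
    """Assign every peak to its nearest-TSS gene on the same chromosome.

    Ties in absolute distance go to the lexicographically smallest gene_id.
    Peaks on chromosomes without genes — or, when ``max_distance`` is set,
    farther than that from every TSS — are returned unassigned.

    Returns ``(assignments, unassigned_peaks)``.
    """
    if not genes:
        raise ValueError("gene table is empty")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in gene table")
    lo, hi = promoter_window
    if lo > hi:
        raise ValueError("promoter_window must be (low, high) with low <= high")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.tss, g.gene_id))
    tss_by_chrom = {c: [g.tss for g in gs] for c, gs in by_chrom.items()}

    assignments: list[PeakGeneAssignment] = []
    unassigned: list[GenomicInterval] = []
    for peak in peaks:
        chrom_genes = by_chrom.get(peak.chrom)
        if not chrom_genes:
            unassigned.append(peak)
            continue
        tss_list = tss_by_chrom[peak.chrom]
        # candidate genes: the few flanking the peak suffice for nearest-TSS,
        # including equal-TSS runs around the insertion points
        i0 = bisect.bisect_left(tss_list, peak.start)
        i1 = bisect.bisect_right(tss_list, peak.end)
        lo_i = max(0, i0 - 1)
        while lo_i > 0 and tss_list[lo_i - 1] == tss_list[lo_i]:
            lo_i -= 1  # cover the whole equal-TSS run for the tie rule
        hi_i = min(len(chrom_genes) - 1, i1)
        while hi_i + 1 < len(chrom_genes) and tss_list[hi_i + 1] == tss_list[hi_i]:
            hi_i += 1
        cand = range(lo_i, hi_i + 1)
        best: GeneModel | None = None
        best_abs = None
        for i in cand:
            g = chrom_genes[i]
            d = abs(_signed_distance(peak, g))
            if best is None or d < best_abs or (d == best_abs and g.gene_id < best.gene_id):
                best, best_abs = g, d
        assert best is not None
        if max_distance is not None and best_abs > max_distance:
            unassigned.append(peak)
            continue
        dist = _signed_distance(peak, best)
        assignments.append(
            PeakGeneAssignment(
                peak=peak,
                gene_id=best.gene_id,
                distance=dist,
                is_promoter=lo <= dist <= hi,
            )
        )
    return assignments, unassigned


def classify_promoter_fraction(assignments: Sequence[PeakGeneAssignment]) -> float:
    """Fraction of assigned peaks whose signed distance is in the promoter window."""
    if not assignments:
        raise ValueError("no assignments given")
    return sum(a.is_promoter for a in assignments) / len(assignments)


def derive_target_groups(
    assignments_cond1_only: Sequence[PeakGeneAssignment],
    assignments_cond2_only: Sequence[PeakGeneAssignment],
    assignments_shared: Sequence[PeakGeneAssignment],
    split_hits: str = "shared",
) -> TargetGroups:
    """Collapse per-category peak assignments to disjoint gene-level groups.

    A gene hit by a shared-category peak is shared. A gene hit by both a
    condition-1-only and a condition-2-only peak is, under the default
    ``split_hits="shared"`` rule, also shared (it is bound in both
    conditions, just at different sites); with ``split_hits="drop"`` such
    genes are excluded from all groups. Remaining genes are
    condition-specific.
    """
    if split_hits not in ("shared", "drop"):
        raise ValueError("split_hits must be 'shared' or 'drop'")
    g1 = {a.gene_id for a in assignments_cond1_only}
    g2 = {a.gene_id for a in assignments_cond2_only}
    gs = {a.gene_id for a in assignments_shared}
    both = g1 & g2
    if split_hits == "shared":
        shared = gs | both
    else:
        shared = gs - both
    return TargetGroups(
        cond1_specific=frozenset(g1 - shared - both),
        cond2_specific=frozenset(g2 - shared - both),
        shared=frozenset(shared),
    )


def assignments_to_frame(assignments: Sequence[PeakGeneAssignment]) -> pd.DataFrame:
    """Tabulate assignments with BED-compatible peak columns."""
    return pd.DataFrame(
        {
            "chrom": [a.peak.chrom for a in assignments],
            "start": [a.peak.start for a in assignments],
            "end": [a.peak.end for a in assignments],
            "peak_name": [a.peak.name for a in assignments],
            "gene_id": [a.gene_id for a in assignments],
            "distance": [a.distance for a in assignments],
            "is_promoter": [a.is_promoter for a in assignments],
        }
    )
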