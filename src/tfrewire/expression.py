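"""Differential-expression tables, rank tests, time courses and CUT&RUN ratios.

The :class:`ExpressionTable` holds per-gene log2 fold changes and adjusted
p-values for one or more contrasts (wide layout, columns
``log2fc_<contrast>`` / ``padj_<contrast>``) plus an optional TPM time
course (columns ``tpm_<timepoint>``). DEG filtering uses the conventional
inclusive thresholds: adjusted p <= alpha and |log2FC| >= a minimum effect.

Rank-based two-group and paired tests wrap scipy with an explicit,
documented switch between exact enumeration (small, tie-free samples) and
the normal approximation with tie and continuity corrections.

CUT&RUN qPCR quantification follows the double-normalisation scheme used
for spike-in-calibrated chromatin profiling: target signal over a genomic
background amplicon, further scaled by the exogenous spike-in signal, and
finally expressed relative to a control sample (whose own fold change is 1
by construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import AbstractSet, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionTable",
    "DegResult",
    "QpcrSignalTable",
    "filter_degs",
    "rank_sum_test",
    "signed_rank_test",
    "trajectory_summary",
    "cutrun_relative_signal",
]

# exact-enumeration switch points for tie-free inputs
RANK_SUM_EXACT_MAX = 8  # min(n, m) <= 8
SIGNED_RANK_EXACT_MAX = 15  # n <= 15


class ExpressionTable:
    """Per-gene expression statistics, indexed by unique gene id."""

    def __init__(self, data: pd.DataFrame):
        if data.index.name != "gene_id":
            if "gene_id" in data.columns:
                data = data.set_index("gene_id")
            else:
                raise ValueError("expected a 'gene_id' index or column")
        if not data.index.is_unique:
            raise ValueError("gene ids must be unique")
        for c in data.columns:
            if c.startswith("padj"):
                vals = data[c].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise ValueError(f"column {c} has adjusted p outside [0, 1]")
        self.data = data

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def contrasts(self) -> list[str]:
        return [c.removeprefix("log2fc_") for c in self.data.columns
                if c.startswith("log2fc_")]

    @property
    def timepoints(self) -> list[str]:
        return [c.removeprefix("tpm_") for c in self.data.columns
                if c.startswith("tpm_")]

    def _contrast(self, contrast: str | None) -> str:
        names = self.contrasts
        if contrast is None:
            if len(names) != 1:
                raise ValueError(
                    f"table has contrasts {names}; specify one explicitly"
                )
            return names[0]
        if contrast not in names:
            raise ValueError(f"unknown contrast {contrast!r}; have {names}")
        return contrast

    def log2fc(self, contrast: str | None = None) -> pd.Series:
        return self.data[f"log2fc_{self._contrast(contrast)}"]

    def padj(self, contrast: str | None = None) -> pd.Series:
        return self.data[f"padj_{self._contrast(contrast)}"]

    def tpm_matrix(self) -> pd.DataFrame:
        cols = [f"tpm_{t}" for t in self.timepoints]
        if not cols:
            raise ValueError("table has no TPM time-course columns")
        return self.data[cols].rename(columns=lambda c: c.removeprefix("tpm_"))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", float_format="%.10g")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class DegResult:
    """Differentially expressed genes with up/down subsets."""

    genes: frozenset[str]
    up: frozenset[str]
    down: frozenset[str]
    alpha: float
    min_abs_log2fc: float

    def __post_init__(self) -> None:
        if self.up | self.down != self.genes or self.up & self.down:
            raise ValueError("up/down must partition the DEG set")


def filter_degs(
    expr: ExpressionTable,
    contrast: str | None = None,
    alpha: float = 0.05,
    min_abs_log2fc: float = 0.5,
) -> DegResult:
    """Genes with padj <= alpha and |log2FC| >= min_abs_log2fc (inclusive).

    Up- and down-regulated subsets split by log2FC sign. Relaxing either
    threshold can only grow the result.
    """
    lfc = expr.log2fc(contrast)
    padj = expr.padj(contrast)
    mask = (padj <= alpha) & (lfc.abs() >= min_abs_log2fc)
    mask &= padj.notna() & lfc.notna()
    up = frozenset(lfc.index[mask & (lfc > 0)])
    down = frozenset(lfc.index[mask & (lfc < 0)])
    # log2FC exactly 0 can pass only when min_abs_log2fc == 0; call it neither
    genes = up | down
    return DegResult(genes=genes, up=up, down=down,
                     alpha=alpha, min_abs_log2fc=min_abs_log2fc)


def _norm_alternative(alternative: str) -> str:
    alt = alternative.replace("_", "-")
    if alt not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    return alt


def rank_sum_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test; returns (U of sample a, p).

    Exact enumeration when min(n, m) <= 8 and the pooled values are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    alt = _norm_alternative(alternative)
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if (min(a.size, b.size) <= RANK_SUM_EXACT_MAX and tie_free) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alt, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(
    paired_diffs: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences; returns (W, p).

    Zero differences are dropped (standard Wilcoxon convention); an
    all-zero input is an error. Exact enumeration when the remaining n <= 15
    and the |differences| are tie-free; otherwise the normal approximation
    with tie and continuity corrections.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    alt = _norm_alternative(alternative)
    tie_free = len(np.unique(np.abs(d))) == d.size
    method = "exact" if (d.size <= SIGNED_RANK_EXACT_MAX and tie_free) else "approx"
    res = stats.wilcoxon(d, alternative=alt, method=method, correction=True)
    return float(res.statistic), float(res.pvalue)


def trajectory_summary(
    expr: ExpressionTable | pd.DataFrame,
    gene_group: Iterable[str],
) -> pd.DataFrame:
    """Per-timepoint mean and sd of row-normalised expression for a group.

    Each gene's trajectory is z-normalised across timepoints (constant
    genes map to an all-zero trajectory); the group summary is the
    per-timepoint mean +/- sd of the normalised trajectories. Input is an
    :class:`ExpressionTable` with TPM columns or a gene x timepoint frame.
    """
    tpm = expr.tpm_matrix() if isinstance(expr, ExpressionTable) else expr
    if tpm.shape[1] < 2:
        raise ValueError("need at least 2 timepoints")
    group = list(dict.fromkeys(gene_group))
    if not group:
        raise ValueError("gene group is empty")
    missing = [g for g in group if g not in tpm.index]
    if missing:
        raise ValueError(f"genes absent from the time course (e.g. {missing[:3]})")
    sub = tpm.loc[group].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (sub - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(
        {"mean": z.mean(axis=0), "sd": z.std(axis=0, ddof=0)},
        index=pd.Index(tpm.columns, name="timepoint"),
    )


class QpcrSignalTable:
    """Long-format qPCR signals: sample, amplicon, role, linear-scale signal.

    Roles are ``target``, ``genomic_background`` and ``spike_in``; every
    sample needs at least one background and one spike-in row, and all
    signals must be positive. With ``from_ct`` the table is built from Ct
    values via signal = 2**(-Ct).
    """

    ROLES = ("target", "genomic_background", "spike_in")

    def __init__(self, data: pd.DataFrame):
        required = {"sample_id", "amplicon_id", "role", "signal"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
        bad_roles = set(data["role"]) - set(self.ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        if (data["signal"] <= 0).any() or data["signal"].isna().any():
            raise ValueError("all signals must be positive")
        for sample, sub in data.groupby("sample_id"):
            roles = set(sub["role"])
            if "genomic_background" not in roles:
                raise ValueError(f"sample {sample!r} lacks a genomic_background row")
            if "spike_in" not in roles:
                raise ValueError(f"sample {sample!r} lacks a spike_in row")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_ct(cls, data: pd.DataFrame) -> "QpcrSignalTable":
        data = data.copy()
        data["signal"] = np.exp2(-data.pop("ct").astype(float))
        return cls(data)

    @classmethod
    def read_tsv(cls, path: str | Path, ct_scale: bool = False) -> "QpcrSignalTable":
        df = pd.read_csv(path, sep="\t")
        return cls.from_ct(df) if ct_scale else cls(df)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))


def _geomean(x: pd.Series) -> float:
    return float(np.exp(np.log(x.to_numpy(dtype=float)).mean()))


def cutrun_relative_signal(
    table: QpcrSignalTable,
    control_sample: str,
) -> pd.DataFrame:
    """Spike-in-normalised fold changes relative to a control sample.

    Per sample, target amplicon signal is divided by the genomic-background
    signal and then by the spike-in signal (geometric means when a role has
    several amplicons):

        rel(sample, amplicon) = (signal_target / signal_background) / signal_spike
        fold(sample, amplicon) = rel(sample, amplicon) / rel(control, amplicon)

    The control sample's own fold change is exactly 1. Multiplying one
    sample's spike-in signals by c divides that sample's rel and fold by c.
    """
    df = table.data
    if control_sample not in set(df["sample_id"]):
        raise ValueError(f"control sample {control_sample!r} not in table")
    rel_rows = []
    for sample, sub in df.groupby("sample_id", sort=False):
        bg = _geomean(sub.loc[sub["role"] == "genomic_background", "signal"])
        sp = _geomean(sub.loc[sub["role"] == "spike_in", "signal"])
        for row in sub.loc[sub["role"] == "target"].itertuples(index=False):
            rel_rows.append(
                {
                    "sample_id": sample,
                    "amplicon_id": row.amplicon_id,
                    "rel": (row.signal / bg) / sp,
                }
            )
    rel = pd.DataFrame(rel_rows)
    control = rel.loc[rel["sample_id"] == control_sample].set_index("amplicon_id")["rel"]
    missing = set(rel["amplicon_id"]) - set(control.index)
    if missing:
        raise ValueError(
            f"control sample lacks target amplicons: {sorted(missing)}"
        )
    rel["fold"] = rel["rel"] / rel["amplicon_id"].map(control).to_numpy()
    return rel
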