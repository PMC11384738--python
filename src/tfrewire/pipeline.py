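"""End-to-end orchestration: simulate -> categorise -> annotate -> enrich ->
bootstrap -> report.

The pipeline runs the stages in dependency order, writes every intermediate
table as TSV/BED under the output directory, and produces a
:class:`RunReport` whose numbers are all re-derivable from the written
stage outputs. One global seed is split deterministically into per-stage
streams, so identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    TargetGroups,
    assign_peaks_to_genes,
    assignments_to_frame,
    classify_promoter_fraction,
    derive_target_groups,
    read_genes_tsv,
    write_genes_tsv,
)
from .bootstrap import compare_target_groups, results_table
from .enrichment import build_background, gene_set_enrichment, region_overlap_enrichment
from .expression import ExpressionTable, filter_degs
from .intervals import (
    RegionSet,
    categorize_by_condition,
    consensus_peaks,
    drop_unplaced,
    filter_blacklist,
    read_bed,
    write_bed,
)
from .simulate import ENHANCER_CLASSES, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "bh_adjust"]


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration; message names the field."""


@dataclass
class PipelineConfig:
    """Inputs, thresholds and bootstrap settings of one pipeline run.

    In synthetic mode (``simulation`` set) all inputs are generated; in
    file mode the ``*_path`` fields must point at existing BED/TSV files.
    """

    outdir: str = "tfrewire_run"
    seed: int = 0
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    # file mode
    peaks_cond1_paths: tuple[str, ...] = ()
    peaks_cond2_paths: tuple[str, ...] = ()
    enhancer_paths: dict[str, str] = field(default_factory=dict)
    blacklist_path: str | None = None
    genes_path: str | None = None
    expression_path: str | None = None
    contrast: str | None = None
    # thresholds
    alpha: float = 0.05
    min_abs_log2fc: float = 0.5
    min_overlap_bp: int = 1
    consensus_min_frac: float = 0.5
    promoter_window: tuple[int, int] = (-3000, 3000)
    unplaced_prefix: str = "chrUn"
    # bootstrap
    bootstrap_draws: int = 30_000
    exclude_targets: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise PipelineConfigError("alpha must be in [0, 1]")
        if self.min_abs_log2fc < 0:
            raise PipelineConfigError("min_abs_log2fc must be >= 0")
        if not 0.0 < self.consensus_min_frac <= 1.0:
            raise PipelineConfigError("consensus_min_frac must be in (0, 1]")
        if self.min_overlap_bp < 1:
            raise PipelineConfigError("min_overlap_bp must be >= 1")
        if self.bootstrap_draws < 1:
            raise PipelineConfigError("bootstrap_draws must be >= 1")
        if self.simulation is None:
            for name in ("peaks_cond1_paths", "peaks_cond2_paths"):
                paths = getattr(self, name)
                if not paths:
                    raise PipelineConfigError(f"file mode requires {name}")
                for p in paths:
                    if not Path(p).exists():
                        raise PipelineConfigError(f"{name}: no such file: {p}")
            for name in ("genes_path", "expression_path"):
                p = getattr(self, name)
                if p is None:
                    raise PipelineConfigError(f"file mode requires {name}")
                if not Path(p).exists():
                    raise PipelineConfigError(f"{name}: no such file: {p}")
            for cls, p in self.enhancer_paths.items():
                if not Path(p).exists():
                    raise PipelineConfigError(f"enhancer_paths[{cls}]: no such file: {p}")
            if self.blacklist_path and not Path(self.blacklist_path).exists():
                raise PipelineConfigError(
                    f"blacklist_path: no such file: {self.blacklist_path}"
                )
        else:
            self.simulation.validate()

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with Path(path).open("w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        if raw.get("simulation") is not None:
            sim = dict(raw["simulation"])
            for key in ("chrom_names", "chrom_lengths"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimulationConfig(**sim)
        for key in ("peaks_cond1_paths", "peaks_cond2_paths", "promoter_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    """Per-stage record of one pipeline run; every number is re-derivable
    from the written stage outputs."""

    version: str
    seed: int
    parameters: dict
    peak_counts: dict
    target_group_sizes: dict
    promoter_fraction: float
    enrichment_rows: list[dict]
    deg_counts: dict
    bootstrap_rows: list[dict]
    output_files: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "RunReport":
        with Path(path).open() as fh:
            return cls(**json.load(fh))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow and write all outputs under ``outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def register(key: str, path: Path) -> Path:
        files[key] = str(path.relative_to(outdir))
        return path

    ss = np.random.SeedSequence(config.seed)
    stream_names = ("simulate", "expression", "bootstrap")
    streams = dict(zip(stream_names, ss.spawn(len(stream_names))))

    # --- stage: inputs -----------------------------------------------------
    t0 = _stage("inputs")
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(
            config.simulation,
            seed=int(np.random.default_rng(streams["simulate"]).integers(2**31 - 1)),
        )
        ds = simulate_dataset(sim_cfg)
        genes = list(ds.genes)
        enhancers = ds.enhancers
        blacklist = ds.blacklist
        reps1 = ds.replicate_peaks[list(ds.replicate_peaks)[0]]
        reps2 = ds.replicate_peaks[list(ds.replicate_peaks)[1]]
        cond1, cond2 = list(ds.replicate_peaks)[:2]
        contrast = sim_cfg.contrast
        expr: ExpressionTable | None = None  # generated after target groups
        write_genes_tsv(genes, register("genes", outdir / "genes.tsv"))
        for cls, rs in enhancers.items():
            write_bed(rs, register(f"enhancers_{cls}", outdir / f"enhancers_{cls}.bed"))
        write_bed(blacklist, register("blacklist", outdir / "blacklist.bed"))
        for cond, reps in ds.replicate_peaks.items():
            for i, rs in enumerate(reps, start=1):
                write_bed(rs, register(f"peaks_{cond}_rep{i}",
                                       outdir / f"peaks_{cond}_rep{i}.bed"))
    else:
        genes = read_genes_tsv(config.genes_path)
        enhancers = {
            cls: read_bed(path, label=cls)
            for cls, path in config.enhancer_paths.items()
        }
        blacklist = (
            read_bed(config.blacklist_path, label="blacklist")
            if config.blacklist_path
            else RegionSet(label="blacklist")
        )
        reps1 = [read_bed(p, label=f"cond1.rep{i + 1}")
                 for i, p in enumerate(config.peaks_cond1_paths)]
        reps2 = [read_bed(p, label=f"cond2.rep{i + 1}")
                 for i, p in enumerate(config.peaks_cond2_paths)]
        cond1, cond2 = "cond1", "cond2"
        expr = ExpressionTable.read_tsv(config.expression_path)
        contrast = config.contrast
    logger.info("inputs ready in %.2fs", time.perf_counter() - t0)

    # --- stage: peak processing -------------------------------------------
    t0 = _stage("peaks")

    def condition_peaks(reps: list[RegionSet], label: str) -> RegionSet:
        peaks = reps[0]
        if len(reps) > 1:
            peaks = consensus_peaks(peaks, reps[1],
                                    min_overlap_frac=config.consensus_min_frac)
        peaks = drop_unplaced(peaks, prefix=config.unplaced_prefix)
        peaks = filter_blacklist(peaks, blacklist)
        return peaks.relabel(label)

    peaks1 = condition_peaks(reps1, cond1)
    peaks2 = condition_peaks(reps2, cond2)
    categories = categorize_by_condition(peaks1, peaks2)
    counts = categories.counts()
    counts[f"n_{cond1}"] = len(peaks1)
    counts[f"n_{cond2}"] = len(peaks2)
    # count conservation re-checked at pipeline level
    assert counts["cond1_only"] + counts["shared_cond1_side"] == len(peaks1)
    assert counts["cond2_only"] + counts["shared_cond2_side"] == len(peaks2)
    write_bed(peaks1, register("peaks_cond1", outdir / f"peaks_{cond1}.bed"))
    write_bed(peaks2, register("peaks_cond2", outdir / f"peaks_{cond2}.bed"))
    write_bed(categories.cond1_only,
              register("cat_cond1_only", outdir / "category_cond1_only.bed"))
    write_bed(categories.cond2_only,
              register("cat_cond2_only", outdir / "category_cond2_only.bed"))
    write_bed(categories.shared, register("cat_shared", outdir / "category_shared.bed"))
    logger.info("peaks done in %.2fs", time.perf_counter() - t0)

    # --- stage: annotation -------------------------------------------------
    t0 = _stage("annotation")
    assign = {}
    for key, rs in (
        ("cond1_only", categories.cond1_only),
        ("cond2_only", categories.cond2_only),
        ("shared", categories.shared),
    ):
        assign[key], _un = assign_peaks_to_genes(
            rs, genes, promoter_window=config.promoter_window
        )
    all_assign = [a for lst in assign.values() for a in lst]
    promoter_fraction = (
        classify_promoter_fraction(all_assign) if all_assign else 0.0
    )
    groups = derive_target_groups(
        assign["cond1_only"], assign["cond2_only"], assign["shared"]
    )
    frames = []
    for key, lst in assign.items():
        df = assignments_to_frame(lst)
        df.insert(0, "category", key)
        frames.append(df)
    _write_tsv(pd.concat(frames, ignore_index=True),
               register("assignments", outdir / "assignments.tsv"))
    group_df = pd.DataFrame(
        [
            {"group": name, "gene_id": gid}
            for name, members in groups.as_dict().items()
            for gid in sorted(members)
        ]
    )
    _write_tsv(group_df, register("target_groups", outdir / "target_groups.tsv"))
    logger.info("annotation done in %.2fs", time.perf_counter() - t0)

    # --- stage: expression ---------------------------------------------------
    t0 = _stage("expression")
    if expr is None:
        from .simulate import generate_expression

        expr = generate_expression(
            genes, groups, sim_cfg, np.random.default_rng(streams["expression"])
        )
    expr.write_tsv(register("expression", outdir / "expression.tsv"))
    degs = filter_degs(expr, contrast, alpha=config.alpha,
                       min_abs_log2fc=config.min_abs_log2fc)
    deg_df = pd.DataFrame(
        {
            "gene_id": sorted(degs.genes),
            "direction": ["up" if g in degs.up else "down" for g in sorted(degs.genes)],
        }
    )
    _write_tsv(deg_df, register("degs", outdir / "degs.tsv"))
    logger.info("expression done in %.2fs", time.perf_counter() - t0)

    # --- stage: enrichment ---------------------------------------------------
    t0 = _stage("enrichment")
    universe = build_background(
        [enhancers[c] for c in ENHANCER_CLASSES if c in enhancers]
        + [peaks1, peaks2]
    )
    write_bed(universe.regions, register("background", outdir / "background.bed"))
    rows = []
    for peaks in (peaks1, peaks2):
        for cls in ENHANCER_CLASSES:
            if cls not in enhancers or len(enhancers[cls]) == 0:
                continue
            rows.append(
                region_overlap_enrichment(
                    peaks, enhancers[cls], universe, min_bp=config.min_overlap_bp
                ).as_dict()
            )
    gene_universe = {g.gene_id for g in genes}
    for name, members in groups.as_dict().items():
        if not members:
            continue
        res = gene_set_enrichment(
            members, degs.genes & gene_universe, gene_universe,
            labels=(f"targets_{name}", "degs"),
        )
        rows.append(res.as_dict())
    enr_df = pd.DataFrame(rows)
    enr_df["p_adjusted"] = bh_adjust(enr_df["p_value"].to_numpy())
    _write_tsv(enr_df, register("enrichment", outdir / "enrichment.tsv"))
    logger.info("enrichment done in %.2fs", time.perf_counter() - t0)

    # --- stage: bootstrap ----------------------------------------------------
    t0 = _stage("bootstrap")
    boot_groups = [
        (name, sorted(members))
        for name, members in groups.as_dict().items()
        if members
    ]
    boot_seed = int(np.random.default_rng(streams["bootstrap"]).integers(2**31 - 1))
    results = compare_target_groups(
        boot_groups,
        expr,
        B=config.bootstrap_draws,
        seed=boot_seed,
        contrast=contrast,
        exclude_targets=config.exclude_targets,
    )
    boot_df = results_table(results)
    boot_df["seed"] = boot_seed
    _write_tsv(boot_df, register("bootstrap", outdir / "bootstrap.tsv"))
    logger.info("bootstrap done in %.2fs", time.perf_counter() - t0)

    # --- report --------------------------------------------------------------
    report = RunReport(
        version=__version__,
        seed=config.seed,
        parameters={
            "alpha": config.alpha,
            "min_abs_log2fc": config.min_abs_log2fc,
            "min_overlap_bp": config.min_overlap_bp,
            "consensus_min_frac": config.consensus_min_frac,
            "promoter_window": list(config.promoter_window),
            "bootstrap_draws": config.bootstrap_draws,
            "mode": "synthetic" if config.simulation is not None else "files",
        },
        peak_counts=counts,
        target_group_sizes=groups.sizes(),
        promoter_fraction=promoter_fraction,
        enrichment_rows=[
            {k: (v if not isinstance(v, float) else float(v)) for k, v in r.items()}
            for r in enr_df.to_dict(orient="records")
        ],
        deg_counts={"total": len(degs.genes), "up": len(degs.up), "down": len(degs.down)},
        bootstrap_rows=boot_df.to_dict(orient="records"),
        output_files=files,
    )
    report.to_json(outdir / "report.json")
    files["report"] = "report.json"
    return report
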