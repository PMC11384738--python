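"""Synthetic genomes, enhancer classes, peak sets and expression tables.

The generator plants known structure so every downstream stage of the
pipeline can be verified against ground truth: enhancers of three classes
(state-A-specific, state-B-specific, shared) placed away from TSSs; peak
sets per condition whose enhancer-class composition follows a configured
probability vector (background peaks are rejection-sampled off enhancers,
so composition labels are exact); replicate peak sets as jittered copies;
and expression tables where each target group carries a planted mean
log2FC shift delta on top of Gaussian noise.

The defaults mirror the study design the pipeline is meant to emulate: two
conditions (a naive-state condition and an early-differentiation condition
24 h later), peak counts of 1,314 and 2,840, and a second-condition
composition putting 74% of peaks on formative-state (class-B + shared)
enhancers. All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .annotation import GeneModel, TargetGroups
from .expression import ExpressionTable
from .intervals import GenomicInterval, RegionSet

__all__ = [
    "GenomeSpec",
    "SimulationConfig",
    "PlacementError",
    "generate_genome",
    "generate_genes",
    "generate_enhancers",
    "generate_peaks",
    "generate_blacklist",
    "generate_expression",
    "generate_timecourse",
    "SyntheticDataset",
    "simulate_dataset",
]

ENHANCER_CLASSES = ("stateA_specific", "stateB_specific", "shared")
COMPOSITION_KEYS = ENHANCER_CLASSES + ("background",)


class PlacementError(RuntimeError):
    """Requested region count cannot be placed under the constraints."""


@dataclass(frozen=True)
class GenomeSpec:
    """Named chromosomes with positive lengths."""

    chrom_names: tuple[str, ...] = ("chr1",)
    chrom_lengths: tuple[int, ...] = (10_000_000,)

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)

    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


def _default_enhancer_counts() -> dict[str, int]:
    return {"stateA_specific": 250, "stateB_specific": 400, "shared": 250}


def _default_peak_counts() -> dict[str, int]:
    # condition peak totals mirroring the naive (2i) and 24 h (N24) TF peak
    # lists the pipeline is designed around
    return {"condA": 1314, "condB": 2840}


def _default_composition() -> dict[str, dict[str, float]]:
    # condB puts 74% of peaks on formative enhancers (class B + shared)
    return {
        "condA": {
            "stateA_specific": 0.45,
            "stateB_specific": 0.05,
            "shared": 0.30,
            "background": 0.20,
        },
        "condB": {
            "stateA_specific": 0.05,
            "stateB_specific": 0.55,
            "shared": 0.19,
            "background": 0.21,
        },
    }


def _default_effect_sizes() -> dict[str, float]:
    # naive-specific targets are planted down, later-condition targets up
    return {"cond1_specific": -0.5, "cond2_specific": 0.5, "shared": 0.0}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the emulated design as default."""

    chrom_names: tuple[str, ...] = ("chr1",)
    chrom_lengths: tuple[int, ...] = (10_000_000,)
    n_genes: int = 1200
    min_tss_spacing: int = 5000
    n_enhancers_per_class: dict[str, int] = field(default_factory=_default_enhancer_counts)
    enhancer_width: int = 1000
    tss_exclusion: int = 3000
    n_peaks_per_condition: dict[str, int] = field(default_factory=_default_peak_counts)
    enhancer_composition: dict[str, dict[str, float]] = field(
        default_factory=_default_composition
    )
    peak_width: int = 400
    replicate_jitter_sd: float = 20.0
    min_peak_width: int = 50
    n_blacklist: int = 10
    blacklist_width: int = 1000
    effect_sizes: dict[str, float] = field(default_factory=_default_effect_sizes)
    noise_sd: float = 0.5
    contrast: str = "condB_vs_condA"
    seed: int = 0

    def validate(self) -> None:
        GenomeSpec(self.chrom_names, self.chrom_lengths)  # reuse its checks
        if self.n_genes < 0 or self.min_tss_spacing < 0:
            raise ValueError("n_genes and min_tss_spacing must be >= 0")
        if any(v < 0 for v in self.n_enhancers_per_class.values()):
            raise ValueError("enhancer counts must be >= 0")
        if set(self.n_enhancers_per_class) - set(ENHANCER_CLASSES):
            raise ValueError(f"enhancer classes must be among {ENHANCER_CLASSES}")
        if any(v < 0 for v in self.n_peaks_per_condition.values()):
            raise ValueError("peak counts must be >= 0")
        for cond, comp in self.enhancer_composition.items():
            if set(comp) != set(COMPOSITION_KEYS):
                raise ValueError(
                    f"composition for {cond!r} must have keys {COMPOSITION_KEYS}"
                )
            if any(p < 0 for p in comp.values()):
                raise ValueError("composition probabilities must be >= 0")
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"composition for {cond!r} must sum to 1")
        if self.peak_width <= 0 or self.enhancer_width <= 0:
            raise ValueError("widths must be positive")
        if self.replicate_jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        for key in ("chrom_names", "chrom_lengths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def generate_genome(config: SimulationConfig) -> GenomeSpec:
    """The genome implied by the config (deterministic; default chr1, 10 Mb)."""
    config.validate()
    return GenomeSpec(config.chrom_names, config.chrom_lengths)


def _allocate(n: int, weights: Sequence[int]) -> list[int]:
    """Deterministic largest-remainder allocation of n items by weight."""
    total = sum(weights)
    raw = [n * w / total for w in weights]
    base = [math.floor(x) for x in raw]
    rem = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - base[i], -i), reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


def generate_genes(
    genome: GenomeSpec,
    n_genes: int,
    min_spacing: int,
    seed: int | np.random.Generator = 0,
) -> list[GeneModel]:
    """Genes with pairwise TSS spacing >= ``min_spacing`` and random strands.

    Genes are split across chromosomes proportionally to length; on each
    chromosome, TSSs are a sorted uniform sample stretched onto the spacing
    grid, which guarantees the spacing bound exactly. Gene ids are
    zero-padded and therefore unique and sortable.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_genes == 0:
        return []
    counts = _allocate(n_genes, genome.chrom_lengths)
    genes: list[GeneModel] = []
    gid = 0
    pad = max(5, len(str(n_genes)))
    for chrom, length, n in zip(genome.chrom_names, genome.chrom_lengths, counts):
        if n == 0:
            continue
        span = (n - 1) * min_spacing
        slack = length - 1 - span
        if slack < 0:
            raise PlacementError(
                f"cannot place {n} genes with spacing {min_spacing} on "
                f"{chrom} (length {length})"
            )
        offsets = np.sort(rng.integers(0, slack + 1, size=n))
        strands = rng.choice(["+", "-"], size=n)
        for i in range(n):
            tss = int(offsets[i] + i * min_spacing)
            genes.append(GeneModel(f"g{gid:0{pad}d}", chrom, str(strands[i]), tss))
            gid += 1
    return genes


def _blocked_lookup(blocked: RegionSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by = blocked.by_chrom()
    return {
        c: (np.array([iv.start for iv in ivs]), np.array([iv.end for iv in ivs]))
        for c, ivs in by.items()
    }


def _hits_blocked(
    chrom: str, start: int, end: int,
    lookup: Mapping[str, tuple[np.ndarray, np.ndarray]],
) -> bool:
    entry = lookup.get(chrom)
    if entry is None:
        return False
    starts, ends = entry
    j = int(np.searchsorted(starts, start, side="right")) - 1
    if j >= 0 and ends[j] > start:
        return True
    j += 1
    return j < len(starts) and starts[j] < end


def generate_enhancers(
    genome: GenomeSpec,
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    max_tries_per_region: int = 1000,
) -> dict[str, RegionSet]:
    """Non-overlapping enhancers per class, away from every TSS.

    No enhancer overlaps another (across classes) and none lies within the
    TSS-exclusion window (default 3 kb) of any TSS. Placement is rejection
    sampling with a bounded retry budget; exhausting it raises
    :class:`PlacementError`.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from .intervals import merge

    width = config.enhancer_width
    excl = config.tss_exclusion
    tss_windows = [
        GenomicInterval(g.chrom, max(0, g.tss - excl), g.tss + excl + 1)
        for g in genes
    ]
    blocked = merge(tss_windows) if tss_windows else RegionSet()
    lookup = _blocked_lookup(blocked)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}

    lengths = genome.lengths()
    chrom_arr = np.array(genome.chrom_names)
    chrom_p = np.array(genome.chrom_lengths, dtype=float)
    chrom_p /= chrom_p.sum()

    out: dict[str, RegionSet] = {}
    for cls in ENHANCER_CLASSES:
        count = config.n_enhancers_per_class.get(cls, 0)
        ivs: list[GenomicInterval] = []
        for i in range(count):
            ok = False
            for _ in range(max_tries_per_region):
                chrom = str(rng.choice(chrom_arr, p=chrom_p))
                hi = lengths[chrom] - width
                if hi < 0:
                    continue
                start = int(rng.integers(0, hi + 1))
                end = start + width
                if _hits_blocked(chrom, start, end, lookup):
                    continue
                if any(start < e and s < end for s, e in placed[chrom]):
                    continue
                placed[chrom].append((start, end))
                ivs.append(
                    GenomicInterval(chrom, start, end, name=f"{cls}.{i:04d}")
                )
                ok = True
                break
            if not ok:
                raise PlacementError(
                    f"could not place enhancer {i} of class {cls!r} after "
                    f"{max_tries_per_region} tries"
                )
        out[cls] = RegionSet(label=cls, intervals=tuple(ivs))
    return out


def generate_blacklist(
    genome: GenomeSpec,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> RegionSet:
    """Random artefact-prone regions to exercise blacklist filtering."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width = config.blacklist_width
    ivs = []
    chrom_p = np.array(genome.chrom_lengths, dtype=float)
    chrom_p /= chrom_p.sum()
    for i in range(config.n_blacklist):
        chrom = str(rng.choice(np.array(genome.chrom_names), p=chrom_p))
        hi = genome.lengths()[chrom] - width
        start = int(rng.integers(0, max(1, hi + 1)))
        ivs.append(GenomicInterval(chrom, start, start + width, name=f"bl.{i:03d}"))
    return RegionSet(label="blacklist", intervals=tuple(ivs))


def _jitter_interval(
    iv: GenomicInterval,
    sd: float,
    min_width: int,
    chrom_len: int,
    rng: np.random.Generator,
) -> GenomicInterval:
    """Gaussian end jitter, truncated at 6 sd, with width and bound clamps."""
    bound = 6.0 * sd
    ds = int(round(float(np.clip(rng.normal(0.0, sd), -bound, bound)))) if sd > 0 else 0
    de = int(round(float(np.clip(rng.normal(0.0, sd), -bound, bound)))) if sd > 0 else 0
    start, end = iv.start + ds, iv.end + de
    if start > end:
        start, end = end, start
    if end - start < min_width:
        centre = (start + end) // 2
        start = centre - min_width // 2
        end = start + min_width
    start = max(0, start)
    end = min(chrom_len, max(end, start + 1))
    if start >= end:  # degenerate clip at chromosome edge
        start, end = max(0, end - min_width), end if end > 0 else min_width
    return GenomicInterval(iv.chrom, start, end, name=iv.name,
                           score=iv.score, strand=iv.strand)


def generate_peaks(
    genome: GenomeSpec,
    enhancers: Mapping[str, RegionSet],
    config: SimulationConfig,
    condition_label: str,
    n_replicates: int = 2,
    seed: int | np.random.Generator = 0,
) -> list[RegionSet]:
    """Replicate peak sets with an exact planted enhancer-class composition.

    Each base peak samples a composition label; class peaks are centred at
    a uniform position inside a uniformly chosen enhancer of that class
    (guaranteeing >= 1 bp overlap even after jitter, since jitter is
    truncated at 6 sd < peak_width / 2); background peaks are
    rejection-resampled until they clear every enhancer by a 6-sd safety
    margin, so they never overlap any enhancer, jittered or not.
    Replicates are independently jittered copies of the base peaks. The
    peak name records the planted label: ``<condition>.<i>.<class>``.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = config.enhancer_composition.get(condition_label)
    if comp is None:
        raise ValueError(f"no composition configured for {condition_label!r}")
    n_peaks = config.n_peaks_per_condition.get(condition_label)
    if n_peaks is None:
        raise ValueError(f"no peak count configured for {condition_label!r}")
    probs = np.array([comp[c] for c in COMPOSITION_KEYS])
    for cls in ENHANCER_CLASSES:
        if comp[cls] > 0 and len(enhancers.get(cls, RegionSet())) == 0:
            raise ValueError(
                f"composition gives probability {comp[cls]} to empty enhancer "
                f"class {cls!r}"
            )
    width = config.peak_width
    half = width // 2
    margin = int(math.ceil(6.0 * config.replicate_jitter_sd)) + 1
    from .intervals import merge

    all_enh = merge(
        [iv for cls in ENHANCER_CLASSES for iv in enhancers.get(cls, RegionSet())]
    )
    # pad enhancers by the jitter margin for background rejection
    padded = RegionSet(
        intervals=tuple(
            GenomicInterval(iv.chrom, max(0, iv.start - margin), iv.end + margin)
            for iv in all_enh
        )
    )
    pad_lookup = _blocked_lookup(merge(padded))
    lengths = genome.lengths()
    chrom_arr = np.array(genome.chrom_names)
    chrom_p = np.array(genome.chrom_lengths, dtype=float)
    chrom_p /= chrom_p.sum()

    labels = rng.choice(len(COMPOSITION_KEYS), size=n_peaks, p=probs)
    base: list[GenomicInterval] = []
    for i, lab in enumerate(labels):
        key = COMPOSITION_KEYS[int(lab)]
        if key == "background":
            for _ in range(100_000):
                chrom = str(rng.choice(chrom_arr, p=chrom_p))
                hi = lengths[chrom] - width - margin
                if hi <= margin:
                    continue
                start = int(rng.integers(margin, hi + 1))
                if not _hits_blocked(chrom, start - margin, start + width + margin,
                                     pad_lookup):
                    break
            else:
                raise PlacementError("cannot place background peak off enhancers")
            end = start + width
            chrom_name = chrom
        else:
            enh_set = enhancers[key]
            enh = enh_set[int(rng.integers(0, len(enh_set)))]
            centre = int(rng.integers(enh.start, enh.end))
            start = max(0, centre - half)
            end = min(lengths[enh.chrom], start + width)
            start = max(0, end - width)
            chrom_name = enh.chrom
        base.append(
            GenomicInterval(chrom_name, start, end,
                            name=f"{condition_label}.{i:05d}.{key}")
        )
    reps = []
    for r in range(n_replicates):
        ivs = tuple(
            _jitter_interval(iv, config.replicate_jitter_sd, config.min_peak_width,
                             lengths[iv.chrom], rng)
            for iv in base
        )
        reps.append(RegionSet(label=f"{condition_label}.rep{r + 1}", intervals=ivs))
    return reps


def generate_expression(
    genes: Sequence[GeneModel],
    target_groups: TargetGroups,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> ExpressionTable:
    """Per-gene log2FC with planted group shifts plus Gaussian noise.

    log2FC = delta(group) + Normal(0, noise_sd), delta = 0 for non-targets.
    Adjusted p-values come from a one-sample z-test of each log2FC against
    the known noise sd, Benjamini-Hochberg corrected — a stand-in with the
    same threshold semantics as a count-based differential test.
    """
    from scipy import stats as sps
    from statsmodels.stats.multitest import multipletests
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    id_set = set(gene_ids)
    delta = np.zeros(len(gene_ids))
    for group, members in target_groups.as_dict().items():
        unknown = members - id_set
        if unknown:
            raise ValueError(
                f"group {group!r} contains unknown genes (e.g. {sorted(unknown)[:3]})"
            )
        shift = config.effect_sizes.get(group, 0.0)
        idx = [i for i, g in enumerate(gene_ids) if g in members]
        delta[idx] = shift
    noise = rng.normal(0.0, config.noise_sd, size=len(gene_ids)) \
        if config.noise_sd > 0 else np.zeros(len(gene_ids))
    lfc = delta + noise
    if config.noise_sd > 0:
        z = lfc / config.noise_sd
        p = 2.0 * sps.norm.sf(np.abs(z))
    else:
        p = np.where(lfc != 0.0, 0.0, 1.0)
    padj = multipletests(p, method="fdr_bh")[1] if len(p) else p
    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            f"log2fc_{config.contrast}": lfc,
            f"padj_{config.contrast}": padj,
        }
    )
    return ExpressionTable(df)


def generate_timecourse(
    genes: Sequence[GeneModel],
    target_groups: TargetGroups,
    config: SimulationConfig,
    n_timepoints: int = 17,
    seed: int | np.random.Generator = 0,
) -> ExpressionTable:
    """Optional TPM time course with monotone planted kinetics per group.

    Group trajectories interpolate from a baseline towards
    baseline * 2**delta across the timepoints (down for negative delta, up
    for positive, flat for zero), with multiplicative log-normal noise —
    enough structure to exercise trajectory summaries, nothing more.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    import pandas as pd

    gene_ids = [g.gene_id for g in genes]
    id_set = set(gene_ids)
    delta = np.zeros(len(gene_ids))
    for group, members in target_groups.as_dict().items():
        unknown = members - id_set
        if unknown:
            raise ValueError(f"group {group!r} contains unknown genes")
        idx = [i for i, g in enumerate(gene_ids) if g in members]
        delta[idx] = config.effect_sizes.get(group, 0.0)
    t = np.linspace(0.0, 1.0, n_timepoints)
    baseline = rng.lognormal(mean=3.0, sigma=1.0, size=len(gene_ids))
    traj = baseline[:, None] * np.exp2(delta[:, None] * t[None, :])
    noise = rng.lognormal(mean=0.0, sigma=0.1, size=traj.shape)
    tpm = traj * noise
    cols = {f"tpm_t{i * 2}": tpm[:, i] for i in range(n_timepoints)}
    return ExpressionTable(pd.DataFrame({"gene_id": gene_ids, **cols}))


@dataclass(frozen=True)
class SyntheticDataset:
    """All stage inputs of one synthetic study, bundled."""

    genome: GenomeSpec
    genes: tuple[GeneModel, ...]
    enhancers: dict[str, RegionSet]
    blacklist: RegionSet
    replicate_peaks: dict[str, list[RegionSet]]
    config: SimulationConfig

    @property
    def conditions(self) -> list[str]:
        return list(self.replicate_peaks)


def simulate_dataset(config: SimulationConfig, n_replicates: int = 2) -> SyntheticDataset:
    """Generate genome, genes, enhancers, blacklist and replicate peak sets.

    Per-stage random streams are split deterministically from
    ``config.seed``, so the whole dataset is a pure function of the config.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    keys = ("genes", "enhancers", "blacklist", "peaks")
    streams = dict(zip(keys, ss.spawn(len(keys))))
    genome = generate_genome(config)
    genes = generate_genes(
        genome, config.n_genes, config.min_tss_spacing,
        np.random.default_rng(streams["genes"]),
    )
    enhancers = generate_enhancers(
        genome, genes, config, np.random.default_rng(streams["enhancers"])
    )
    blacklist = generate_blacklist(
        genome, config, np.random.default_rng(streams["blacklist"])
    )
    peak_rng = np.random.default_rng(streams["peaks"])
    replicate_peaks = {
        cond: generate_peaks(genome, enhancers, config, cond,
                             n_replicates=n_replicates, seed=peak_rng)
        for cond in config.n_peaks_per_condition
    }
    return SyntheticDataset(
        genome=genome,
        genes=tuple(genes),
        enhancers=enhancers,
        blacklist=blacklist,
        replicate_peaks=replicate_peaks,
        config=config,
    )
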