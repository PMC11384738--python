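# Methods

`tfrewire` analyses how a transcription factor's (TF's) genomic binding
repertoire changes between two cellular conditions and what that change does
to transcription. The motivating setting is the exit of mouse embryonic stem
cells from naive pluripotency: a TF binds one set of enhancers in the naive
state ("condition 1") and a largely different, larger set 24 h into
differentiation ("condition 2"), and the genes near those sites respond in
opposite directions. The package provides the full integrative workflow as a
tested library: peak-set algebra, condition categorisation, peak-to-gene
annotation, background-constrained overlap enrichment, and a size-matched
bootstrap null for group-level expression effects — plus a synthetic-data
generator that plants every quantity the downstream stages are supposed to
recover.

## Interval model and peak-set algebra

All coordinates are 0-based, half-open (the BED convention); GTF-style
inputs must be converted at the boundary. The operations and their exact
dialect:

- **merge** (`max_gap = 0` default): overlapping *and book-ended* intervals
  merge ([0,100) + [100,200) → [0,200)). Merging is idempotent,
  order-invariant, and preserves the set of covered bases at gap 0.
- **overlap** requires ≥ 1 bp by default (`min_bp`), optionally a minimum
  fraction of the reference-side interval (`min_frac`, side configurable).
- **blacklist filtering** removes any peak overlapping an artefact region by
  ≥ 1 bp, mirroring standard ENCODE-blacklist practice; peaks on unplaced
  contigs (name prefix `chrUn`, configurable) can be dropped the same way.
- **consensus peaks** across replicates: a reference-replicate peak is
  retained iff some peak of the other replicate covers at least
  `min_overlap_frac` (default 0.5, threshold inclusive) of *its* length.
  The denominator is deliberately the reference side — the common "at least
  50% overlap" phrasing does not name one — and a reciprocal mode is
  available.
- **condition categorisation**: a peak overlapping (≥ 1 bp) any peak of the
  other condition is "shared"; shared regions are reported as merged unions
  of mutually overlapping peaks, while per-side shared counts refer to the
  original peaks so that count conservation holds exactly on each side:
  n(cond-only) + n(shared, that side) = n(condition peaks). Both the
  per-side counts and the merged-region count are exposed, since published
  three-way decompositions can be stated either way.

All of these are verified against per-base and all-pairs brute-force
oracles on random toy genomes (≤ 10 kb), and the merge dialect additionally
against `bedtools merge`.

## Peak-to-gene annotation and target groups

Each peak is assigned to the gene with the nearest TSS on its chromosome.
The signed distance is 0 if the peak spans the TSS, positive if the peak
lies downstream of the TSS in the gene's orientation, negative upstream;
ties in absolute distance go to the lexicographically smallest gene id. A
peak is a *promoter* peak if its signed distance falls within the promoter
window, default (−3000, +3000) bp — the conventional default of nearest-TSS
ChIP annotation tools. There is no maximum assignment distance by default
(an optional cap exists), matching the observation that gene-group sizes
track peak counts in this kind of data.

Gene-level **target groups** are derived from the per-category assignments:
genes hit by shared-category peaks are shared targets; genes hit by both a
condition-1-only and a condition-2-only peak are *also* counted as shared
(they are bound in both conditions, at different sites) — this resolution
rule is a documented choice, togglable to `drop`, because published
pipelines rarely state it. The three groups are disjoint by construction
and their union is the set of all bound genes.

## Overlap enrichment against an explicit background

Enrichment questions ("do condition-2 peaks concentrate on formative-state
enhancers?") are answered with an upper-tail hypergeometric test whose urn
is an explicit **background universe**: the merged, non-overlapping union
of every region that could have been hit (in the emulated study: all
detected open-chromatin regions plus the enhancer lists). Counting is done
in universe-region space — N universe regions, K overlapped by set A, n by
set B, k by both — so the urn stays well-defined even when one raw peak
touches several universe regions. Overlap *fractions* are reported on raw
peak counts (the Venn-style percentage of A peaks overlapping any B
interval) and are therefore universe-independent; the p-value is not, and a
test documents both facts. The tail probability comes from
`scipy.stats.hypergeom.sf`, which is computed stably; it agrees with exact
rational enumeration to ≤ 1e-10 relative error over the complete parameter
grid N ≤ 30 (measured: ~7e-16). Depletion (lower tail) is available behind
a flag. No multiple-testing correction is applied inside the module; the
pipeline layer provides Benjamini–Hochberg adjustment
(`statsmodels.stats.multitest`) and applies it across the enrichment table
it writes.

The same statistic serves gene-set enrichment (query vs target within a
gene universe, e.g. bound genes vs DEGs among all detected genes).

## Size-matched bootstrap for group effect sizes

To ask whether a target group's mean log2 fold change exceeds chance, the
package draws B (default 30,000) random gene groups of the same size,
without replacement within a draw and independently across draws, from the
pool of all detected genes (targets included by default; an
`exclude_targets` flag exists). The draw statistic is the unweighted mean
log2FC; genes with missing log2FC are dropped from pool and targets with a
logged warning. The empirical p-value uses the add-one permutation
convention, p = (1 + #{null means at least as extreme}) / (B + 1), so it is
never 0 and its floor at B = 30,000 is ≈ 3.3e-5.

**Direction.** By default (`direction="auto"`) the tail is taken in the
direction of the observed mean's sign, which is how such effect-size nulls
are usually reported alongside figures. That choice is post hoc: under a
true null it yields p ~ Uniform(0, 0.5) and a rejection rate of ~2α at
threshold α. A one-sided test is calibrated only under a pre-specified
alternative, so calibration studies (and any user who wants nominal type-I
control) should pass `direction="greater"` or `"less"` explicitly; the
package's own calibration tests do exactly that and recover a 5% ± 2%
rejection rate at α = 0.05.

An exhaustive **exact mode** enumerates every size-matched subset when
C(pool, group) ≤ 1e6 and is the sampler's oracle: on the worked pool
{1,2,3,4,5} with target {4,5} the enumerated tail is exactly 1/10, and the
sampler agrees with enumeration within 3 Monte-Carlo standard deviations.
The sampler itself draws via random-key order statistics (argpartition of
uniform keys, chunked), which is exactly uniform sampling without
replacement and vectorises well.

`compare_target_groups` runs several groups against a shared pool with
per-group matched sizes, splitting independent random streams off one
master seed (`numpy` `SeedSequence.spawn`), and reports a ranking by
absolute observed effect.

## Expression-side statistics

- **DEG filtering**: adjusted p ≤ α (default 0.05) AND |log2FC| ≥ 0.5,
  thresholds inclusive; up/down subsets split by sign. Relaxing either
  threshold can only grow the set.
- **Rank tests**: Wilcoxon rank-sum and signed-rank wrap
  `scipy.stats.mannwhitneyu` / `wilcoxon` with a documented switch point:
  exact enumeration when the input is tie-free and small (min(n,m) ≤ 8,
  resp. n ≤ 15 after dropping zero differences), otherwise the normal
  approximation with tie and continuity corrections. Zero paired
  differences are dropped (standard convention); all-zero input is an
  error. Both match exhaustive enumeration on tie-free inputs.
- **Time-course summaries**: each gene's TPM trajectory is z-normalised
  across timepoints (constant genes map to all-zero, by convention), and
  the group summary is the per-timepoint mean ± sd of normalised
  trajectories.
- **CUT&RUN qPCR quantification** follows the spike-in double
  normalisation: rel = (target signal / genomic-background signal) /
  spike-in signal per sample (geometric means when a role has several
  amplicons), then fold = rel / rel(control sample). The control's own
  fold is exactly 1 by construction, and scaling one sample's spike-in
  signals by c divides that sample's rel and fold by c — both identities
  are asserted on random tables. Signals are linear-scale; a Ct mode
  converts via 2^(−Ct) first, since qPCR instruments report Ct.

## Synthetic data: what it emulates and what it does not

The generator is first-class, tested code; its defaults *are* the study
design the pipeline emulates:

| parameter | default | rationale |
|---|---|---|
| genome | 1 chromosome, 10 Mb | interval logic without multi-chromosome bookkeeping; multi-chromosome via config |
| genes | 1,200, TSS spacing ≥ 5 kb | densest grid that still leaves room for off-promoter enhancers under the 3 kb TSS exclusion |
| enhancers | 250 / 400 / 250 per class, 1 kb wide, ≥ 3 kb from any TSS, mutually non-overlapping | three enhancer classes (state-A-specific, state-B-specific, shared) as overlap targets |
| peaks | 1,314 (cond A) and 2,840 (cond B), 400 bp | the two conditions' TF peak-list sizes in the emulated study |
| composition, cond B | 0.05 / 0.55 / 0.19 / 0.21 over (A, B, shared, background) | puts 74% of condition-B peaks on formative (class-B + shared) enhancers, the study's headline fraction |
| composition, cond A | 0.45 / 0.05 / 0.30 / 0.20 | naive-state peaks concentrate on naive-specific and shared enhancers |
| replicate jitter | Gaussian, sd 20 bp, truncated at ±6 sd | replicates as noisy copies; truncation makes composition labels exact guarantees (see below) |
| planted effects δ | −0.5 / +0.5 / 0 for cond-1-specific / cond-2-specific / shared targets | naive-specific targets down, later targets up, shared without consistent direction |
| log2FC noise | sd 0.5 | per-gene spread around the planted shift |

Composition labels are *exact*, not approximate: class peaks are centred
inside a uniformly chosen enhancer of the sampled class (overlap guaranteed
even after jitter because 6·sd < peak_width/2), and background peaks are
rejection-resampled until they clear every enhancer by a 6·sd safety
margin. Synthetic DE tables get adjusted p-values from a one-sample z-test
of each log2FC against the known noise sd with Benjamini–Hochberg
correction — a stand-in with the right threshold semantics, not a model of
count noise. The time-course generator produces monotone group kinetics
with log-normal noise, enough to exercise trajectory summaries.

Every generator is a pure function of (config, seed). What the synthetic
data does **not** have: reads, nucleotide sequence, signal tracks,
replicate-level count variability, peak-width/score distributions of real
callers, chromatin-domain structure, or correlated gene expression. Tests
passing on it therefore demonstrate the correctness of the algebra and the
statistics under planted truth — not robustness to the messiness of real
sequencing data.

## Pipeline and reproducibility

`run_pipeline` executes simulate (or load files) → replicate consensus →
blacklist filter → categorise → annotate → target groups → expression →
DEGs → enrichment (with BH-adjusted column) → bootstrap, writing every
intermediate as BED/TSV plus a JSON report whose every number is
re-derivable from the written files (a test re-derives them). One global
seed is split deterministically into per-stage streams; identical config +
seed gives byte-identical outputs (asserted at file level). Count
conservation is re-checked at the pipeline level. The CLI is a thin layer
over these functions; `--threads` is accepted for interface stability and
results are independent of it.

## Problem sizes used in the verification runs

The shipped verification suite exercises: the full hypergeometric grid
N ≤ 30 against exact rational arithmetic; bootstrap calibration and power
with a 5,000-gene pool, group size 100, noise sd 0.5, B = 2,000 over 500
simulations per condition; the study-sized bootstrap design (groups of 249
and 889 shifted by ∓0.5 plus a random 486-gene control) on a 15,000-gene
pool — a realistic detected-transcriptome size, which keeps the planted
groups a small fraction of the pool — at B = 30,000; composition recovery
with 2,000 peaks planted 74% on one enhancer class; 100 random toy-genome
instances for the interval oracles; and two full pipeline runs for
byte-level determinism. These sizes keep the whole suite in the
few-minutes range on one CPU.

## Known limitations

- The delta=0 "control" in the scaled design must be a *random* gene set to
  be exchangeable with the bootstrap null; a disjoint block of unshifted
  genes sits systematically below the pool mean whenever the planted shifts
  are asymmetric (the pool mean moves, the block does not). The package
  exposes both readings; the verification uses the exchangeable one.
- Nearest-TSS annotation ignores gene bodies, isoforms and annotation
  hierarchies; promoter classification is a window, not a state model.
- The hypergeometric model treats universe regions as exchangeable urns;
  region length, GC and mappability biases that motivate shuffling-based
  nulls are out of scope.
- The bootstrap matches groups on size only, not on expression level or
  gene length.
- DE tables are consumed, not produced; no count-level modelling.
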