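# tfrewire

Condition-specific transcription-factor target groups from peak sets —
interval algebra, background-constrained overlap enrichment, and a
size-matched bootstrap null for transcriptional effect sizes.

## The problem

A TF that shuttles into the nucleus during a cell-state transition binds
different enhancers before and after the switch. Given peak lists for the
two conditions (e.g. naive pluripotency vs 24 h into differentiation),
enhancer class annotations, and a differential-expression table, the
questions are always the same:

1. Which peaks are specific to condition 1, specific to condition 2, or
   shared? (`categorize_by_condition`, with exact per-side count
   conservation: n(cond-only) + n(shared, that side) = n(condition peaks).)
2. Do the peaks concentrate on a particular enhancer class more than chance
   allows? This is an upper-tail hypergeometric test on an **explicit
   background universe** of regions — the urn is everything that could have
   been hit, e.g. all open-chromatin regions merged with the enhancer
   lists (`region_overlap_enrichment`).
3. Which genes do the peak categories target (`assign_peaks_to_genes`,
   nearest TSS, signed distances, promoter window), and how do those
   target groups respond transcriptionally? The effect-size question is
   answered with a **size-matched bootstrap**: draw B = 30,000 random gene
   groups of the same size from all detected genes and report the
   one-sided empirical probability

   p = (1 + #{draws with mean log2FC as or more extreme}) / (B + 1),

   which is never zero and has floor 1/(B+1) (`bootstrap_effect_size`,
   `compare_target_groups`, plus an exhaustive exact mode for small pools).

Supporting utilities cover DEG filtering (padj ≤ 0.05, |log2FC| ≥ 0.5,
inclusive), Wilcoxon rank-sum/signed-rank tests with exact small-sample
enumeration, time-course trajectory summaries, and spike-in-normalised
CUT&RUN qPCR quantification. A synthetic-data module generates toy
genomes, enhancer classes, replicate peak sets with *exact* planted
composition and expression tables with planted group shifts, so every
stage is verifiable against ground truth without any downloads. See
`docs/methods.md` for the model details and conventions.

## Worked example

```sh
python examples/03_bootstrap_effect_size.py
```

plants a 249-gene group shifted by −0.5 log2FC and an 889-gene group
shifted by +0.5 in a 15,000-gene transcriptome, plus a random 486-gene
control, and prints:

```
                     label  size  observed_mean  p_empirical direction     B  rank_by_abs_effect
    naive_specific_targets   249      -0.575180     0.000033      less 30000                   1
formative_specific_targets   889       0.471838     0.000033   greater 30000                   2
            random_control   486       0.011186     0.600947   greater 30000                   3
```

Both planted groups recover their shift and sit at the empirical floor
1/(B+1) ≈ 3.3e-5 — no random size-matched gene group comes close — while
the random control is indistinguishable from the null. The other examples
cover simulation + peak categorisation (`01`), planted-composition
enrichment recovering a 74% enhancer overlap (`02`), expression statistics
and CUT&RUN normalisation (`04`), and the end-to-end pipeline (`05`).

The pipeline also has a thin CLI:

```sh
tfrewire run --seed 7 --outdir my_run      # end-to-end on synthetic data
tfrewire simulate --outdir sim             # just the synthetic dataset
tfrewire enrich --set-a peaks.bed --set-b enhancers.bed \
    --background atac.bed --background enhancers.bed
```

Identical config + seed reproduces every output byte for byte.

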