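"""Run the whole pipeline on synthetic data and inspect the report.

simulate -> consensus/blacklist -> categorise -> annotate -> target groups
-> enrichment -> DEGs -> size-matched bootstrap, all from one config and
one seed. Rerunning with the same config and seed reproduces every output
byte for byte.
"""

from tfrewire import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="example_run", seed=7, bootstrap_draws=10_000)
report = run_pipeline(cfg)

print("peak categories:", report.peak_counts)
print("target groups:", report.target_group_sizes)
print(f"promoter fraction: {report.promoter_fraction:.2f} "
      "(TF peaks sit mostly outside promoters)")
print("DEGs:", report.deg_counts)
print("\nbootstrap results:")
for row in report.bootstrap_rows:
    print(f"  {row['label']}: size {row['size']}, "
          f"mean log2FC {row['observed_mean']:+.3f}, "
          f"p={row['p_empirical']:.2g} ({row['direction']})")
print(f"\nall outputs under {cfg.outdir}/ (see report.json)")
# The naive-specific target group comes out down-regulated and the
# formative-specific group up-regulated — the planted regulatory rewiring —
# while the shared group shows no consistent direction.
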