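"""DEG filtering, rank tests and CUT&RUN spike-in normalisation.

Small worked inputs for the expression-side utilities: the inclusive DEG
thresholds, a Wilcoxon rank-sum comparison of two gene groups, and the
double-normalised qPCR fold changes used for spike-in-calibrated CUT&RUN.
"""

import pandas as pd

from tfrewire import (
    ExpressionTable,
    QpcrSignalTable,
    cutrun_relative_signal,
    filter_degs,
    rank_sum_test,
)

expr = ExpressionTable(pd.DataFrame({
    "gene_id": [f"g{i}" for i in range(6)],
    "log2fc_n24_vs_naive": [1.0, 0.4, -0.6, 2.0, -0.5, 0.0],
    "padj_n24_vs_naive": [0.01, 0.01, 0.04, 0.20, 0.05, 1.0],
}))
degs = filter_degs(expr, alpha=0.05, min_abs_log2fc=0.5)
print(f"DEGs (padj<=0.05, |log2FC|>=0.5): {sorted(degs.genes)} "
      f"(up {sorted(degs.up)}, down {sorted(degs.down)})")
# boundary genes pass: thresholds are inclusive

targets = [0.9, 1.4, 0.7, 1.1, 0.8]
non_targets = [0.1, -0.2, 0.3, 0.0, -0.1, 0.2]
u, p = rank_sum_test(targets, non_targets)
print(f"rank-sum U={u:.0f}, p={p:.4f}  (targets upregulated vs non-targets)")

qpcr = QpcrSignalTable(pd.DataFrame(
    [
        ("siScr", "enh1", "target", 4.0),
        ("siScr", "bg", "genomic_background", 2.0),
        ("siScr", "spk", "spike_in", 1.0),
        ("siTF", "enh1", "target", 2.0),
        ("siTF", "bg", "genomic_background", 2.0),
        ("siTF", "spk", "spike_in", 1.0),
    ],
    columns=["sample_id", "amplicon_id", "role", "signal"],
))
res = cutrun_relative_signal(qpcr, "siScr")
print(res.to_string(index=False))
# fold = (target/background)/spike, relative to the control sample: the
# knockdown sample shows half the control's acetylation signal at enh1.
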