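"""Score the transcriptional impact of gene groups with a size-matched null.

Builds an expression table for 15,000 detected genes in which one group of
249 genes is shifted down by 0.5 log2FC and one group of 889 genes up by
0.5, then compares each group's mean log2FC against 30,000 random gene
groups of the same size.
"""

import numpy as np

from tfrewire import GenomeSpec, SimulationConfig, TargetGroups, compare_target_groups
from tfrewire.bootstrap import results_table
from tfrewire.simulate import generate_expression, generate_genes

genome = GenomeSpec(("chr1",), (10_000_000,))
genes = generate_genes(genome, 15_000, 500, seed=7)
ids = [g.gene_id for g in genes]
groups = TargetGroups(
    cond1_specific=frozenset(ids[:249]),      # planted -0.5
    cond2_specific=frozenset(ids[249:1138]),  # planted +0.5
    shared=frozenset(),
)
expr = generate_expression(genes, groups, SimulationConfig(seed=7), seed=7)
control = [ids[i] for i in
           np.random.default_rng(7).choice(len(ids), 486, replace=False)]

results = compare_target_groups(
    [
        ("naive_specific_targets", sorted(groups.cond1_specific)),
        ("formative_specific_targets", sorted(groups.cond2_specific)),
        ("random_control", control),
    ],
    expr, B=30_000, seed=7,
)
print(results_table(results).to_string(index=False))
# The planted groups sit far outside anything 30,000 random size-matched
# gene groups produce (p at the empirical floor 1/(B+1)); the random
# control group is indistinguishable from the null.
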