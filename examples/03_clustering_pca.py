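"""Cluster samples with Kendall-correlation distance and run PCA.

The dissimilarity between two samples is 1 - Kendall tau-b of their
expression profiles; average linkage builds the dendrogram. PCA operates
on row-z-scored log2 expression, so variance fractions describe
between-sample structure.
"""

import numpy as np

from mgtkit import ExpressionMatrix, SimulationConfig, hcluster, pca
from mgtkit.simulate import generate_annotation, simulate_expression

cfg = SimulationConfig(seed=7, n_genes=80)
expr = simulate_expression(generate_annotation(cfg), cfg)
logx = np.log2(expr.fpkm + 0.1)

tree = hcluster(logx)
assign = tree.cut(2)
print("two-group cut of the sample dendrogram:")
for sample, group in sorted(assign.items()):
    cond = expr.meta.loc[sample, "condition"]
    print(f"  {sample:>12} ({cond:>6}) -> cluster {group}")

res = pca(logx)
print("\nvariance explained:", " ".join(
    f"PC{i+1} {100 * v:.1f}%" for i, v in enumerate(res.variance_explained[:3])))
print("newick:", tree.to_newick()[:70], "...")
# Tumour samples share planted shifts, so the k=2 cut tends to split
# tumours from normals and PC1 carries the tumour/normal axis.
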