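"""Cross-dataset preprocessing: shared genes, log counts, extreme-gene trim.

Before predicting on a dataset other than the training one: intersect the
gene sets (training order), log-transform the counts, and drop the 1% of
genes with the highest and lowest mean log expression in the training
set.  The trim statistic is fit on training data only, so no information
leaks from the test set.
"""

import numpy as np

import cellont as co
from cellont.expression import AnnotatedMatrix

rng = np.random.default_rng(0)

genes_a = [f"g{i:03d}" for i in range(250)]
genes_b = genes_a[30:] + ["other1", "other2"]  # partial overlap
train = AnnotatedMatrix(values=rng.poisson(4.0, size=(100, 250)).astype(float),
                        cell_ids=[f"a{i}" for i in range(100)], gene_ids=genes_a)
test = AnnotatedMatrix(values=rng.poisson(6.0, size=(80, 222)).astype(float),
                       cell_ids=[f"b{i}" for i in range(80)], gene_ids=genes_b)

tr, te = co.preprocess(train, test, trim_frac=0.01)
shared = len(set(genes_a) & set(genes_b))
print(f"genes: train {len(genes_a)}, test {len(genes_b)}, shared {shared}")
print(f"after preprocessing: {len(tr.gene_ids)} genes "
      f"(= {shared} shared - 2x{int(shared * 0.01)} trimmed), "
      f"orders identical: {tr.gene_ids == te.gene_ids}")
print(f"values are log1p counts, max {tr.values.max():.2f} "
      f"(raw max was {train.values.max():.0f})")

# aligning a later dataset to a fitted model's vocabulary:
missing = AnnotatedMatrix(values=rng.poisson(3.0, size=(5, 100)).astype(float),
                          cell_ids=[f"c{i}" for i in range(5)],
                          gene_ids=tr.gene_ids[:100])
aligned = co.align_to_genes(missing, tr.gene_ids)
print(f"alignment: {missing.shape[1]} input genes -> {aligned.shape[1]} model genes, "
      f"missing ones zero-filled")
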