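"""Coexpression-module detection with the fixed-cut + PAM loop.

Three correlated gene blocks are planted; the dendrogram of 1 - |r|
dissimilarities is cut at a predefined height and refined by
partitioning-around-medoids until no new clusters form.
"""

from batsel import dissimilarity, generate_dataset, pam_dtc, pearson_matrix

x, _, truth = generate_dataset(n_genes=60, n_samples=200, n_informative=0,
                               blocks=(20, 20, 20), rho=0.9, seed=0)
D = dissimilarity(pearson_matrix(x), mode="absolute")
modules = pam_dtc(D, x.gene_ids, cut_height=0.5, min_module_size=5, seed=0)

print(f"detected {modules.n_modules} modules "
      f"(3 planted blocks of 20 genes)")
for mid, medoid in sorted(modules.medoids.items()):
    members = modules.members(mid)
    block = next((i for i, b in enumerate(truth.blocks) if medoid in b), None)
    print(f"  module {mid}: {len(members)} genes, medoid {medoid} "
          f"(planted block {block})")
print(f"total within-module cost: {modules.total_cost:.2f}")
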