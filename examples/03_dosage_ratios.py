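"""Measure dosage compensation from the count matrix.

Median XYm/XXf expression ratios per region class, expression relative
to the autosomal median, and gametologue pair sums: the three panels
that together say whether, and how, the single X is compensated.
"""

import dosagecomp as dc
from dosagecomp import expression as ex

cfg = dc.SimulationConfig(seed=42)  # rho=0.7, kappa=0.5 defaults
genes, features, _ = dc.generate_annotation(cfg)
counts, samples = dc.generate_counts(genes, cfg)

rpkm = ex.rpkm(counts, ex.gene_lengths(features))
means = ex.group_mean_rpkm(rpkm, samples)
classes = genes["region"]

ratios = ex.per_gene_ratio(means, "XYm", "XXf", classes)
print("median XYm/XXf ratio by class:")
print(ex.median_ratio_by_class(ratios).to_string(index=False))

_, auto = ex.ratio_to_autosomal_median(means, classes)
print("\nexpression relative to the autosomal median:")
print(auto.to_string(index=False))

pairs_df = genes[genes["region"] == "XY_shared_X"].reset_index().rename(
    columns={"gene_id": "x_gene", "partner": "y_gene"})[["x_gene", "y_gene"]]
_, pair_medians = ex.gametologue_sum(means, pairs_df, samples)
print("\ngametologue output (median RPKM per component):")
print(pair_medians.to_string(index=False))
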