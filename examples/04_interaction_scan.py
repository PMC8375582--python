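"""Membership x stage-expression interaction scan.

Plants heterogeneous association effects in a 125-gene set and couples each
gene's early-adulthood expression to its association strength.  Scans every
developmental stage for an interaction between set membership and that
stage's expression score, Bonferroni-corrected over stages.  Heterogeneity
matters: the interaction regression detects the covariance between a gene's
expression score and its Z within the set, so uniform effects in a small
subset carry much less information than a continuum.
"""

import pandas as pd

from devgsa import (
    bonferroni,
    brain_expression_covariate,
    compute_rpkm,
    expression_scores,
    gene_analysis,
    interaction_test,
)
from devgsa.synthetic_data import SimulationConfig, generate_dataset

cfg = SimulationConfig(
    seed=5,
    n_genes=800,
    n_panel=300,
    n_background_sets=2,
    set_size_range=(100, 150),
    structured_sets={"target_set": list(range(125))},
    enriched_sets=[("target_set", 1.0)],
    effect_distribution="uniform",  # per-gene effects U(0, 2)
    interaction_spec=("target_set", "early_adulthood", 3.0),
)
ds = generate_dataset(cfg)

results = gene_analysis(ds.snps, ds.panel.loci, ds.panel.ld_blocks())
gene_z = pd.Series({r.gene_id: r.z for r in results})

rpkm = compute_rpkm(ds.expression_counts, ds.gene_lengths)
covariates = brain_expression_covariate(rpkm).to_frame()
scores = expression_scores(rpkm, ds.samples)

members = ds.sets.sets["target_set"]
rows = []
for stage in scores.stages:
    res = interaction_test(gene_z, members, scores.stage_column(stage),
                           covariates=covariates, set_name="target_set")
    rows.append({"stage": stage, "beta": res.beta, "p": res.pvalue})
scan = pd.DataFrame(rows)
scan["p_adj"] = bonferroni(scan["p"], len(scan))
print(scan.round(4).to_string(index=False))
print("\ntarget stage: early_adulthood (planted coupling 3.0 log2 units per Z)")
# The coupled stage should carry a positive interaction surviving the
# stage-level Bonferroni; other stages show near-zero or mildly negative
# betas (expression scores are one-vs-rest contrasts, so elevating one
# stage depresses the others).
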