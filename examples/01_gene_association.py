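"""Per-gene association statistics from simulated GWAS summary data.

Generates a small synthetic dataset (LD-blocked reference panel + summary
statistics with a planted enriched set), runs the SNP-wise mean gene test
with its LD-aware weighted-chi-square null, and prints the strongest genes.
"""

import pandas as pd

from devgsa import gene_analysis
from devgsa.synthetic_data import SimulationConfig, generate_dataset

cfg = SimulationConfig(
    seed=7,
    n_genes=300,
    n_panel=500,
    n_background_sets=2,
    set_size_range=(40, 60),
    structured_sets={"planted": list(range(20))},
    enriched_sets=[("planted", 1.5)],  # median gene probit Z of 1.5
)
ds = generate_dataset(cfg)

results = gene_analysis(ds.snps, ds.panel.loci, ds.panel.ld_blocks())
df = pd.DataFrame(
    [{"gene": r.gene_id, "n_snps": r.n_snps, "stat": r.stat, "p": r.pvalue, "z": r.z}
     for r in results]
).sort_values("p")

print(df.head(10).to_string(index=False))
planted = df.gene.isin(ds.sets.sets["planted"])
print(f"\nmedian Z planted genes:    {df.z[planted].median():.2f}  (target 1.5)")
print(f"median Z background genes: {df.z[~planted].median():.2f}  (target 0)")
# The planted set's genes should dominate the top of the table: their
# summary statistics carry a mean shift calibrated to a median probit Z of
# 1.5, while background genes are null.
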