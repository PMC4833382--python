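"""Stability-screen a top hit, then annotate: LD r2, gene window, CpG change.

The stability screen refits the interaction model after removing
observations with |standardized Pearson residual| > 4; an order of
magnitude change in the odds ratio or p-value marks the result unstable.
Annotation helpers compute composite LD r2 between dosage vectors, select
variants within 1 Mb of a gene, and classify CpG-site disruption by a
substitution.
"""

import numpy as np
import pandas as pd

from trafficgwis import SimConfig, cpg_change, gene_window, pairwise_r2, simulate_genotypes, stability_screen
from trafficgwis.exposure import iqr_scale

# --- stability screen on clean simulated data ------------------------------
rng = np.random.default_rng(2)
n = 1000
g = rng.binomial(2, 0.3, n).astype(float)
e, _ = iqr_scale(rng.lognormal(6.09, 1.0, n))
y = (rng.random(n) < 1 / (1 + np.exp(1.8 - 0.3 * g * np.minimum(e, 5)))).astype(float)
verdict = stability_screen(g, e, y, snp="rs_demo")
print(f"stability: removed {verdict.outliers_removed} outliers, "
      f"OR {verdict.or_before:.2f} -> {verdict.or_after:.2f}, "
      f"p {verdict.p_before:.2e} -> {verdict.p_after:.2e}, stable={verdict.stable}")

# --- LD between neighboring SNPs in an LD-block panel ----------------------
panel = simulate_genotypes(SimConfig(n_per_stratum=(2000,), stratum_names=("EA",),
                                     n_snps=20, block_size=10, rho=0.9, fst=0.1, seed=4))
print(f"within-block adjacent r2:  {pairwise_r2(panel, 3, 4):.3f}")
print(f"across-block r2:           {pairwise_r2(panel, 9, 10):.3f}")

# --- gene-window query ------------------------------------------------------
variants = pd.DataFrame({
    "chrom": "1", "pos": [38_900_000, 39_995_074, 41_100_000],
    "id": ["far_left", "candidate", "far_right"], "ref": "G", "alt": "A",
})
hits = gene_window(variants, ("1", 39_950_000, 40_040_000), flank=1_000_000)
print(f"variants within 1 Mb of the gene span: {list(hits['id'])}")

# --- CpG disruption ---------------------------------------------------------
print(f"CGC[G->A]: {cpg_change('C', 'G', 'A', 'C')}   (a 3'-UTR CpG lost)")
print(f"C[C->T]G:  {cpg_change('C', 'C', 'T', 'G')}   (CpG on the 3' side lost)")
print(f"A[A->G]T:  {cpg_change('A', 'A', 'G', 'T')}")
print()
print("Unstable or SE>10 interactions are dropped from candidate lists;")
print("CpG-disrupting candidates are of interest because traffic-related")
print("air pollution alters DNA methylation.")
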