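"""Align effect alleles across cohorts and combine with inverse-variance weights.

Cohort B reports the opposite effect allele, so its log-odds ratio is
negated and its allele frequency complemented before combining.  The
fixed-effect estimate weights each cohort by 1/SE^2; equal cohorts shrink
the combined SE by exactly sqrt(2).
"""

import numpy as np

from trafficgwis import CohortStat, align_alleles, inverse_variance_meta

ea = CohortStat("rs0001", effect_allele="G", other_allele="A",
                beta=0.9858, se=0.2180, p=6.1e-6, maf=0.29, n=1623, cohort="EA")
aa = CohortStat("rs0001", effect_allele="A", other_allele="G",
                beta=-0.5247, se=0.4660, p=0.26, maf=0.73, n=554, cohort="AA")

ea_al, aa_al, effect_allele, ambiguous = align_alleles(ea, aa)
print(f"effect allele: {effect_allele}; AA beta {aa.beta:+.4f} -> {aa_al.beta:+.4f}, "
      f"AA freq {aa.maf:.2f} -> {aa_al.maf:.2f}; strand-ambiguous: {ambiguous}")

m = inverse_variance_meta([ea_al, aa_al])
print(f"combined: beta = {m.beta_meta:.4f}, se = {m.se_meta:.4f}, "
      f"z = {m.z_meta:.2f}, p = {m.p_meta:.2e}, consistent = {m.consistent}")
print()
print("beta is the combined interaction log-odds ratio per effect allele per")
print("exposure IQR; consistent means both aligned effects share a sign.")
print(f"Sanity: equal-cohort SE shrink factor = {1/np.sqrt(2):.4f} of a single cohort.")
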