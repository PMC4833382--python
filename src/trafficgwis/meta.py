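"""Allele alignment, fixed-effect inverse-variance meta-analysis, hit tiers.

Stages 2-3 of the analysis: per-cohort interaction effects are harmonized
to a common effect allele (sign-flipping betas and complementing allele
frequencies where cohorts report opposite alleles), combined with
inverse-variance weights (w = 1/se^2, beta = sum(w b)/sum(w),
se = sum(w)^-1/2, two-sided normal p), and classified into significance
tiers: genome-wide (p < 5e-8), suggestive (p < 1e-5), nominal replication
(p < 0.05 in the other stratum), and cross-stratum consistency (same
aligned effect sign).  The per-stratum MAF filter is relaxed for the
meta-analysis: a variant is kept if its MAF is >= 0.05 in at least one
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CohortStat", "MetaRecord", "align_alleles", "inverse_variance_meta", "classify_hits", "meta_scan"]

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class CohortStat:
    """One cohort's summary statistic for one variant."""

    snp: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    maf: float
    n: int = 0
    cohort: str = ""


@dataclass
class MetaRecord:
    """Combined inverse-variance estimate with consistency bookkeeping."""

    snp: str
    effect_allele: str
    beta_meta: float
    se_meta: float
    z_meta: float
    p_meta: float
    consistent: bool | None
    maf_rule_pass: bool
    n_cohorts: int
    excluded_reason: str = ""
    cohorts: tuple[CohortStat, ...] = ()


class AlleleMismatchError(ValueError):
    pass


def align_alleles(record_a: CohortStat, record_b: CohortStat) -> tuple[CohortStat, CohortStat, str, bool]:
    """Harmonize cohort B to cohort A's effect allele.

    If B reports the opposite allele its beta is negated and its allele
    frequency complemented.  Strand-ambiguous variants (A/T or C/G) whose
    frequencies cannot arbitrate the strand (both MAFs in [0.4, 0.6]) are
    flagged unresolvable.  Returns ``(a, b_aligned, effect_allele,
    ambiguous)``.
    """
    set_a = {record_a.effect_allele, record_a.other_allele}
    set_b = {record_b.effect_allele, record_b.other_allele}
    if set_a != set_b:
        raise AlleleMismatchError(
            f"incompatible alleles for {record_a.snp}: {sorted(set_a)} vs {sorted(set_b)}"
        )
    ambiguous = (
        frozenset(set_a) in AMBIGUOUS_PAIRS
        and 0.4 <= record_a.maf <= 0.6
        and 0.4 <= record_b.maf <= 0.6
    )
    if record_b.effect_allele == record_a.effect_allele:
        return record_a, record_b, record_a.effect_allele, ambiguous
    flipped = replace(
        record_b,
        effect_allele=record_a.effect_allele,
        other_allele=record_a.other_allele,
        beta=-record_b.beta,
        maf=1.0 - record_b.maf,
    )
    return record_a, flipped, record_a.effect_allele, ambiguous


def inverse_variance_meta(records: list[CohortStat], maf_min: float = 0.05) -> MetaRecord:
    """Fixed-effect inverse-variance combination of aligned cohort records.

    Records must already share an effect allele (see
    :func:`align_alleles`).  The relaxed MAF rule keeps the variant if the
    minor allele frequency is >= ``maf_min`` in at least one cohort; the
    combined estimate uses every record with a finite positive SE.
    """
    if not records:
        raise ValueError("no records to combine")
    snp = records[0].snp
    ea = records[0].effect_allele
    if any(r.effect_allele != ea for r in records):
        raise AlleleMismatchError(f"records for {snp} not aligned to a common effect allele")

    maf_pass = any(min(r.maf, 1.0 - r.maf) >= maf_min for r in records if np.isfinite(r.maf))
    usable = [r for r in records if np.isfinite(r.beta) and np.isfinite(r.se) and r.se > 0.0]
    if not maf_pass or not usable:
        reason = "maf_rule" if not maf_pass else "no finite standard errors"
        return MetaRecord(
            snp=snp, effect_allele=ea, beta_meta=np.nan, se_meta=np.nan,
            z_meta=np.nan, p_meta=np.nan, consistent=None, maf_rule_pass=maf_pass,
            n_cohorts=0, excluded_reason=reason, cohorts=tuple(records),
        )
    w = np.array([1.0 / r.se**2 for r in usable])
    b = np.array([r.beta for r in usable])
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    consistent = None
    if len(usable) >= 2:
        signs = np.sign(b)
        consistent = bool(np.all(signs == signs[0]) and signs[0] != 0)
    return MetaRecord(
        snp=snp, effect_allele=ea, beta_meta=beta, se_meta=se, z_meta=z, p_meta=p,
        consistent=consistent, maf_rule_pass=maf_pass, n_cohorts=len(usable),
        cohorts=tuple(records),
    )


def meta_scan(scan: pd.DataFrame, maf_min: float = 0.05) -> pd.DataFrame:
    """Meta-analyze a stratified scan table across its strata, per SNP.

    Expects the :func:`trafficgwis.gwis.run_scan` output columns.  Variants
    present in a single stratum pass through as single-cohort records.
    """
    rows = []
    for snp, grp in scan.groupby("snp", sort=False):
        recs = []
        for r in grp.itertuples():
            padj = getattr(r, "p_adjusted", None)
            p_use = float(padj) if padj is not None and np.isfinite(float(padj or np.nan)) else r.p_raw
            recs.append(
                CohortStat(
                    snp=snp,
                    effect_allele=r.effect_allele,
                    other_allele=r.other_allele,
                    beta=r.beta_gxe,
                    se=r.se_gxe,
                    p=p_use,
                    maf=r.maf,
                    n=int(getattr(r, "n", 0)),
                    cohort=r.stratum,
                )
            )
        ambiguous = False
        base = recs[0]
        aligned = [base]
        try:
            for other in recs[1:]:
                _, flipped, _, amb = align_alleles(base, other)
                ambiguous = ambiguous or amb
                aligned.append(flipped)
        except AlleleMismatchError:
            continue
        if ambiguous:
            continue
        m = inverse_variance_meta(aligned, maf_min=maf_min)
        rows.append(
            {
                "snp": snp,
                "chrom": grp["chrom"].iloc[0],
                "pos": grp["pos"].iloc[0],
                "effect_allele": m.effect_allele,
                "beta_meta": m.beta_meta,
                "se_meta": m.se_meta,
                "z_meta": m.z_meta,
                "p_meta": m.p_meta,
                "consistent": m.consistent,
                "maf_rule_pass": m.maf_rule_pass,
                "n_cohorts": m.n_cohorts,
                "excluded_reason": m.excluded_reason,
            }
        )
    return pd.DataFrame(rows)


def classify_hits(
    scan: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    genome_wide: float = 5e-8,
    suggestive: float = 1e-5,
    replication: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP significance tiers across strata and the meta-analysis.

    Tags: ``genome_wide`` / ``suggestive`` if any stratum's p passes the
    tier; ``replicated`` if suggestive in one stratum and p < 0.05 in
    another; ``consistent`` if aligned effect signs agree across strata;
    ``meta_suggestive`` if the combined p is below the suggestive tier.
    Uses adjusted p-values where present, raw otherwise.
    """
    def eff_p(grp):
        padj = grp["p_adjusted"] if "p_adjusted" in grp else None
        p = grp["p_raw"].copy()
        if padj is not None:
            use = padj.notna() & np.isfinite(padj.astype(float))
            p[use] = padj[use]
        return p.astype(float)

    rows = []
    meta_p = {}
    meta_cons = {}
    if meta is not None and len(meta):
        meta_p = dict(zip(meta["snp"], meta["p_meta"]))
        meta_cons = dict(zip(meta["snp"], meta["consistent"]))
    for snp, grp in scan.groupby("snp", sort=False):
        p = eff_p(grp).to_numpy()
        finite = np.isfinite(p)
        strata = grp["stratum"].to_numpy()
        sugg_mask = finite & (p < suggestive)
        repl = bool(
            sugg_mask.any()
            and any(finite[i] and p[i] < replication and not sugg_mask[i] for i in range(len(p)))
        ) or bool(sugg_mask.sum() >= 2)
        betas = grp["beta_gxe"].to_numpy(float)
        cons = meta_cons.get(snp)
        if cons is None and np.isfinite(betas).sum() >= 2:
            s = np.sign(betas[np.isfinite(betas)])
            cons = bool(np.all(s == s[0]) and s[0] != 0)
        mp = meta_p.get(snp, np.nan)
        rows.append(
            {
                "snp": snp,
                "chrom": grp["chrom"].iloc[0],
                "pos": grp["pos"].iloc[0],
                "best_stratum": strata[np.nanargmin(np.where(finite, p, np.inf))] if finite.any() else "",
                "best_p": float(np.nanmin(np.where(finite, p, np.nan))) if finite.any() else np.nan,
                "genome_wide": bool((finite & (p < genome_wide)).any()),
                "suggestive": bool(sugg_mask.any()),
                "replicated": repl,
                "consistent": cons,
                "p_meta": mp,
                "meta_suggestive": bool(np.isfinite(mp) and mp < suggestive),
            }
        )
    return pd.DataFrame(rows)
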