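"""Statistical-stability screening, LD, gene windows, CpG annotation.

Top interaction hits are screened for dependence on a handful of
observations: subjects with extreme standardized Pearson residuals under
the full interaction model are removed and the model refit; an order of
magnitude or greater change in the interaction odds ratio or p-value
marks the result statistically unstable.  Results with interaction
standard errors above 10 are flagged for removal outright, since an SE of
that magnitude alongside a small p-value implies an implausible odds
ratio.  The module also provides composite (dosage-correlation) LD r^2,
gene +/- flank window queries, and CpG creation/disruption calls for
single-base substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwis import fit_interaction_model, _fit_logit

__all__ = ["StabilityVerdict", "stability_screen", "pairwise_r2", "ld_matrix", "gene_window", "cpg_change"]


@dataclass
class StabilityVerdict:
    """Outcome of the outlier-removal refit for one SNP."""

    snp: str
    outliers_removed: int
    or_before: float
    or_after: float
    p_before: float
    p_after: float
    stable: bool
    se_filter_pass: bool
    reason: str = ""


def _standardized_pearson_residuals(y, phat, X, w) -> np.ndarray:
    """Pearson residuals standardized by leverage under the IRLS fit."""
    r = (y - phat) / np.sqrt(w)
    xw = X * np.sqrt(w)[:, None]
    try:
        q, _ = np.linalg.qr(xw)
        h = np.minimum((q * q).sum(axis=1), 1.0 - 1e-12)
    except np.linalg.LinAlgError:
        h = np.zeros(len(y))
    return r / np.sqrt(1.0 - h)


def stability_screen(
    g: np.ndarray,
    e: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    snp: str = "",
    residual_threshold: float = 4.0,
    se_max: float = 10.0,
) -> StabilityVerdict:
    """Refit the interaction model without outlying observations.

    Outliers are observations whose |standardized Pearson residual| under
    the full model exceeds ``residual_threshold``.  Stability requires
    less than a tenfold change in both the interaction odds ratio and its
    p-value after removal; a non-convergent refit is unstable by
    definition.
    """
    g = np.asarray(g, float)
    e = np.asarray(e, float)
    y = np.asarray(y, float)
    cov = np.empty((len(g), 0)) if covariates is None else np.asarray(covariates, float)
    ok = ~np.isnan(g)
    if cov.size:
        ok &= ~np.isnan(cov).any(axis=1)
    g, e, y, cov = g[ok], e[ok], y[ok], cov[ok]

    before = fit_interaction_model(g, e, y, cov, snp=snp)
    if not before.converged:
        raise ValueError(f"original fit for {snp!r} did not converge; nothing to screen")
    se_pass = bool(np.isfinite(before.se_gxe) and before.se_gxe <= se_max)

    X_full = np.column_stack([np.ones(len(g)), g, e, cov, g * e])
    fit, fit_ok = _fit_logit(y, X_full)
    phat = np.asarray(fit.fittedvalues)
    w = phat * (1.0 - phat)
    resid = _standardized_pearson_residuals(y, phat, X_full, w)
    out_mask = np.abs(resid) > residual_threshold
    n_out = int(out_mask.sum())

    if n_out == 0:
        return StabilityVerdict(
            snp=snp, outliers_removed=0,
            or_before=before.or_gxe, or_after=before.or_gxe,
            p_before=before.p_raw, p_after=before.p_raw,
            stable=True, se_filter_pass=se_pass,
        )
    keep = ~out_mask
    after = fit_interaction_model(g[keep], e[keep], y[keep], cov[keep], snp=snp)
    if not after.converged or not np.isfinite(after.or_gxe) or not np.isfinite(after.p_raw):
        return StabilityVerdict(
            snp=snp, outliers_removed=n_out,
            or_before=before.or_gxe, or_after=after.or_gxe,
            p_before=before.p_raw, p_after=after.p_raw,
            stable=False, se_filter_pass=se_pass, reason="refit did not converge",
        )
    d_or = abs(np.log10(after.or_gxe / before.or_gxe))
    d_p = abs(np.log10(after.p_raw / before.p_raw))
    return StabilityVerdict(
        snp=snp, outliers_removed=n_out,
        or_before=before.or_gxe, or_after=after.or_gxe,
        p_before=before.p_raw, p_after=after.p_raw,
        stable=bool(d_or < 1.0 and d_p < 1.0), se_filter_pass=se_pass,
    )


def pairwise_r2(panel, snp_a: int | str, snp_b: int | str) -> float:
    """Composite LD r^2: squared Pearson correlation of dosage vectors.

    Computed over pairwise-complete subjects.  Raises if either SNP is
    monomorphic in the complete-pair subset or fewer than 2 pairs remain.
    """
    ia = panel.snp_index(snp_a) if isinstance(snp_a, str) else int(snp_a)
    ib = panel.snp_index(snp_b) if isinstance(snp_b, str) else int(snp_b)
    a = panel.dosages[:, ia]
    b = panel.dosages[:, ib]
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("fewer than 2 pairwise-complete calls")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("SNP monomorphic in the pairwise-complete subset; r2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_matrix(panel, snps: list) -> pd.DataFrame:
    """Symmetric r^2 matrix for a variant list (NaN where undefined)."""
    ids = [panel.variants["id"].iloc[panel.snp_index(s) if isinstance(s, str) else int(s)] for s in snps]
    out = pd.DataFrame(np.ones((len(snps), len(snps))), index=ids, columns=ids)
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            try:
                v = pairwise_r2(panel, snps[i], snps[j])
            except ValueError:
                v = np.nan
            out.iloc[i, j] = out.iloc[j, i] = v
    return out


def gene_window(variants: pd.DataFrame, gene: tuple, flank: int = 1_000_000) -> pd.DataFrame:
    """Variants within ``flank`` bp of a gene's 1-based inclusive span.

    ``gene`` is ``(chrom, start, end)``; the window is the closed interval
    [start - flank, end + flank] on that chromosome.
    """
    chrom, start, end = gene[0], int(gene[1]), int(gene[2])
    if start > end:
        raise ValueError("gene start > end")
    lo, hi = start - flank, end + flank
    m = (variants["chrom"].astype(str) == str(chrom)) & (variants["pos"] >= lo) & (variants["pos"] <= hi)
    return variants[m]


_VALID_BASES = set("ACGT")


def cpg_change(flank5: str, ref: str, alt: str, flank3: str) -> str:
    """Classify a substitution's effect on CpG dinucleotides.

    A CpG exists at the variant site iff the 5' flank is C and the base is
    G, or the base is C and the 3' flank is G.  Returns ``"destroys_cpg"``,
    ``"creates_cpg"`` or ``"none"``, evaluated on the given strand only.
    """
    bases = {"flank5": flank5, "ref": ref, "alt": alt, "flank3": flank3}
    for name, b in bases.items():
        if not isinstance(b, str) or len(b) != 1 or b.upper() not in _VALID_BASES:
            raise ValueError(f"{name} must be a single unambiguous base (ACGT), got {b!r}")
    f5, r, a, f3 = (b.upper() for b in (flank5, ref, alt, flank3))

    def has_cpg(base: str) -> bool:
        return (f5 == "C" and base == "G") or (base == "C" and f3 == "G")

    before, after = has_cpg(r), has_cpg(a)
    if before and not after:
        return "destroys_cpg"
    if after and not before:
        return "creates_cpg"
    return "none"
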