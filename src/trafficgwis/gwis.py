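"""Per-SNP logistic interaction model with a robust score test.

Stage 1 of the analysis: within each ancestry stratum, each SNP enters a
case-control logistic regression

    logit P(y = 1) = b0 + bG * g + bE * e + bGxE * g*e + covariates

with g the additive minor-allele dosage and e the IQR-scaled exposure.
Effect sizes (odds ratios) come from the full-model maximum-likelihood
fit; the interaction's significance comes from a score test evaluated at
the null fit (the model without the g*e column), with an empirical
sandwich-type variance of the score so the p-value is robust to variance
misspecification:

    U       = sum_i z_i (y_i - phat_i)           z = g*e
    a       = z - X (X'WX)^-1 X'W z              W = diag(phat (1 - phat))
    V_rob   = sum_i a_i^2 (y_i - phat_i)^2
    T       = U^2 / V_rob  ~  chi-squared(1) under H0.

The model-based variance a'Wz is retained for diagnostics.  Fits use
iteratively reweighted least squares via statsmodels GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exposure import iqr_scale
from .genotype import GenotypePanel, compute_pcs, maf_vector

__all__ = ["ModelSpec", "InteractionResult", "robust_score_test", "fit_interaction_model", "run_scan"]

PRIMARY_COVARIATES = ("age", "sex")
CLINICAL_COVARIATES = PRIMARY_COVARIATES + ("bmi", "hypertension", "smoking", "diabetes", "dyslipidemia")

MAX_ITER = 50
TOL = 1e-8


@dataclass
class ModelSpec:
    """Covariate set and per-stratum principal-component counts.

    ``covariates`` is ``"primary"`` (age, sex, PCs) or ``"clinical"``
    (primary plus BMI, hypertension, smoking, diabetes, dyslipidemia).
    ``n_pcs`` maps stratum label to PC count; unlisted strata use
    ``default_pcs``.
    """

    covariates: str = "primary"
    n_pcs: dict | None = None
    default_pcs: int = 2

    def covariate_names(self) -> tuple[str, ...]:
        if self.covariates == "primary":
            return PRIMARY_COVARIATES
        if self.covariates == "clinical":
            return CLINICAL_COVARIATES
        raise ValueError(f"unknown covariate set {self.covariates!r}")

    def pcs_for(self, stratum: str) -> int:
        if self.n_pcs and stratum in self.n_pcs:
            return int(self.n_pcs[stratum])
        return self.default_pcs


@dataclass
class InteractionResult:
    """One SNP's interaction fit within one stratum."""

    snp: str
    beta_gxe: float = np.nan
    se_gxe: float = np.nan
    or_gxe: float = np.nan
    score_U: float = np.nan
    score_V_robust: float = np.nan
    score_V_model: float = np.nan
    stat_T: float = np.nan
    p_raw: float = np.nan
    p_adjusted: float | None = None
    maf: float = np.nan
    converged: bool = False
    stable: bool | None = None
    beta_g: float = np.nan
    se_g: float = np.nan
    p_g: float = np.nan
    beta_e: float = np.nan
    se_e: float = np.nan
    p_e: float = np.nan

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """IRLS logistic fit; returns (result, converged)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=MAX_ITER, tol=TOL, start_params=np.zeros(X.shape[1])
            )
        except Exception:
            return None, False
    if not np.all(np.isfinite(res.params)):
        return None, False
    # diverging coefficients or non-finite standard errors indicate
    # (quasi-)separation: the MLE does not exist at a finite point
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bse = np.asarray(res.bse)
    if np.max(np.abs(res.params)) > 30.0 or not np.all(np.isfinite(bse)):
        return res, False
    return res, bool(getattr(res, "converged", True))


def _drop_degenerate(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop constant columns (beyond the intercept) and report kept mask."""
    keep = np.ones(X.shape[1], dtype=bool)
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            keep[j] = False
    return X[:, keep], keep


def robust_score_test(
    g: np.ndarray, e: np.ndarray, y: np.ndarray, X: np.ndarray
) -> tuple[float, float, float, float, float, bool]:
    """Score test for the g*e interaction against the null design ``X``.

    ``X`` is the null covariate matrix and must already contain the
    intercept and the G and E main effects.  Returns
    ``(U, V_robust, T, p, V_model, converged)``; on null non-convergence,
    separation or a non-positive variance the statistic is NaN and
    ``converged`` is False.
    """
    g = np.asarray(g, float)
    e = np.asarray(e, float)
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    z = g * e

    res, ok = _fit_logit(y, X)
    if res is None or not ok:
        return np.nan, np.nan, np.nan, np.nan, np.nan, False
    phat = np.asarray(res.fittedvalues)
    w = phat * (1.0 - phat)

    U = float(z @ (y - phat))
    XtW = X.T * w
    try:
        coef = np.linalg.solve(XtW @ X, XtW @ z)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan, np.nan, np.nan, False
    a = z - X @ coef
    V_rob = float(np.sum(a * a * (y - phat) ** 2))
    V_model = float(a @ (w * z))
    if not np.isfinite(V_rob) or V_rob <= 0.0:
        return U, V_rob, np.nan, np.nan, V_model, False
    T = U * U / V_rob
    p = float(stats.chi2.sf(T, 1))
    return U, V_rob, T, p, V_model, True


def fit_interaction_model(
    g: np.ndarray,
    e: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    snp: str = "",
) -> InteractionResult:
    """Fit the full interaction model for one SNP.

    Betas, SEs and ORs come from the full-model Wald fit; the interaction
    p-value comes from :func:`robust_score_test` on the null that retains
    the G and E main effects and all covariates.  Rows with a missing
    dosage are dropped (complete-case per variant).
    """
    g = np.asarray(g, float)
    e = np.asarray(e, float)
    y = np.asarray(y, float)
    cov = np.empty((len(g), 0)) if covariates is None else np.asarray(covariates, float)
    ok = ~np.isnan(g)
    if cov.size:
        ok &= ~np.isnan(cov).any(axis=1)
    g, e, y, cov = g[ok], e[ok], y[ok], cov[ok]

    res = InteractionResult(snp=snp)
    if len(g) == 0 or np.ptp(g) == 0.0:
        return res
    p_alt = g.mean() / 2.0
    res.maf = float(min(p_alt, 1.0 - p_alt))

    n = len(g)
    X_null = np.column_stack([np.ones(n), g, e, cov])
    X_null, _ = _drop_degenerate(X_null)
    X_full = np.column_stack([X_null, g * e])

    U, V_rob, T, p_score, V_model, score_ok = robust_score_test(g, e, y, X_null)
    res.score_U, res.score_V_robust, res.score_V_model = U, V_rob, V_model
    res.stat_T, res.p_raw = T, p_score

    fit, fit_ok = _fit_logit(y, X_full)
    res.converged = bool(score_ok and fit_ok)
    if fit is not None and fit_ok:
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
        res.beta_g, res.se_g, res.p_g = float(params[1]), float(bse[1]), float(pvals[1])
        res.beta_e, res.se_e, res.p_e = float(params[2]), float(bse[2]), float(pvals[2])
        res.beta_gxe, res.se_gxe = float(params[-1]), float(bse[-1])
        res.or_gxe = float(np.exp(res.beta_gxe))
    return res


def run_scan(
    panel: GenotypePanel,
    frame: pd.DataFrame,
    spec: ModelSpec | None = None,
    strata: list[str] | None = None,
    maf_min: float = 0.05,
    genome_wide: float = 5e-8,
    suggestive: float = 1e-5,
    flip_to_minor: bool = True,
) -> pd.DataFrame:
    """Ancestry-stratified interaction scan over all SNPs.

    Each stratum is analyzed independently: exposure rescaled to the
    stratum IQR, per-stratum MAF filter (>= ``maf_min``), per-stratum
    principal components appended to the covariates, and dosages flipped so
    effects are per minor allele within the stratum.  Returns one row per
    (stratum, SNP) in deterministic order, tagged ``genome_wide`` /
    ``suggestive`` on the raw score p.
    """
    spec = spec or ModelSpec()
    if strata is None:
        strata = list(pd.unique(frame["stratum"]))
    cov_names = spec.covariate_names()
    subj_pos = {s: i for i, s in enumerate(panel.subjects)}

    rows = []
    frame = frame[frame["sample_id"].isin(subj_pos)]
    for stratum in strata:
        sub = frame[frame["stratum"] == stratum]
        if len(sub) < 50:
            warnings.warn(f"stratum {stratum!r} has only {len(sub)} subjects")
        idx = np.array([subj_pos[s] for s in sub["sample_id"]])
        sp = panel.subset(subjects=idx)
        e, _ = iqr_scale(sub["distance_m"].to_numpy())
        y = sub["outcome"].to_numpy(float)
        cov = sub[list(cov_names)].to_numpy(float)

        mafs = maf_vector(sp)
        keep = np.flatnonzero(np.nan_to_num(mafs, nan=-1.0) >= maf_min)

        k = spec.pcs_for(stratum)
        pcs = compute_pcs(sp.subset(snps=keep), k) if k > 0 else np.empty((len(sub), 0))
        cov_all = np.column_stack([cov, pcs])

        for j in keep:
            dose = sp.dosages[:, j].copy()
            freq = np.nanmean(dose) / 2.0
            ref, alt = sp.variants["ref"].iloc[j], sp.variants["alt"].iloc[j]
            effect, other = alt, ref
            if flip_to_minor and freq > 0.5:
                dose = 2.0 - dose
                effect, other = ref, alt
            r = fit_interaction_model(dose, e, y, cov_all, snp=sp.variants["id"].iloc[j])
            d = r.as_dict()
            d["stratum"] = stratum
            d["chrom"] = sp.variants["chrom"].iloc[j]
            d["pos"] = int(sp.variants["pos"].iloc[j])
            d["effect_allele"] = effect
            d["other_allele"] = other
            d["n"] = int(len(sub))
            p = d["p_raw"]
            d["tag_genome_wide"] = bool(np.isfinite(p) and p < genome_wide)
            d["tag_suggestive"] = bool(np.isfinite(p) and p < suggestive)
            rows.append(d)
    out = pd.DataFrame(rows)
    if len(out):
        front = ["chrom", "pos", "snp", "stratum", "maf"]
        out = out[front + [c for c in out.columns if c not in front]]
    return out
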