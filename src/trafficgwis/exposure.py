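"""Exposure scaling, sample-table I/O, and cohort summary statistics.

The exposure is residential distance to the nearest major roadway in
meters, modeled per interquartile-range (IQR) unit so a one-unit change in
the scaled exposure corresponds to an IQR-meter change in raw distance.
Cohort summaries follow the usual clinical Table-1 layout: mean (SD) for
continuous covariates with a one-way ANOVA across strata, count (%) for
binary covariates with a continuity-corrected chi-squared test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "iqr_scale",
    "chisq_yates",
    "anova_f",
    "summarize_cohort",
    "read_sample_table",
    "write_sample_table",
]

SAMPLE_COLUMNS = ("sample_id", "stratum", "outcome", "distance_m", "age", "sex")
CLINICAL_FLAGS = ("bmi", "hypertension", "smoking", "diabetes", "dyslipidemia")


def iqr_scale(values) -> tuple[np.ndarray, float]:
    """Divide values by their interquartile range.

    Quartiles use linear interpolation (NumPy default, R type 7).  Returns
    the scaled vector and the IQR in the input's units.  Raises on fewer
    than 4 finite values or a zero IQR.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 4:
        raise ValueError(f"need >= 4 finite values to estimate quartiles, got {finite.size}")
    q1, q3 = np.percentile(finite, [25.0, 75.0])
    iqr = float(q3 - q1)
    if iqr <= 0.0:
        raise ValueError("IQR is zero; exposure cannot be scaled")
    return v / iqr, iqr


def chisq_yates(table, correction: bool = True) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 table with Yates continuity correction.

    The correction term is ``min(0.5, |O - E|)`` per cell, so a table with
    observed equal to expected scores exactly zero.  ``correction=False``
    gives the uncorrected Pearson statistic.  The p-value is the upper tail
    of chi-squared with 1 df.
    """
    o = np.asarray(table, dtype=float).reshape(2, 2)
    if (o < 0).any():
        raise ValueError("counts must be non-negative")
    rows, cols = o.sum(axis=1), o.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise ValueError("both margins must be positive")
    e = np.outer(rows, cols) / o.sum()
    dev = np.abs(o - e)
    c = np.minimum(0.5, dev) if correction else 0.0
    stat = float((((dev - c) ** 2) / e).sum())
    return stat, float(stats.chi2.sf(stat, 1))


def anova_f(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F with (k-1, N-k) df across groups."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    gs = [g[np.isfinite(g)] for g in gs]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs n >= 2")
    if all(np.var(g) == 0.0 for g in gs):
        raise ValueError("zero within-group variance in all groups; F undefined")
    f, p = stats.f_oneway(*gs)
    return float(f), float(p)


def summarize_cohort(
    frame: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "bmi"),
    binary: tuple[str, ...] = ("sex", "smoking", "diabetes", "hypertension", "dyslipidemia", "outcome"),
) -> pd.DataFrame:
    """Table-1-style per-stratum summary with cross-stratum p-values.

    Continuous covariates report mean (SD) and an ANOVA p; binary
    covariates report count (percent) and a continuity-corrected
    chi-squared p.  Missing values are dropped per summary cell.  With a
    single stratum no p column is produced.
    """
    if "stratum" not in frame.columns:
        raise ValueError("frame lacks a 'stratum' column")
    strata = list(pd.unique(frame["stratum"]))
    rows = []
    n_row = {"covariate": "n", "kind": "n"}
    n_row.update({s: str(int((frame["stratum"] == s).sum())) for s in strata})
    n_row["all"] = str(len(frame))
    rows.append(n_row)

    for cov in continuous:
        if cov not in frame.columns:
            continue
        row = {"covariate": cov, "kind": "continuous"}
        for label, sub in [("all", frame)] + [(s, frame[frame["stratum"] == s]) for s in strata]:
            v = sub[cov].dropna()
            row[label] = f"{v.mean():.1f} ({v.std():.3g})" if len(v) else ""
        if len(strata) > 1:
            groups = [frame.loc[frame["stratum"] == s, cov].dropna() for s in strata]
            try:
                _, row["p"] = anova_f(groups)
            except ValueError:
                row["p"] = np.nan
        rows.append(row)

    for cov in binary:
        if cov not in frame.columns:
            continue
        row = {"covariate": cov, "kind": "binary"}
        for label, sub in [("all", frame)] + [(s, frame[frame["stratum"] == s]) for s in strata]:
            v = sub[cov].dropna()
            cnt = int(v.sum())
            pct = 100.0 * cnt / len(v) if len(v) else np.nan
            row[label] = f"{cnt} ({pct:.3g})"
        if len(strata) > 1:
            tab = []
            for s in strata:
                v = frame.loc[frame["stratum"] == s, cov].dropna()
                tab.append([int(v.sum()), int(len(v) - v.sum())])
            if len(strata) == 2:
                try:
                    _, row["p"] = chisq_yates(np.array(tab))
                except ValueError:
                    row["p"] = np.nan
            else:
                stat, p, _, _ = stats.chi2_contingency(np.array(tab))
                row["p"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def read_sample_table(path) -> pd.DataFrame:
    """Read the TSV sample table and recompute the scaled exposure."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"sample table lacks columns: {sorted(missing)}")
    scaled, _ = iqr_scale(frame["distance_m"].to_numpy())
    frame["exposure_scaled"] = scaled
    return frame


def write_sample_table(frame: pd.DataFrame, path) -> None:
    cols = [c for c in frame.columns if c != "exposure_scaled"]
    frame[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
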