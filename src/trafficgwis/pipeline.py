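"""End-to-end orchestration: simulate -> QC -> scan -> adjust -> meta ->
stability -> report, with a manifest and deterministic outputs.

Every run writes a fixed sequence of stage outputs into one directory and
finishes with ``manifest.json`` echoing the resolved configuration and a
SHA-256 checksum for every file, so a rerun with an identical
configuration is byte-identical and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exposure import summarize_cohort, write_sample_table, read_sample_table
from .genotype import apply_qc, read_vcf, write_vcf
from .gwis import ModelSpec, run_scan
from .inflation import estimate_lambda_median, gcf_adjust, qq_data
from .meta import classify_hits, meta_scan
from .simulate import SimConfig, simulate_cohort
from .stability import stability_screen

__all__ = ["RunConfig", "run_pipeline", "render_reports"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Thresholds default to the conventional GWIS tiers: genome-wide
    5e-8, suggestive 1e-5, nominal replication 0.05, MAF 0.05, call rate
    0.98, interaction-SE cap 10, GCF denominator df 100.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    vcf_path: str | None = None
    samples_path: str | None = None
    covariates: str = "primary"
    n_pcs: dict = field(default_factory=lambda: {"EA": 2, "AA": 2})
    genome_wide: float = 5e-8
    suggestive: float = 1e-5
    replication: float = 0.05
    maf: float = 0.05
    callrate: float = 0.98
    se_max: float = 10.0
    gcf_df2: float = 100.0
    lambda_subsample: int | None = None
    adjust_only_inflated: bool = True
    stability_threshold: float = 4.0
    seed: int = 0
    out_dir: str = "gwis_run"

    def __post_init__(self) -> None:
        for name in ("genome_wide", "suggestive", "replication", "maf", "callrate"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.se_max <= 0 or self.gcf_df2 <= 0:
            raise ValueError("se_max and gcf_df2 must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a config file; unknown keys are errors, not warnings."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in raw and isinstance(raw["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(raw["sim"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            for key in ("n_per_stratum", "stratum_names", "maf_range"):
                if key in raw["sim"]:
                    raw["sim"][key] = tuple(raw["sim"][key])
            if "causal_snps" in raw["sim"]:
                raw["sim"]["causal_snps"] = tuple(tuple(c) for c in raw["sim"]["causal_snps"])
            raw["sim"] = SimConfig(**raw["sim"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk).

    Inputs are simulated from ``config.sim`` unless ``vcf_path`` and
    ``samples_path`` point at existing data.  Stage failure raises with
    the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_files: dict[str, list[str]] = {}
    stage = "simulate"
    try:
        if config.vcf_path and config.samples_path:
            panel = read_vcf(config.vcf_path)
            frame = read_sample_table(config.samples_path)
        else:
            panel, frame = simulate_cohort(config.sim)
        write_vcf(panel, out / "genotypes.vcf")
        write_sample_table(frame, out / "samples.tsv")
        _write_tsv(summarize_cohort(frame), out / "cohort_summary.tsv")
        stage_files[stage] = ["genotypes.vcf", "samples.tsv", "cohort_summary.tsv"]

        stage = "qc"
        panel_qc, report = apply_qc(
            panel, snp_callrate=config.callrate, subject_callrate=config.callrate, maf_min=config.maf
        )
        frame_qc = frame[frame["sample_id"].isin(panel_qc.subjects)].reset_index(drop=True)
        _write_tsv(report.to_frame(), out / "qc_report.tsv")
        stage_files[stage] = ["qc_report.tsv"]

        stage = "scan"
        spec = ModelSpec(covariates=config.covariates, n_pcs=config.n_pcs)
        scan = run_scan(
            panel_qc, frame_qc, spec,
            maf_min=config.maf, genome_wide=config.genome_wide, suggestive=config.suggestive,
        )
        _write_tsv(scan, out / "scan_results.tsv")
        stage_files[stage] = ["scan_results.tsv"]

        stage = "adjust"
        lam_rows = []
        scan = scan.copy()
        scan["p_adjusted"] = np.nan
        for stratum, grp in scan.groupby("stratum", sort=False):
            stats_t = grp["stat_T"].to_numpy(float)
            finite = stats_t[np.isfinite(stats_t)]
            if finite.size >= 100:
                lam = estimate_lambda_median(finite, config.lambda_subsample, seed=config.seed)
                lam_val = lam.lambda_m
            else:
                lam_val = 1.0
            apply_adj = (lam_val > 1.0) or not config.adjust_only_inflated
            if apply_adj:
                idx = grp.index[np.isfinite(stats_t)]
                scan.loc[idx, "p_adjusted"] = gcf_adjust(
                    scan.loc[idx, "stat_T"].to_numpy(float), lam_val, config.gcf_df2
                )
            lam_rows.append(
                {"stratum": stratum, "lambda_m": lam_val, "n_stats": int(finite.size),
                 "adjusted": bool(apply_adj), "df2": config.gcf_df2}
            )
        _write_tsv(pd.DataFrame(lam_rows), out / "lambda_report.tsv")
        _write_tsv(scan, out / "scan_adjusted.tsv")
        stage_files[stage] = ["lambda_report.tsv", "scan_adjusted.tsv"]

        stage = "meta"
        meta = meta_scan(scan, maf_min=config.maf)
        _write_tsv(meta, out / "meta_results.tsv")
        stage_files[stage] = ["meta_results.tsv"]

        stage = "stability"
        stab = _screen_top_hits(panel_qc, frame_qc, scan, config)
        _write_tsv(stab, out / "stability.tsv")
        stage_files[stage] = ["stability.tsv"]

        stage = "report"
        report_files = render_reports(out, scan, meta, config)
        stage_files[stage] = report_files
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config.to_jsonable(),
        "stages": stage_files,
        "snp_counts": {
            "input": panel.n_snps,
            "post_qc": panel_qc.n_snps,
            "scanned": int(scan["snp"].nunique()) if len(scan) else 0,
        },
        "files": {},
    }
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["files"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _screen_top_hits(panel_qc, frame_qc, scan: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Stability-screen every suggestive hit (by raw or adjusted p)."""
    from .exposure import iqr_scale
    from .genotype import compute_pcs, maf_vector
    from .gwis import ModelSpec

    spec = ModelSpec(covariates=config.covariates, n_pcs=config.n_pcs)
    p_eff = scan["p_raw"].to_numpy(float).copy()
    padj = scan["p_adjusted"].to_numpy(float)
    use = np.isfinite(padj)
    p_eff[use] = padj[use]
    hits = scan[np.isfinite(p_eff) & (p_eff < config.suggestive)]
    rows = []
    subj_pos = {s: i for i, s in enumerate(panel_qc.subjects)}
    for stratum, grp in hits.groupby("stratum", sort=False):
        sub = frame_qc[frame_qc["stratum"] == stratum]
        idx = np.array([subj_pos[s] for s in sub["sample_id"]])
        sp = panel_qc.subset(subjects=idx)
        e, _ = iqr_scale(sub["distance_m"].to_numpy())
        y = sub["outcome"].to_numpy(float)
        cov = sub[list(spec.covariate_names())].to_numpy(float)
        mafs = maf_vector(sp)
        keep = np.flatnonzero(np.nan_to_num(mafs, nan=-1.0) >= config.maf)
        k = spec.pcs_for(stratum)
        pcs = compute_pcs(sp.subset(snps=keep), k) if k > 0 else np.empty((len(sub), 0))
        cov_all = np.column_stack([cov, pcs])
        for r in grp.itertuples():
            j = sp.snp_index(r.snp)
            dose = sp.dosages[:, j].copy()
            if np.nanmean(dose) / 2.0 > 0.5:
                dose = 2.0 - dose
            try:
                v = stability_screen(
                    dose, e, y, cov_all, snp=r.snp,
                    residual_threshold=config.stability_threshold, se_max=config.se_max,
                )
                d = dataclasses.asdict(v)
            except ValueError as exc:
                d = {"snp": r.snp, "outliers_removed": 0, "or_before": np.nan,
                     "or_after": np.nan, "p_before": np.nan, "p_after": np.nan,
                     "stable": False, "se_filter_pass": False, "reason": str(exc)}
            d["stratum"] = stratum
            rows.append(d)
    cols = ["snp", "stratum", "outliers_removed", "or_before", "or_after",
            "p_before", "p_after", "stable", "se_filter_pass", "reason"]
    return pd.DataFrame(rows, columns=cols)


def render_reports(out_dir, scan: pd.DataFrame, meta: pd.DataFrame, config: RunConfig) -> list[str]:
    """Manhattan/QQ data files and Table-2/3-shaped top-hit tables.

    Writes, per stratum, ``manhattan_<s>.tsv`` (chrom, pos, snp, minus
    log10 p with the two significance lines recorded as header metadata)
    and ``qq_<s>.tsv`` (expected vs observed quantiles plus lambda), and
    the cross-stratum ``top_hits.tsv`` classification.
    """
    out = Path(out_dir)
    files = []
    for stratum, grp in scan.groupby("stratum", sort=False):
        p = grp["p_raw"].to_numpy(float)
        padj = grp["p_adjusted"].to_numpy(float)
        p_eff = np.where(np.isfinite(padj), padj, p)
        ok = np.isfinite(p_eff) & (p_eff > 0)
        man = pd.DataFrame(
            {
                "chrom": grp["chrom"].to_numpy()[ok],
                "pos": grp["pos"].to_numpy()[ok],
                "snp": grp["snp"].to_numpy()[ok],
                "neglog10_p": -np.log10(p_eff[ok]),
            }
        )
        name = f"manhattan_{stratum}.tsv"
        with open(out / name, "w") as fh:
            fh.write(f"# genome_wide_line={-np.log10(config.genome_wide):.6g}\t"
                     f"suggestive_line={-np.log10(config.suggestive):.6g}\n")
            man.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
        files.append(name)

        if ok.any():
            exp, obs, lam = qq_data(p_eff[ok])
            qq = pd.DataFrame({"expected_neglog10": exp, "observed_neglog10": obs})
            name = f"qq_{stratum}.tsv"
            with open(out / name, "w") as fh:
                fh.write(f"# lambda_from_all={lam:.6g}\n")
                qq.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
            files.append(name)

    hits = classify_hits(
        scan, meta, genome_wide=config.genome_wide,
        suggestive=config.suggestive, replication=config.replication,
    )
    if len(hits):
        hits = hits.sort_values("best_p", na_position="last").reset_index(drop=True)
    _write_tsv(hits, out / "top_hits.tsv")
    files.append("top_hits.tsv")
    return files
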