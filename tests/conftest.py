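"""Shared fixtures: hand-built panels and a session-scoped simulated cohort."""

import numpy as np
import pandas as pd
import pytest

from trafficgwis import GenotypePanel, SimConfig, simulate_cohort


def make_panel(dosages, chrom="1", ids=None, ref="A", alt="G"):
    """Small helper to build a panel from a dosage matrix."""
    d = np.asarray(dosages, dtype=float)
    n_subj, n_snp = d.shape
    ids = ids or [f"rs{i}" for i in range(n_snp)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_snp + 1) * 100,
            "id": ids,
            "ref": ref,
            "alt": alt,
        }
    )
    return GenotypePanel(dosages=d, variants=variants, subjects=[f"s{i}" for i in range(n_subj)])


@pytest.fixture(scope="session")
def small_cohort():
    """Two-stratum cohort at reduced size for structural tests."""
    cfg = SimConfig(n_per_stratum=(400, 200), n_snps=300, seed=1)
    return cfg, *simulate_cohort(cfg)


@pytest.fixture
def hand_vcf(tmp_path):
    """3-subject, 2-SNP VCF with exactly one missing call."""
    text = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\ts2\n"
        "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0\n"
    )
    path = tmp_path / "hand.vcf"
    path.write_text(text)
    return path
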