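"""Genotype I/O, QC ordering, allele frequencies and PCA structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from trafficgwis import GenotypePanel, apply_qc, compute_pcs, maf, read_vcf, write_vcf
from trafficgwis.genotype import VCFDialectError, maf_vector

from conftest import make_panel


class TestVCF:
    def test_hand_vcf_reads_one_missing_cell(self, hand_vcf):
        panel = read_vcf(hand_vcf)
        assert panel.dosages.shape == (3, 2)
        assert np.isnan(panel.dosages).sum() == 1
        assert np.isnan(panel.dosages[1, 1])
        expected = np.array([[0.0, 1.0], [1.0, np.nan], [2.0, 0.0]])
        assert np.array_equal(panel.dosages, expected, equal_nan=True)
        assert list(panel.variants["id"]) == ["rs1", "rs2"]
        assert list(panel.variants["pos"]) == [100, 200]

    def test_round_trip_identity(self, hand_vcf, tmp_path):
        panel = read_vcf(hand_vcf)
        out = tmp_path / "rt.vcf"
        write_vcf(panel, out)
        back = read_vcf(out)
        assert np.array_equal(panel.dosages, back.dosages, equal_nan=True)
        pd.testing.assert_frame_equal(panel.variants, back.variants)
        assert panel.subjects == back.subjects

    def test_multiallelic_rejected_naming_variant(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\n"
            "1\t100\trsBad\tA\tG,T\t.\tPASS\t.\tGT\t0/2\n"
        )
        path = tmp_path / "multi.vcf"
        path.write_text(text)
        with pytest.raises(VCFDialectError, match="rsBad"):
            read_vcf(path)

    def test_duplicate_id_and_nonmonotone_pos_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_panel([[0, 1]], ids=["rs1", "rs1"])
        variants = pd.DataFrame(
            {"chrom": "1", "pos": [200, 100], "id": ["a", "b"], "ref": "A", "alt": "G"}
        )
        with pytest.raises(ValueError, match="increasing"):
            GenotypePanel(dosages=np.zeros((1, 2)), variants=variants, subjects=["s0"])


class TestMAF:
    @pytest.mark.parametrize(
        "dosages, expected",
        [
            ([0, 0, 0, 0], 0.0),
            ([0, 1, 2, np.nan], 0.5),
            ([2, 2, 2, 1], 1.0 / 8.0),
        ],
    )
    def test_hand_counts(self, dosages, expected):
        panel = make_panel(np.array(dosages).reshape(-1, 1))
        assert maf(panel, 0) == pytest.approx(expected)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(40, 5)).astype(float)
        panel = make_panel(d)
        flipped = make_panel(2.0 - d)
        for j in range(5):
            assert maf(panel, j) == pytest.approx(maf(flipped, j))

    def test_all_missing_flagged(self):
        panel = make_panel(np.full((4, 1), np.nan))
        with pytest.warns(UserWarning, match="all-missing"):
            assert np.isnan(maf(panel, 0))


class TestQC:
    def test_snp_callrate_removal(self):
        d = np.ones((10, 2))
        d[0, 0] = np.nan  # SNP 0 at 90% call rate
        _, rep = apply_qc(make_panel(d), snp_callrate=0.98, subject_callrate=0.0, maf_min=0.0)
        assert rep.snps_removed_callrate == 1

    def test_maf_boundary_inclusive(self):
        # MAF exactly 0.05: 1 alt allele in 10 subjects = 1/20 = 0.05
        d = np.zeros((10, 1))
        d[0, 0] = 1.0
        filtered, rep = apply_qc(make_panel(d), snp_callrate=0.0, subject_callrate=0.0, maf_min=0.05)
        assert filtered.n_snps == 1
        assert rep.snps_removed_maf == 0

    def test_constructed_per_stage_removals(self):
        # 20 subjects x 8 SNPs: 2 SNPs at low call rate; then subject 19
        # misses half the surviving SNPs (their call rate stays at 95%);
        # then 3 SNPs are monomorphic among the remaining subjects
        rng = np.random.default_rng(4)
        d = rng.integers(1, 3, size=(20, 8)).astype(float)
        d[:, 0] = np.nan  # call rate 0
        d[:10, 1] = np.nan  # call rate 0.5
        d[19, 2:5] = np.nan  # subject 19: 3 of 6 surviving SNPs missing
        d[:19, 2] = 0.0  # monomorphic after subject removal
        d[:19, 3] = 0.0
        d[:19, 4] = 0.0
        d[:, 5] = 1.0
        d[0, 5] = 2.0  # MAF 21/40 -> 0.475
        d[:, 6] = np.tile([0.0, 1.0], 10)
        d[:, 7] = np.tile([2.0, 1.0], 10)
        _, rep = apply_qc(make_panel(d), snp_callrate=0.9, subject_callrate=0.9, maf_min=0.05)
        assert (rep.snps_removed_callrate, rep.subjects_removed_callrate, rep.snps_removed_maf) == (2, 1, 3)

    def test_idempotent(self, small_cohort):
        _, panel, _ = small_cohort
        once, _ = apply_qc(panel)
        twice, rep2 = apply_qc(once)
        assert np.array_equal(once.dosages, twice.dosages, equal_nan=True)
        assert rep2.snps_removed_callrate == 0
        assert rep2.subjects_removed_callrate == 0
        assert rep2.snps_removed_maf == 0

    def test_empty_result_errors(self):
        d = np.zeros((4, 1))  # monomorphic, removed by MAF filter
        with pytest.raises(ValueError, match="removed everything"):
            apply_qc(make_panel(d))


class TestPCA:
    def test_pc1_separates_strata(self):
        from trafficgwis import SimConfig, simulate_genotypes

        cfg = SimConfig(n_per_stratum=(150, 150), n_snps=400, fst=0.1, rho=0.0, missing_rate=0.0, seed=3)
        panel = simulate_genotypes(cfg)
        qc, _ = apply_qc(panel)
        scores = compute_pcs(qc, 2)
        is_second = np.array([s.startswith("AA") for s in qc.subjects], dtype=float)
        r, _ = pearsonr(scores[:, 0], is_second)
        assert abs(r) > 0.9

    def test_duplicated_subjects_get_identical_scores(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(20, 30)).astype(float)
        d2 = np.vstack([d, d[:1]])  # subject 0 duplicated as row 20
        panel = make_panel(d2)
        scores = compute_pcs(panel, 2)
        assert np.allclose(scores[0], scores[20])

    def test_orthogonality(self, small_cohort):
        _, panel, _ = small_cohort
        qc, _ = apply_qc(panel)
        scores = compute_pcs(qc, 3)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_k_bound(self):
        panel = make_panel(np.array([[0.0, 1.0], [1.0, 2.0]]))
        with pytest.raises(ValueError, match="k="):
            compute_pcs(panel, 2)

    def test_monomorphic_excluded_with_warning(self):
        rng = np.random.default_rng(9)
        d = rng.integers(0, 3, size=(15, 10)).astype(float)
        d[:, 0] = 0.0
        with pytest.warns(UserWarning, match="monomorphic"):
            scores = compute_pcs(make_panel(d), 2)
        assert scores.shape == (15, 2)


def test_maf_vector_matches_scalar(small_cohort):
    _, panel, _ = small_cohort
    vec = maf_vector(panel)
    for j in (0, 5, 50):
        assert vec[j] == pytest.approx(maf(panel, j))
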