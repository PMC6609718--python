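"""VCF intake, exact Hardy-Weinberg test, and the QC filter chain."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from sociogwas.genoqc import (
    GenotypeMatrix,
    QCThresholds,
    apply_qc,
    hwe_exact_test,
    read_vcf,
    write_genotype_tables,
)
from sociogwas.simulate import SimulationConfig, simulate_study, write_vcf

from conftest import make_genotype_matrix

VCF_FIXTURE = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/0:20\t0/1:20\t1/1:20
1\t200\t.\tC\tT\t.\tPASS\t.\tGT:DP\t0|1:20\t0/1:5\t./.:20
1\t300\t.\tG\tA\t.\tPASS\t.\tGT:DP\t1/1:9\t0/0:9\t0/1:9
1\t400\t.\tT\tC,G\t.\tPASS\t.\tGT:DP\t0/1:20\t0/2:20\t1/2:20
2\t150\t.\tA\tC\t.\tPASS\t.\tGT:DP\t0/0:30\t0/0:30\t0/1:30
2\t250\t.\tG\tC\t.\tPASS\t.\tGT:DP\t0/1:15\t1|0:15\t0/1:15
"""


@pytest.fixture()
def fixture_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_FIXTURE)
    return path


class TestReadVcf:
    def test_shape_and_multiallelic_skip(self, fixture_vcf):
        gm = read_vcf(fixture_vcf)
        assert gm.n_samples == 3 and gm.n_loci == 5  # 6 records, 1 multiallelic
        assert gm.loci.attrs["n_multiallelic_skipped"] == 1

    def test_phased_and_unphased_dosage_agree(self, fixture_vcf):
        gm = read_vcf(fixture_vcf)
        row = gm.loci.query("contig == '2' and pos == 250").index[0]
        assert list(gm.dosages[:, row]) == [1.0, 1.0, 1.0]

    def test_missing_genotype_is_nan(self, fixture_vcf):
        gm = read_vcf(fixture_vcf)
        row = gm.loci.query("pos == 200").index[0]
        assert np.isnan(gm.dosages[2, row])

    def test_low_depth_masked_only_at_qc(self, fixture_vcf):
        gm = read_vcf(fixture_vcf)
        row = gm.loci.query("pos == 200").index[0]
        assert gm.dosages[1, row] == 1.0  # DP=5 still present after read
        filt, _ = apply_qc(gm, QCThresholds(maf_min=0.0, miss_max=1.0, hwe_p_min=0.0))
        # the whole locus survives, but DP=5 genotype was masked before stats
        r2 = filt.loci.query("pos == 200")
        assert len(r2) == 1
        assert filt.n_miss()[r2.index[0]] == 2


class TestHweExactTest:
    def enumeration_oracle(self, n_aa, n_ab, n_bb):
        """Direct enumeration with binomial coefficients (independent of the
        log-gamma recurrence used by the implementation)."""
        n = n_aa + n_ab + n_bb
        na = 2 * n_aa + n_ab
        probs = {}
        for het in range(na % 2, min(na, 2 * n - na) + 1, 2):
            homa = (na - het) // 2
            homb = n - het - homa
            if homa < 0 or homb < 0:
                continue
            probs[het] = (
                comb(n, homa, exact=True)
                * comb(n - homa, homb, exact=True)
                * 2**het
            )
        tot = sum(probs.values())
        p_obs = probs[n_ab]
        return sum(v for v in probs.values() if v <= p_obs) / tot

    def test_most_probable_configuration(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=0.05)

    def test_extreme_het_deficit(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts", [(5, 10, 5), (12, 2, 6), (0, 10, 0), (30, 12, 1), (7, 7, 7)]
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            self.enumeration_oracle(*counts), rel=1e-9
        )

    def test_symmetric_under_allele_swap(self):
        assert hwe_exact_test(12, 8, 3) == pytest.approx(hwe_exact_test(3, 8, 12))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestApplyQc:
    def toy_matrix(self):
        rng = np.random.default_rng(0)
        clean = rng.binomial(2, 0.4, size=(60, 1)).astype(float)
        rare = rng.binomial(2, 0.02, size=(60, 1)).astype(float)
        x_chrom = rng.binomial(2, 0.4, size=(60, 1)).astype(float)
        dosages = np.hstack([clean, rare, x_chrom])
        return make_genotype_matrix(dosages, contigs=["5", "7", "X"])

    def test_one_removal_per_rule(self):
        gm = self.toy_matrix()
        filt, rep = apply_qc(gm)
        assert filt.n_loci == 1
        assert rep.removed_contig == 1 and rep.removed_maf == 1
        assert filt.loci["contig"].iloc[0] == "5"

    def test_identity_thresholds(self):
        gm = self.toy_matrix().take_loci([0, 1])  # autosomal, polymorphic
        th = QCThresholds(maf_min=0.0, miss_max=1.0, hwe_p_min=0.0, depth_min=0)
        filt, rep = apply_qc(gm, th)
        assert filt.n_loci == 2 and rep.n_pass == 2

    def test_idempotent(self, small_study):
        filt1, _ = apply_qc(small_study.genotypes)
        filt2, rep2 = apply_qc(filt1)
        assert filt2.n_loci == filt1.n_loci
        assert rep2.removed_miss == rep2.removed_maf == rep2.removed_hwe == 0
        assert np.allclose(filt1.dosages, filt2.dosages, equal_nan=True)

    def test_order_independence_of_survivor_set(self):
        # on complete data, miss/maf/hwe each depend only on the locus itself,
        # so the surviving set is the intersection regardless of order
        gm = self.toy_matrix()
        th = QCThresholds()
        filt, _ = apply_qc(gm, th)
        keep = (
            (gm.missing_rate() < th.miss_max)
            & (gm.maf() >= th.maf_min)
            & (gm.maf() > 0)
            & np.array([hwe_exact_test(*c) >= th.hwe_p_min for c in gm.genotype_counts()])
            & gm.loci["contig"].isin(th.autosomes).to_numpy()
        )
        assert filt.n_loci == keep.sum()

    def test_planted_violations_removed_exactly(self):
        cfg = SimulationConfig(
            n_animals=300, n_founders=60, n_snps=1000, seed=7,
            maf_range=(0.3, 0.5), low_maf_range=(0.01, 0.03),
            frac_nonautosomal=0.02, frac_low_depth=0.04,
            frac_high_missing=0.04, frac_low_maf=0.05, frac_hwe_violators=0.04,
        )
        study = simulate_study(cfg)
        gm = study.genotypes
        filt, rep = apply_qc(gm)
        clean = set(map(tuple, gm.loci[(gm.planted_flaw == "").to_numpy()]
                        [["contig", "pos"]].itertuples(index=False)))
        passed = set(map(tuple, filt.loci[["contig", "pos"]].itertuples(index=False)))
        assert passed == clean
        assert rep.removed_contig == int((gm.planted_flaw == "nonautosomal").sum())

    def test_zero_flaws_only_maf_boundary_possible(self):
        cfg = SimulationConfig(n_animals=300, n_founders=60, n_snps=400, seed=8,
                               maf_range=(0.25, 0.5))
        study = simulate_study(cfg)
        filt, rep = apply_qc(study.genotypes)
        assert rep.removed_contig == rep.removed_miss == rep.removed_hwe == 0
        assert filt.n_loci == 400

    def test_empty_survivor_set_flagged(self):
        gm = self.toy_matrix().take_loci([2])  # only the X-chromosome locus
        filt, rep = apply_qc(gm)
        assert filt.n_loci == 0 and "no locus survived QC" in rep.notes


class TestRoundTrips:
    def test_vcf_write_read(self, small_study, tmp_path):
        gm = small_study.genotypes
        write_vcf(gm, tmp_path / "x.vcf")
        back = read_vcf(tmp_path / "x.vcf")
        assert back.samples == [str(s) for s in gm.samples]
        assert np.allclose(back.dosages, gm.dosages, equal_nan=True)
        assert np.allclose(back.depths, gm.depths, equal_nan=True)
        pd.testing.assert_frame_equal(
            back.loci.astype({"pos": int}), gm.loci.astype({"pos": int})
        )

    def test_table_writer(self, small_study, tmp_path):
        gm, _ = apply_qc(small_study.genotypes)
        write_genotype_tables(gm, tmp_path / "d.tsv", tmp_path / "l.tsv")
        d = pd.read_csv(tmp_path / "d.tsv", sep="\t", index_col=0)
        assert d.shape == (gm.n_samples, gm.n_loci)
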