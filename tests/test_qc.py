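import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gqlscan.genotypes import (MISSING, read_plink_text, write_plink_text)
from gqlscan.qc import (QcThresholds, apply_qc, hwe_test, hwe_test_chisq)

from conftest import make_dataset
from _oracles import hwe_exact_enumeration


def write_files(tmp_path, ped_lines, map_lines):
    ped = tmp_path / "g.ped"
    mp = tmp_path / "g.map"
    ped.write_text("\n".join(ped_lines) + "\n")
    mp.write_text("\n".join(map_lines) + "\n")
    return ped, mp


class TestPlinkText:
    def test_allele1_counting(self, tmp_path):
        ped, mp = write_files(
            tmp_path,
            ["F a1 0 0 1 -9 A A", "F a2 0 0 2 -9 A G"],
            ["1 snp1 0 500"],
        )
        ds = read_plink_text(ped, mp)
        assert ds.animal_ids == ["a1", "a2"]
        np.testing.assert_array_equal(ds.calls[:, 0], [2, 1])
        assert ds.snps.allele1[0] == "A" and ds.snps.allele2[0] == "G"

    def test_zero_zero_is_missing(self, tmp_path):
        ped, mp = write_files(
            tmp_path, ["F a1 0 0 1 -9 0 0 A A"],
            ["1 s1 0 100", "1 s2 0 200"])
        ds = read_plink_text(ped, mp)
        assert ds.calls[0, 0] == MISSING and ds.calls[0, 1] == 2

    def test_column_parity_mismatch_raises(self, tmp_path):
        ped, mp = write_files(
            tmp_path, ["F a1 0 0 1 -9 A A G G G G G"],
            ["1 s%d 0 %d" % (j, 100 * j) for j in range(1, 5)])
        with pytest.raises(ValueError, match="line 1"):
            read_plink_text(ped, mp)

    def test_third_allele_raises(self, tmp_path):
        ped, mp = write_files(
            tmp_path, ["F a1 0 0 1 -9 A C", "F a2 0 0 1 -9 A T"],
            ["1 s1 0 100"])
        with pytest.raises(ValueError, match="two alleles"):
            read_plink_text(ped, mp)

    def test_roundtrip(self, tmp_path, small_cohort):
        ds = small_cohort.dataset
        write_plink_text(ds, tmp_path / "o.ped", tmp_path / "o.map")
        again = read_plink_text(tmp_path / "o.ped", tmp_path / "o.map")
        assert again.animal_ids == ds.animal_ids
        # allele1 of the rewritten file may differ per SNP; compare dosage
        # up to the allele swap
        for j in range(ds.n_snps):
            a, b = ds.calls[:, j], again.calls[:, j]
            miss = a == MISSING
            np.testing.assert_array_equal(miss, b == MISSING)
            ok = ~miss
            assert ((a[ok] == b[ok]).all() or (a[ok] == 2 - b[ok]).all())


class TestHweExactTest:
    def test_monomorphic_p_is_one(self):
        assert hwe_test(50, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [
        (25, 50, 25), (50, 0, 50), (10, 5, 2), (1, 1, 1), (0, 3, 97),
        (40, 20, 40), (3, 30, 67),
    ])
    def test_matches_exact_enumeration_oracle(self, counts):
        assert hwe_test(*counts) == pytest.approx(
            hwe_exact_enumeration(*counts), rel=1e-10)

    def test_extreme_heterozygote_deficit_is_tiny(self):
        assert hwe_test(50, 0, 50) < 1e-5

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_is_a_valid_conditional_p_value(self, naa, nab, nbb):
        # p in (0, 1], symmetric in the two homozygote classes
        if naa + nab + nbb == 0:
            return
        p = hwe_test(naa, nab, nbb)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_test(nbb, nab, naa), rel=1e-12)

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)

    def test_chisq_agrees_at_large_balanced_counts(self):
        # both tests should call a gross violation significant
        assert hwe_test_chisq(50, 0, 50) < 1e-5
        assert hwe_test_chisq(25, 50, 25) > 0.5


class TestApplyQc:
    def planted(self):
        """100 animals x 25 SNPs: 20 clean + one violation per rule.

        SNP20 MAF 0.04; SNP21 call rate < 0.90; SNP22 HWE (50,0,50);
        SNP23 chromosome X; SNP24 unknown position; animal 99 has call
        rate 20/23 < 0.90 after the map-based SNP removals.
        """
        rng = np.random.default_rng(7)
        n = 100
        hw = lambda p: rng.choice(
            [0, 1, 2], size=n, p=[(1 - p) ** 2, 2 * p * (1 - p), p * p])
        calls = np.column_stack([hw(0.3) for _ in range(25)]).astype(np.int8)
        calls[:, 20] = 0
        calls[np.arange(8), 20] = 1          # MAF = 8/200 = 0.04
        calls[:11, 21] = MISSING             # 88/99 genotyped post animal QC
        calls[:, 22] = np.repeat([2, 0], 50)  # (50,0,50): HWE violation
        calls[99, 10:13] = MISSING           # animal call rate 20/23
        chrom = ["1"] * 23 + ["X", "2"]
        pos = [100 * (j + 1) for j in range(24)] + [0]
        return make_dataset(calls, chrom=chrom, pos=pos)

    def test_planted_violation_counts_are_exact(self):
        ds, rep = apply_qc(self.planted())
        assert rep.removed_non_autosomal == 1
        assert rep.removed_unknown_position == 1
        assert rep.removed_animal_call_rate == 1
        assert rep.removed_maf == 1
        assert rep.removed_snp_call_rate == 1
        assert rep.removed_hwe == 1
        assert rep.n_snps_retained == 20
        assert rep.n_animals_retained == 99
        assert rep.snp_counts_reconcile and rep.animal_counts_reconcile

    def test_boundary_maf_and_call_rate_are_retained(self):
        rng = np.random.default_rng(3)
        n = 100
        hw = lambda p: rng.choice(
            [0, 1, 2], size=n, p=[(1 - p) ** 2, 2 * p * (1 - p), p * p])
        calls = np.column_stack([hw(0.3) for _ in range(22)]).astype(np.int8)
        calls[:, 20] = 0
        calls[:10, 20] = 1                 # MAF exactly 10/200 = 0.05
        calls[:, 21] = 1
        calls[:10, 21] = MISSING           # call rate exactly 0.90
        ds, rep = apply_qc(make_dataset(calls),
                           QcThresholds(hwe_p_min=0.0))
        assert rep.removed_maf == 0 and rep.removed_snp_call_rate == 0
        assert rep.removed_animal_call_rate == 0
        assert ds.n_snps == 22

    def test_low_call_rate_animal_removed(self):
        calls = np.ones((10, 10), dtype=np.int8)
        calls[0, :2] = MISSING             # animal call rate 0.8
        # MAF filter would kill everything; disable to isolate the rule
        thr = QcThresholds(maf_min=0.0, hwe_p_min=0.0)
        ds, rep = apply_qc(make_dataset(calls), thr)
        assert rep.removed_animal_call_rate == 1
        assert ds.n_animals == 9

    def test_idempotent(self, small_cohort):
        ds1, rep1 = apply_qc(small_cohort.dataset)
        ds2, rep2 = apply_qc(ds1)
        assert ds2.n_snps == ds1.n_snps
        assert ds2.n_animals == ds1.n_animals
        np.testing.assert_array_equal(ds1.calls, ds2.calls)

    def test_invalid_threshold_raises(self):
        with pytest.raises(ValueError):
            QcThresholds(maf_min=1.5)
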