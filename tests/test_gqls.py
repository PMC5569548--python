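import numpy as np
import pandas as pd
import pytest

from gqlscan.genotypes import MISSING
from gqlscan.gqls import (encode_genotypes, estimate_null_frequency,
                          gqls_statistic, run_scan)
from gqlscan.pedigree import build_relationship_matrix

from conftest import make_dataset
from _oracles import wg_dense
from _util import random_ainv


class TestEncodeGenotypes:
    def test_allele_counts_become_proportions(self):
        np.testing.assert_array_equal(
            encode_genotypes([0, 1, 2]), [0.0, 0.5, 1.0])

    def test_missing_preserved_as_nan(self):
        y = encode_genotypes([0, MISSING, 2])
        assert np.isnan(y[1])

    def test_all_homozygous(self):
        np.testing.assert_array_equal(encode_genotypes([2, 2, 2]), [1, 1, 1])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            encode_genotypes([0, 3, 1])


class TestNullFrequency:
    def test_identity_weights_reduce_to_mean(self):
        y = np.array([0.0, 0.5, 1.0, 1.0])
        assert estimate_null_frequency(y, np.eye(4)) == pytest.approx(
            y.mean())

    def test_constant_y_for_any_weights(self, rng):
        W = random_ainv(rng, 6)
        y = np.full(6, 0.5)
        assert estimate_null_frequency(y, W) == pytest.approx(0.5)

    def test_matches_dense_formula(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 15))
            W = random_ainv(rng, n)
            y = rng.integers(0, 3, n) / 2.0
            one = np.ones((n, 1))
            expected = (np.linalg.inv(one.T @ W @ one)
                        @ one.T @ W @ y.reshape(-1, 1)).item()
            assert estimate_null_frequency(y, W) == pytest.approx(
                expected, rel=1e-12)

    def test_conformability_error(self):
        with pytest.raises(ValueError):
            estimate_null_frequency(np.zeros(3), np.eye(4))


class TestGqlsStatistic:
    def test_hand_worked_example(self):
        # identity weights, X = Y in {0,0,1,1}: mu=1/2, s=1, M=1, WG=8
        res = gqls_statistic(np.array([0., 0, 1, 1]),
                             np.array([0., 0, 1, 1]), np.eye(4))
        assert res.status == "ok"
        assert res.mu_hat == pytest.approx(0.5)
        assert res.wg == pytest.approx(8.0, rel=1e-12)

    def test_monomorphic_snp_reported_not_raised(self):
        res = gqls_statistic(np.array([1., 2, 3]), np.zeros(3), np.eye(3))
        assert res.status == "monomorphic"
        assert np.isnan(res.p_value)

    def test_constant_covariate_is_degenerate(self):
        res = gqls_statistic(np.full(4, 2.5),
                             np.array([0., 0.5, 1, 0.5]), np.eye(4))
        assert res.status == "degenerate_covariate"

    def test_allele_swap_leaves_wg_unchanged(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 25))
            W = random_ainv(rng, n)
            x = rng.normal(size=n)
            y = rng.integers(0, 3, n) / 2.0
            a = gqls_statistic(x, y, W)
            b = gqls_statistic(x, 1.0 - y, W)
            if a.status == "ok":
                assert b.wg == pytest.approx(a.wg, rel=1e-10)

    def test_affine_covariate_invariance(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 25))
            W = random_ainv(rng, n)
            x = rng.normal(size=n)
            y = rng.integers(0, 3, n) / 2.0
            a = gqls_statistic(x, y, W)
            if a.status != "ok":
                continue
            scale, shift = rng.normal(), rng.normal()
            scale = scale if abs(scale) > 1e-3 else 1.0
            b = gqls_statistic(scale * x + shift, y, W)
            assert b.wg == pytest.approx(a.wg, rel=1e-10)

    def test_matches_dense_oracle_on_random_instances(self, rng):
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 31))
            W = random_ainv(rng, n)
            x = rng.normal(size=n)
            y = rng.integers(0, 3, n) / 2.0
            res = gqls_statistic(x, y, W)
            if res.status != "ok":
                continue
            assert res.wg == pytest.approx(wg_dense(x, y, W), rel=1e-10)
            assert res.wg >= 0 and 0 < res.p_value <= 1
            checked += 1

    def test_conformability_and_min_n(self):
        with pytest.raises(ValueError):
            gqls_statistic(np.zeros(3), np.zeros(4), np.eye(4))
        with pytest.raises(ValueError):
            gqls_statistic(np.zeros(2), np.zeros(2), np.eye(2))


class TestRunScan:
    def scan_inputs(self, rng, n=30, k=8):
        calls = rng.integers(0, 3, size=(n, k)).astype(np.int8)
        calls[:, 2] = 0  # monomorphic column
        ds = make_dataset(calls)
        trait = pd.Series(rng.normal(size=n), index=ds.animal_ids)
        return ds, trait

    def test_monomorphic_row_flagged_others_ok(self, rng):
        ds, trait = self.scan_inputs(rng)
        out = run_scan(ds, trait)
        assert out.status[2] == "monomorphic"
        assert (out.status.drop(2) == "ok").all()

    def test_complete_data_uses_every_animal(self, rng):
        ds, trait = self.scan_inputs(rng)
        assert (run_scan(ds, trait).n_used == 30).all()

    def test_unrelated_scan_equals_direct_statistic(self, rng):
        ds, trait = self.scan_inputs(rng)
        out = run_scan(ds, trait)
        x = trait.to_numpy()
        for j in range(ds.n_snps):
            res = gqls_statistic(x, ds.calls[:, j] / 2.0, np.eye(30))
            if res.status == "ok":
                assert out.wg[j] == pytest.approx(res.wg, rel=1e-12)

    def test_missing_calls_drop_to_complete_case(self, rng, small_cohort):
        coh = small_cohort
        A = build_relationship_matrix(coh.pedigree)
        ds = coh.dataset
        out = run_scan(ds, coh.trait, A)
        Asub = A.submatrix(ds.animal_ids).values
        x_all = coh.trait.loc[ds.animal_ids].to_numpy()
        for j in rng.choice(ds.n_snps, 12, replace=False):
            col = ds.calls[:, j]
            obs = col != MISSING
            W = np.linalg.inv(Asub[np.ix_(*2 * (np.flatnonzero(obs),))])
            res = gqls_statistic(x_all[obs], col[obs] / 2.0, W)
            assert out.n_used[j] == obs.sum()
            if res.status == "ok":
                assert out.wg[j] == pytest.approx(res.wg, rel=1e-9)

    def test_disjoint_ids_raise(self, rng):
        ds, _ = self.scan_inputs(rng)
        trait = pd.Series([1.0, 2.0], index=["zz1", "zz2"])
        with pytest.raises(ValueError):
            run_scan(ds, trait)
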