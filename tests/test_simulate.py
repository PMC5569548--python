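import numpy as np
import pytest
from dataclasses import replace

from gqlscan.genotypes import MISSING
from gqlscan.pedigree import build_relationship_matrix
from gqlscan.simulate import (SimConfig, gene_drop, simulate_cohort,
                              simulate_ebv, simulate_pedigree)

SMALL = SimConfig(seed=99, sires_per_generation=8, dams_per_generation=40,
                  offspring_per_generation=50, n_chromosomes=2,
                  snps_per_chrom=40)


class TestSimulatePedigree:
    def test_zero_generations_gives_founders_only(self):
        cfg = replace(SMALL, n_generations=0)
        ped = simulate_pedigree(cfg)
        assert len(ped) == cfg.n_founders
        assert len(ped.founders) == len(ped)

    def test_determinism(self):
        a = simulate_pedigree(SMALL)
        b = simulate_pedigree(SMALL)
        assert a.records == b.records

    def test_half_sib_structure_sires_reused_more_than_dams(self):
        from collections import Counter
        means = []
        for seed in range(20):
            ped = simulate_pedigree(replace(SMALL, seed=seed))
            sires = Counter(s for _, s, _ in ped.records if s)
            dams = Counter(d for _, _, d in ped.records if d)
            means.append((np.mean(list(sires.values())),
                          np.mean(list(dams.values()))))
        sire_mean = np.mean([m[0] for m in means])
        dam_mean = np.mean([m[1] for m in means])
        assert sire_mean > 2 * dam_mean

    def test_no_founders_raises(self):
        with pytest.raises(ValueError):
            simulate_pedigree(replace(SMALL, sires_per_generation=0,
                                      dams_per_generation=0))


class TestGeneDrop:
    def test_determinism(self):
        ped = simulate_pedigree(SMALL)
        ds1, t1 = gene_drop(ped, SMALL)
        ds2, t2 = gene_drop(ped, SMALL)
        np.testing.assert_array_equal(ds1.calls, ds2.calls)
        np.testing.assert_array_equal(t1.true_freq, t2.true_freq)

    def test_zero_missing_rate_leaves_no_gaps(self):
        cfg = replace(SMALL, missing_rate=0.0)
        ds, _ = gene_drop(simulate_pedigree(cfg), cfg)
        assert (ds.calls != MISSING).all()

    def test_missing_rate_respected(self):
        cfg = replace(SMALL, missing_rate=0.1)
        ds, _ = gene_drop(simulate_pedigree(cfg), cfg)
        frac = (ds.calls == MISSING).mean()
        assert frac == pytest.approx(0.1, abs=0.02)

    def test_mendelian_consistency_no_opposite_homozygotes(self):
        ped = simulate_pedigree(SMALL)
        _, truth = gene_drop(ped, SMALL)
        idx = {a: i for i, a in enumerate(truth.all_ids)}
        for child, sire, dam in ped.records:
            for parent in (sire, dam):
                if parent is None:
                    continue
                c = truth.all_calls[idx[child]]
                p = truth.all_calls[idx[parent]]
                assert not (((c == 0) & (p == 2)) | ((c == 2) & (p == 0))).any()

    def test_sample_frequency_tracks_true_frequency(self):
        # founders are i.i.d. draws from the haplotype model; offspring
        # frequencies stay within a few standard errors of the truth
        cfg = replace(SMALL, seed=5, missing_rate=0.0,
                      offspring_per_generation=200)
        ped = simulate_pedigree(cfg)
        ds, truth = gene_drop(ped, cfg)
        p_hat = ds.allele_freq()
        se = np.sqrt(truth.true_freq * (1 - truth.true_freq)
                     / (2 * ds.n_animals))
        # relatedness inflates the sampling variance; allow a wide band
        frac_inside = (np.abs(p_hat - truth.true_freq) < 6 * se + 0.02).mean()
        assert frac_inside > 0.9

    def test_true_r2_table_covers_within_block_pairs(self):
        cfg = replace(SMALL, block_length=5)
        _, truth = gene_drop(simulate_pedigree(cfg), cfg)
        L, B = 5, cfg.n_snps // 5
        assert len(truth.true_r2) == B * L * (L - 1) // 2
        assert ((truth.true_r2.r2 >= 0) & (truth.true_r2.r2 <= 1)).all()


class TestSimulateEbv:
    def test_degenerate_limit_trait_determined_by_genotype(self):
        cfg = replace(SMALL, polygenic_variance=0.0, residual_variance=0.0,
                      n_causal=1, causal_effect=1.0, missing_rate=0.0)
        ped = simulate_pedigree(cfg)
        ds, truth = gene_drop(ped, cfg)
        trait = simulate_ebv(ped, ds, truth, cfg)
        j = ds.snps.snp_id.tolist().index(truth.causal.snp_id.iloc[0])
        np.testing.assert_allclose(trait.to_numpy(),
                                   truth.raw_calls[:, j].astype(float))

    def test_determinism(self):
        coh1 = simulate_cohort(SMALL)
        coh2 = simulate_cohort(SMALL)
        np.testing.assert_array_equal(coh1.trait.to_numpy(),
                                      coh2.trait.to_numpy())

    def test_polygenic_covariance_scales_with_relationship(self):
        # regression of realized cross-products on A entries recovers the
        # polygenic variance; sib pairs covary more than unrelated pairs
        cfg = replace(SMALL, seed=1, polygenic_variance=1.0,
                      residual_variance=0.0, missing_rate=0.0)
        ped = simulate_pedigree(cfg)
        ds0, _ = gene_drop(ped, cfg)
        ids = ds0.animal_ids
        A = build_relationship_matrix(ped).submatrix(ids)
        prods = []
        for rep in range(150):
            c = replace(cfg, seed=1000 + rep)
            ds, truth = gene_drop(ped, c)
            u = simulate_ebv(ped, ds, truth, c).loc[ids].to_numpy()
            prods.append(np.outer(u, u))
        emp = np.mean(prods, axis=0)
        a = A.values.ravel()
        slope = np.polyfit(a, emp.ravel(), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)

    def test_missing_causal_snp_raises(self):
        cfg = replace(SMALL, n_causal=1, causal_effect=1.0)
        ped = simulate_pedigree(cfg)
        ds, truth = gene_drop(ped, cfg)
        truth.causal.loc[0, "snp_id"] = "nope"
        with pytest.raises(ValueError, match="nope"):
            simulate_ebv(ped, ds, truth, cfg)
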