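"""Validation experiments exercising the whole pipeline on synthetic data.

Each function runs a self-contained, seeded experiment at desk scale and
returns the quantities it measured.  They are used both by the acceptance
checks and by the reproduction script, so every number they report is
recomputed from scratch at call time.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING
from .gqls import encode_genotypes, gqls_statistic, run_scan
from .ld import em_haplotype_freqs, r_squared
from .multiple_testing import classify
from .pedigree import build_relationship_matrix, subset_and_invert
from .qc import apply_qc
from .simulate import SimConfig, gene_drop, simulate_ebv, simulate_pedigree


def _wg_dense_reference(x: np.ndarray, y: np.ndarray, W: np.ndarray) -> float:
    """Plain matrix-expression evaluation of the score statistic, used as a
    cross-check for the O(n) scan path."""
    x = x.reshape(-1, 1)
    y = y.reshape(-1, 1)
    one = np.ones_like(x)
    mu = (np.linalg.inv(one.T @ W @ one) @ (one.T @ W @ y)).item()
    s = x.T @ W @ (y - mu * one)
    m = (x.T @ W @ x - (x.T @ W @ one) @ np.linalg.inv(one.T @ W @ one)
         @ (one.T @ W @ x))
    return (2.0 / (mu * (1 - mu)) * s.T @ np.linalg.inv(m) @ s).item()


def _random_ainv(rng: np.random.Generator, n: int) -> np.ndarray:
    """A^-1 for a random subset of a random pedigree."""
    rows = []
    total = n + int(rng.integers(0, 5))
    for i in range(total):
        if i < 2 or rng.random() < 0.3:
            rows.append((f"A{i}", None, None))
        else:
            s, d = rng.choice(i, 2, replace=False)
            rows.append((f"A{i}", f"A{s}", f"A{d}"))
    from .pedigree import Pedigree
    A = build_relationship_matrix(Pedigree.from_records(rows))
    ids = list(rng.choice(A.ids, size=n, replace=False))
    try:
        return subset_and_invert(A, ids).values
    except np.linalg.LinAlgError:
        return np.eye(n)


def oracle_agreement(seed: int, n_instances: int = 100) -> dict:
    """Max relative deviation between the scan statistic and the dense
    reference evaluation over random related-cohort instances (n <= 30)."""
    rng = np.random.default_rng([seed, 10])
    worst = 0.0
    done = 0
    while done < n_instances:
        n = int(rng.integers(4, 31))
        W = _random_ainv(rng, n)
        x = rng.normal(size=n)
        y = rng.integers(0, 3, n) / 2.0
        res = gqls_statistic(x, y, W)
        if res.status != "ok":
            continue
        ref = _wg_dense_reference(x, y, W)
        worst = max(worst, abs(res.wg - ref) / max(abs(ref), 1e-12))
        done += 1
    return {"max_rel_error": worst, "n": n_instances}


def invariance_suite(seed: int, n_cases: int = 1000) -> dict:
    """Affine-covariate and allele-swap invariance of WG."""
    rng = np.random.default_rng([seed, 11])
    worst_affine = worst_swap = 0.0
    done = 0
    while done < n_cases:
        n = int(rng.integers(5, 30))
        W = _random_ainv(rng, n)
        x = rng.normal(size=n)
        y = rng.integers(0, 3, n) / 2.0
        base = gqls_statistic(x, y, W)
        if base.status != "ok":
            continue
        a = rng.uniform(0.2, 5.0) * rng.choice([-1.0, 1.0])
        b = rng.normal(scale=3.0)
        affine = gqls_statistic(a * x + b, y, W)
        swap = gqls_statistic(x, 1.0 - y, W)
        denom = max(base.wg, 1e-12)  # WG can be exactly 0 for orthogonal Y
        worst_affine = max(worst_affine, abs(affine.wg - base.wg) / denom)
        worst_swap = max(worst_swap, abs(swap.wg - base.wg) / denom)
        done += 1
    return {"max_rel_dev_affine": worst_affine,
            "max_rel_dev_swap": worst_swap, "n": n_cases}


def kinship_validation(seed: int, n_pedigrees: int = 100,
                       max_n: int = 200) -> dict:
    """A * A^-1 = I over random pedigrees; returns the worst deviation."""
    rng = np.random.default_rng([seed, 12])
    from .pedigree import Pedigree
    worst = 0.0
    for _ in range(n_pedigrees):
        n = int(rng.integers(5, max_n + 1))
        rows = []
        for i in range(n):
            if i < 2 or rng.random() < 0.25:
                rows.append((f"A{i}", None, None))
            else:
                s, d = rng.choice(i, 2, replace=False)
                rows.append((f"A{i}", f"A{s}", f"A{d}"))
        A = build_relationship_matrix(Pedigree.from_records(rows))
        k = int(rng.integers(3, n + 1))
        ids = list(rng.choice(A.ids, size=k, replace=False))
        try:
            inv = subset_and_invert(A, ids)
        except np.linalg.LinAlgError:
            continue
        dev = np.abs(A.submatrix(ids).values @ inv.values - np.eye(k)).max()
        worst = max(worst, float(dev))
    return {"max_identity_dev": worst, "n": n_pedigrees}


def default_cohort_config(seed: int, **overrides) -> SimConfig:
    """The standard validation cohort: 49 sires, 355 dams, 399 calves."""
    return SimConfig(seed=seed, **overrides)


def null_calibration(seed: int, n_snps: int = 10_000) -> dict:
    """Gene-drop null SNPs, polygenic-only EBV, full-pedigree weighting.

    Measures the empirical type-I error of the score test at alpha = 0.05
    and the Kolmogorov-Smirnov p-value of WG against chi-squared(1).  The
    null SNPs are simulated without LD (one SNP per block): the KS
    comparison treats the per-SNP statistics as independent draws, which
    within-block LD would violate.
    """
    chrom = 10
    cfg = default_cohort_config(seed, n_chromosomes=chrom,
                                snps_per_chrom=n_snps // chrom,
                                block_length=1)
    ped = simulate_pedigree(cfg)
    ds, truth = gene_drop(ped, cfg)
    trait = simulate_ebv(ped, ds, truth, cfg)
    A = build_relationship_matrix(ped)
    assoc = run_scan(ds, trait, A)
    ok = assoc[assoc.status == "ok"]
    ks = stats.kstest(ok.wg.to_numpy(), stats.chi2(1).cdf)
    return {
        "type_i_error_alpha05": float((ok.p_value < 0.05).mean()),
        "ks_p_value": float(ks.pvalue),
        "n": int(len(ok)),
        "n_animals": ds.n_animals,
    }


def power_study(seed: int, n_replicates: int = 50) -> dict:
    """One causal SNP at half a residual SD per allele copy, ~400 animals.

    Reports how often the causal SNP ranks first genome-wide and how often
    it carries the chromosome-wise FDR-10% (suggestive) flag.
    """
    base = default_cohort_config(seed, n_chromosomes=5, snps_per_chrom=100,
                                 n_causal=1)
    base = replace(base,
                   causal_effect=0.5 * float(np.sqrt(base.residual_variance)))
    ped = simulate_pedigree(base)
    A = build_relationship_matrix(ped)
    top1 = flagged = 0
    for rep in range(n_replicates):
        cfg = replace(base, seed=(seed + 7919 * (rep + 1)) % (2**31))
        ds, truth = gene_drop(ped, cfg)
        trait = simulate_ebv(ped, ds, truth, cfg)
        fl = classify(run_scan(ds, trait, A))
        causal = truth.causal.snp_id.iloc[0]
        ok = fl[fl.status == "ok"]
        top1 += int(ok.sort_values("p_value").snp_id.iloc[0] == causal)
        flagged += int(fl.loc[fl.snp_id == causal, "cw_fdr10"].iloc[0])
    return {"top1_fraction": top1 / n_replicates,
            "cw_fdr10_fraction": flagged / n_replicates,
            "n": n_replicates}


def ld_recovery(seed: int) -> dict:
    """EM r^2 vs the generator's analytic within-block truth at n ~ 400."""
    cfg = default_cohort_config(seed, n_chromosomes=2, snps_per_chrom=100)
    ped = simulate_pedigree(cfg)
    ds, truth = gene_drop(ped, cfg)
    pos = {s: j for j, s in enumerate(ds.snps.snp_id)}
    errs = []
    for r in truth.true_r2.itertuples(index=False):
        if np.isnan(r.r2):
            continue
        try:
            est = r_squared(em_haplotype_freqs(ds.calls[:, pos[r.snp1]],
                                               ds.calls[:, pos[r.snp2]]))
        except ValueError:
            continue
        if not np.isnan(est):
            errs.append(abs(est - r.r2))
    errs = np.asarray(errs)
    return {"mean_abs_error": float(errs.mean()),
            "p90_abs_error": float(np.quantile(errs, 0.9)),
            "n": int(errs.size), "n_animals": ds.n_animals}


def full_study(seed: int) -> dict:
    """End-to-end synthetic GWAS: QC, scan, FDR, LD among flagged SNPs.

    The cohort carries two causal SNPs so the discovery stages have signal
    to find; everything downstream runs exactly as on real inputs.
    """
    cfg = default_cohort_config(seed, n_chromosomes=5, snps_per_chrom=200,
                                n_causal=2)
    cfg = replace(cfg,
                  causal_effect=0.6 * float(np.sqrt(cfg.residual_variance)))
    ped = simulate_pedigree(cfg)
    ds_raw, truth = gene_drop(ped, cfg)
    trait = simulate_ebv(ped, ds_raw, truth, cfg)
    ds, report = apply_qc(ds_raw)
    A = build_relationship_matrix(ped)
    fl = classify(run_scan(ds, trait, A))

    selected = fl.loc[fl.cw_fdr10, "snp_id"]
    from .ld import ld_summary
    ld = ld_summary(ds, selected)
    mean_r2 = {c: m.mean_r2 for c, m in ld.items()}
    causal_rank = []
    ok = fl[fl.status == "ok"].sort_values("p_value").reset_index()
    for snp in truth.causal.snp_id:
        where = np.flatnonzero(ok.snp_id == snp)
        causal_rank.append(int(where[0]) + 1 if where.size else None)
    return {
        "qc_snps_retained": report.n_snps_retained,
        "qc_animals_retained": report.n_animals_retained,
        "n_cw_fdr10": int(fl.cw_fdr10.sum()),
        "n_gw_fdr10": int(fl.gw_fdr10.sum()),
        "n_gw_fdr05": int(fl.gw_fdr05.sum()),
        "best_causal_rank": min(r for r in causal_rank if r is not None),
        "mean_r2_flagged": mean_r2,
    }
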