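"""Simulate the study cohort: pedigree, SNP genotypes, and two EBV traits.

The cohort mirrors a single-generation half-sib beef-cattle design
(49 sires, 355 dams, 399 genotyped calves) with 1,000 SNPs on 5 chromosomes
in 10-SNP LD blocks.  Trait "sc420" carries two planted causal SNPs
(0.6 residual SD per allele copy); trait "afc" is purely polygenic, so any
hit on it downstream is a false positive.  Inputs for the later stages are
written as plain-text files (pedigree, PLINK PED/MAP, trait files, a
synthetic GFF3 of gene models) plus the generator's truth tables.
"""

import argparse
from dataclasses import replace

import numpy as np
import pandas as pd

from gqlscan.genotypes import write_plink_text, write_trait
from gqlscan.pedigree import write_pedigree
from gqlscan.simulate import SimConfig, gene_drop, simulate_ebv, \
    simulate_pedigree

from _paths import DATA, RESULTS


def write_synthetic_gff3(path, cfg: SimConfig, rng: np.random.Generator,
                         genes_per_chrom: int = 25) -> int:
    """Random gene models spanning the simulated chromosomes (synthetic)."""
    span = cfg.snps_per_chrom * cfg.snp_spacing_bp
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in range(1, cfg.n_chromosomes + 1):
            starts = np.sort(rng.integers(1, span, genes_per_chrom))
            for i, s in enumerate(starts):
                e = int(s + rng.integers(5_000, 100_000))
                strand = "+" if rng.random() < 0.5 else "-"
                n += 1
                fh.write(f"{c}\tsim\tgene\t{s}\t{e}\t.\t{strand}\t.\t"
                         f"ID=simg{c}_{i};Name=SIMG{c}_{i}\n")
    return n


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed, n_chromosomes=5, snps_per_chrom=200,
                    n_causal=2)
    cfg = replace(cfg,
                  causal_effect=0.6 * float(np.sqrt(cfg.residual_variance)))
    ped = simulate_pedigree(cfg)
    ds, truth = gene_drop(ped, cfg)
    trait_sc = simulate_ebv(ped, ds, truth, cfg)
    null_cfg = replace(cfg, seed=(args.seed + 104729) % (2**31), n_causal=0)
    trait_afc = simulate_ebv(ped, ds, replace(truth, causal=truth.causal[:0]),
                             null_cfg)

    write_pedigree(ped, DATA / "pedigree.tsv")
    write_plink_text(ds, DATA / "geno.ped", DATA / "geno.map")
    write_trait(trait_sc, DATA / "trait_sc420.tsv")
    write_trait(trait_afc, DATA / "trait_afc.tsv")
    truth.true_r2.to_csv(DATA / "truth_r2.tsv", sep="\t", index=False,
                         float_format="%.6g")
    n_genes = write_synthetic_gff3(
        DATA / "synthetic_genes.gff3", cfg,
        np.random.default_rng([cfg.seed % (2**31), 99]))

    summary = pd.DataFrame([
        ("animals_genotyped", ds.n_animals),
        ("pedigree_animals", len(ped)),
        ("founder_sires", cfg.sires_per_generation),
        ("founder_dams", cfg.dams_per_generation),
        ("snps", ds.n_snps),
        ("chromosomes", cfg.n_chromosomes),
        ("ld_block_length", cfg.block_length),
        ("causal_snps_sc420", len(truth.causal)),
        ("causal_effect_per_allele", round(cfg.causal_effect, 4)),
        ("polygenic_variance", cfg.polygenic_variance),
        ("residual_variance", cfg.residual_variance),
        ("missing_call_rate", cfg.missing_rate),
        ("gene_models", n_genes),
    ], columns=["quantity", "value"])
    summary.to_csv(RESULTS / "01_cohort_summary.tsv", sep="\t", index=False)
    truth.causal.to_csv(RESULTS / "01_true_causal_snps.tsv", sep="\t",
                        index=False)

    print(f"cohort: {ds.n_animals} genotyped calves of "
          f"{cfg.sires_per_generation} sires / {cfg.dams_per_generation} "
          f"dams; {ds.n_snps} SNPs on {cfg.n_chromosomes} chromosomes")
    print("causal SNPs for sc420:",
          ", ".join(truth.causal.snp_id), f"(effect {cfg.causal_effect:.3f})")
    print(f"inputs in {DATA}, summaries in {RESULTS}")


if __name__ == "__main__":
    main()
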