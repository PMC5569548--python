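"""Linkage disequilibrium among the flagged (suggestive) SNPs.

Pairwise r^2 from EM haplotype-frequency estimates, within chromosome,
among SNPs carrying the chromosome-wise FDR-10% flag; the per-chromosome
mean r^2 is compared against the generator's analytic truth where both are
defined.
"""

import numpy as np
import pandas as pd

from gqlscan.genotypes import read_plink_text
from gqlscan.ld import ld_summary

from _paths import DATA, INTERMEDIATE, RESULTS, TRAITS


def main() -> None:
    ds = read_plink_text(INTERMEDIATE / "qc.ped", INTERMEDIATE / "qc.map")
    truth = pd.read_csv(DATA / "truth_r2.tsv", sep="\t",
                        dtype={"chrom": str})
    true_pairs = {frozenset((a, b)): r
                  for a, b, r in zip(truth.snp1, truth.snp2, truth.r2)}
    rows = []
    for trait_name in TRAITS:
        flagged = pd.read_csv(INTERMEDIATE / f"flagged_{trait_name}.tsv",
                              sep="\t", dtype={"chrom": str})
        selected = flagged.loc[flagged.cw_fdr10, "snp_id"]
        for chrom, mat in ld_summary(ds, selected).items():
            truths = [true_pairs.get(frozenset((a, b)), np.nan)
                      for i, a in enumerate(mat.snp_ids)
                      for b in mat.snp_ids[i + 1:]]
            truths = np.asarray(truths, dtype=float)
            rows.append((trait_name, chrom, len(mat.snp_ids), mat.n_pairs,
                         round(mat.mean_r2, 4),
                         round(float(np.nanmean(truths)), 4)
                         if np.isfinite(truths).any() else ""))
    out = pd.DataFrame(rows, columns=["trait", "chrom", "n_snps", "n_pairs",
                                      "mean_r2", "true_mean_r2_same_block"])
    out.to_csv(RESULTS / "06_ld_summary.tsv", sep="\t", index=False)
    if len(out):
        print(out.to_string(index=False))
    else:
        print("no chromosome had >= 2 flagged SNPs; no LD to report")


if __name__ == "__main__":
    main()
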