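"""GQLS association scan of each trait against the QC-passed SNPs.

One SNP at a time, the genotype proportion is regressed on the trait EBV
with inverse-relationship-matrix weighting; WG ~ chi2(1) under the null.
Full association tables go to scratch; the top 15 SNPs per trait by
p-value are summarized under results/.
"""

from gqlscan.genotypes import read_plink_text, read_trait
from gqlscan.gqls import run_scan
from gqlscan.pedigree import build_relationship_matrix, read_pedigree

from _paths import DATA, INTERMEDIATE, RESULTS, TRAITS


def main() -> None:
    ped = read_pedigree(DATA / "pedigree.tsv")
    ds = read_plink_text(INTERMEDIATE / "qc.ped", INTERMEDIATE / "qc.map")
    A = build_relationship_matrix(ped)
    for trait_name in TRAITS:
        trait = read_trait(DATA / f"trait_{trait_name}.tsv")
        assoc = run_scan(ds, trait, A)
        assoc.to_csv(INTERMEDIATE / f"assoc_{trait_name}.tsv", sep="\t",
                     index=False, float_format="%.6g")
        top = assoc[assoc.status == "ok"].nsmallest(15, "p_value")
        top.to_csv(RESULTS / f"04_top_hits_{trait_name}.tsv", sep="\t",
                   index=False, float_format="%.3e")
        best = top.iloc[0]
        print(f"{trait_name}: {int((assoc.status == 'ok').sum())} SNPs "
              f"tested; best {best.snp_id} (chr{best.chrom}) "
              f"p={best.p_value:.2e}")


if __name__ == "__main__":
    main()
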