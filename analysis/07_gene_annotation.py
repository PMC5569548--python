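"""Nearest-gene annotation of the flagged SNPs.

Each suggestive SNP is mapped onto the synthetic gene models: intragenic
hits get distance 0.00 kb, intergenic SNPs the distance to the co-nearest
gene(s) with an upstream/downstream label relative to gene strand.
"""

import pandas as pd

from gqlscan.annotate import annotate_table, load_gene_models

from _paths import DATA, INTERMEDIATE, RESULTS, TRAITS


def main() -> None:
    genes = load_gene_models(DATA / "synthetic_genes.gff3")
    frames = []
    for trait_name in TRAITS:
        flagged = pd.read_csv(INTERMEDIATE / f"flagged_{trait_name}.tsv",
                              sep="\t", dtype={"chrom": str})
        hits = flagged[flagged.cw_fdr10]
        if hits.empty:
            continue
        ann = annotate_table(hits, genes)
        ann.insert(0, "trait", trait_name)
        frames.append(ann)
    if frames:
        out = pd.concat(frames, ignore_index=True)
        out.to_csv(RESULTS / "07_annotation.tsv", sep="\t", index=False,
                   float_format="%.6g")
        intragenic = int((out.distance_kb == 0).sum())
        print(f"annotated {len(out)} flagged SNPs against {len(genes)} "
              f"genes; {intragenic} intragenic, "
              f"{len(out) - intragenic} intergenic")
        print(out.head(10).to_string(index=False))
    else:
        print("no flagged SNPs to annotate")


if __name__ == "__main__":
    main()
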