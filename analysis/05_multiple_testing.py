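"""Multiple-testing correction and significance classification.

Benjamini-Hochberg FDR at 5% (significant) and 10% (suggestive), each both
genome-wide and chromosome-wise, plus genome-wide Bonferroni at 5%.  The
flagged association tables (with the Manhattan-ready -log10 p column) go to
scratch; per-scope rejection counts land under results/.
"""

import pandas as pd

from gqlscan.multiple_testing import classify, flag_summary
from gqlscan.pipeline import manhattan_table

from _paths import INTERMEDIATE, RESULTS, TRAITS


def main() -> None:
    for trait_name in TRAITS:
        assoc = pd.read_csv(INTERMEDIATE / f"assoc_{trait_name}.tsv",
                            sep="\t", dtype={"chrom": str})
        flagged = classify(assoc)
        flagged.to_csv(INTERMEDIATE / f"flagged_{trait_name}.tsv", sep="\t",
                       index=False, float_format="%.6g")
        manhattan_table(flagged).to_csv(
            INTERMEDIATE / f"manhattan_{trait_name}.tsv", sep="\t",
            index=False, float_format="%.6g")
        summ = flag_summary(flagged)
        summ.to_csv(RESULTS / f"05_fdr_summary_{trait_name}.tsv", sep="\t",
                    index=False)
        counts = {f"{r.scope}/{r.level}": r.n_rejected
                  for r in summ.itertuples(index=False)}
        print(f"{trait_name}: rejections {counts}")


if __name__ == "__main__":
    main()
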