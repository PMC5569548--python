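"""Apply chip QC to the simulated genotypes.

Standard livestock-chip filters: HWE exact-test P < 1e-5, MAF < 0.05,
SNP/animal call rate < 0.90, autosomes with known positions only.  Writes
the filtered dataset back out as PED/MAP for the downstream stages and the
reconciled removal counts as the QC report.
"""

from gqlscan.genotypes import read_plink_text, write_plink_text
from gqlscan.qc import QcThresholds, apply_qc

from _paths import DATA, INTERMEDIATE, RESULTS


def main() -> None:
    ds = read_plink_text(DATA / "geno.ped", DATA / "geno.map")
    filtered, report = apply_qc(ds, QcThresholds())
    write_plink_text(filtered, INTERMEDIATE / "qc.ped",
                     INTERMEDIATE / "qc.map")
    report.to_frame().to_csv(RESULTS / "02_qc_report.tsv", sep="\t",
                             index=False)
    print(f"QC: {ds.n_snps} -> {report.n_snps_retained} SNPs "
          f"({report.removed_maf} by MAF, {report.removed_hwe} by HWE, "
          f"{report.removed_snp_call_rate} by call rate); "
          f"{ds.n_animals} -> {report.n_animals_retained} animals")


if __name__ == "__main__":
    main()
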