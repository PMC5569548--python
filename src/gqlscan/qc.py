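"""SNP-chip quality control.

Filters mirror standard chip QC for livestock GWAS: drop SNPs deviating from
Hardy-Weinberg equilibrium (exact test, P < 1e-5), with minor allele
frequency below 0.05, or call rate below 0.90; drop animals with call rate
below 0.90; keep autosomal SNPs with known map positions only.

Stage order (fixed, logged in the report): (1) non-autosomal / unknown
position SNPs out, (2) low-call-rate animals out, (3) per-SNP statistics
recomputed on the retained animals, (4) SNPs filtered by call rate, MAF and
HWE.  "Less than" thresholds get a 1e-9 guard so exact boundary ratios
(e.g. MAF = 18/360 = 0.05) are retained despite float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .genotypes import MISSING, GenotypeDataset

BOVINE_AUTOSOMES = frozenset(str(c) for c in range(1, 30))
_EPS = 1e-9

__all__ = ["QcThresholds", "QcReport", "hwe_test", "hwe_test_chisq",
           "apply_qc", "BOVINE_AUTOSOMES"]


@dataclass(frozen=True)
class QcThresholds:
    """QC thresholds; strict "less than" semantics throughout."""

    hwe_p_min: float = 1e-5
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    autosomes_only: bool = True
    require_known_position: bool = True
    autosome_labels: frozenset[str] = BOVINE_AUTOSOMES
    hwe_method: str = "exact"  # or "chisq"

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "maf_min", "call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.hwe_method not in ("exact", "chisq"):
            raise ValueError(f"unknown hwe_method {self.hwe_method!r}")


@dataclass
class QcReport:
    """Per-rule removal counts; removed + retained reconcile to the input."""

    n_snps_in: int
    n_animals_in: int
    removed_non_autosomal: int = 0
    removed_unknown_position: int = 0
    removed_snp_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_animal_call_rate: int = 0
    n_snps_retained: int = 0
    n_animals_retained: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def snp_counts_reconcile(self) -> bool:
        removed = (self.removed_non_autosomal + self.removed_unknown_position
                   + self.removed_snp_call_rate + self.removed_maf
                   + self.removed_hwe)
        return removed + self.n_snps_retained == self.n_snps_in

    @property
    def animal_counts_reconcile(self) -> bool:
        return (self.removed_animal_call_rate + self.n_animals_retained
                == self.n_animals_in)

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        d["thresholds"] = repr(d["thresholds"])
        return pd.DataFrame({"key": list(d), "value": [d[k] for k in d]})


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, enumerates every heterozygote
    count of matching parity and sums the probability mass of configurations
    no more probable than the observed one (the SNP-HWE exact test of
    Wigginton et al.).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped animals")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    rare = min(nA, na)
    if rare == 0:
        return 1.0  # monomorphic: single attainable configuration
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = (max(nA, na) - hets) // 2
    # log P(h | allele counts) up to the common normalizer
    logp = (hets * np.log(2.0) - gammaln(homr + 1) - gammaln(hets + 1)
            - gammaln(homc + 1))
    logp -= logsumexp(logp)
    obs = np.flatnonzero(hets == n_Aa)[0]
    p = float(np.exp(logsumexp(logp[logp <= logp[obs] + 1e-12])))
    return min(p, 1.0)


def hwe_test_chisq(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Asymptotic 1-df chi-square HWE test (config alternative)."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped animals")
    p = (2 * n_AA + n_Aa) / (2.0 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(chi2.sf(stat, df=1))


def _hwe_pvalues(ds: GenotypeDataset, method: str) -> np.ndarray:
    test = hwe_test if method == "exact" else hwe_test_chisq
    out = np.ones(ds.n_snps)
    for j in range(ds.n_snps):
        col = ds.calls[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        out[j] = test(int((col == 2).sum()), int((col == 1).sum()),
                      int((col == 0).sum()))
    return out


def apply_qc(
    ds: GenotypeDataset, thr: QcThresholds = QcThresholds()
) -> tuple[GenotypeDataset, QcReport]:
    """Apply all QC filters; returns the filtered dataset and the report.

    A SNP failing several rules is counted once, under the first failing rule
    in the fixed order (non-autosomal, unknown position, call rate, MAF, HWE),
    so the report's removed + retained counts partition the input.
    """
    report = QcReport(n_snps_in=ds.n_snps, n_animals_in=ds.n_animals,
                      thresholds={
                          "hwe_p_min": thr.hwe_p_min, "maf_min": thr.maf_min,
                          "call_rate_min": thr.call_rate_min,
                          "hwe_method": thr.hwe_method,
                      })

    chrom = ds.snps["chrom"].astype(str).to_numpy()
    pos = ds.snps["pos"].to_numpy()
    bad_auto = (~np.isin(chrom, list(thr.autosome_labels))
                if thr.autosomes_only else np.zeros(ds.n_snps, bool))
    bad_pos = (pos <= 0) if thr.require_known_position else np.zeros(ds.n_snps, bool)
    report.removed_non_autosomal = int(bad_auto.sum())
    report.removed_unknown_position = int((bad_pos & ~bad_auto).sum())
    ds = ds.subset(snp_mask=~(bad_auto | bad_pos))

    if ds.n_snps > 0:
        animal_cr = (ds.calls != MISSING).mean(axis=1)
    else:
        animal_cr = np.ones(ds.n_animals)
    keep_animals = animal_cr >= thr.call_rate_min - _EPS
    report.removed_animal_call_rate = int((~keep_animals).sum())
    ds = ds.subset(animals=[a for a, k in zip(ds.animal_ids, keep_animals) if k])
    report.n_animals_retained = ds.n_animals

    snp_cr = ((ds.calls != MISSING).mean(axis=0) if ds.n_animals
              else np.ones(ds.n_snps))
    bad_cr = snp_cr < thr.call_rate_min - _EPS
    maf = ds.minor_allele_freq()
    bad_maf = np.where(np.isnan(maf), True, maf < thr.maf_min - _EPS) & ~bad_cr
    need_hwe = ~(bad_cr | bad_maf)
    bad_hwe = np.zeros(ds.n_snps, bool)
    if need_hwe.any():
        hwe_p = _hwe_pvalues(ds.subset(snp_mask=need_hwe), thr.hwe_method)
        bad_hwe[np.flatnonzero(need_hwe)] = hwe_p < thr.hwe_p_min
    report.removed_snp_call_rate = int(bad_cr.sum())
    report.removed_maf = int(bad_maf.sum())
    report.removed_hwe = int(bad_hwe.sum())
    ds = ds.subset(snp_mask=~(bad_cr | bad_maf | bad_hwe))
    report.n_snps_retained = ds.n_snps

    assert report.snp_counts_reconcile and report.animal_counts_reconcile
    return ds, report
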