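"""Pairwise linkage disequilibrium (r^2) from unphased genotypes.

Haplotype frequencies for a SNP pair are the maximum-likelihood estimates
under random mating (HWE), obtained by EM over the one ambiguous genotype
class (the double heterozygote, which may be AB/ab or Ab/aB).  This mirrors
how the standard haplotype-analysis tools estimate r^2 from SNP-chip data.
r^2 = D^2 / (pA pa pB pb) with D = f_AB - pA pB.
"""

from __future__ import annotations

from dataclasses import dataclass, astuple

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset

EM_TOL = 1e-9
EM_MAX_ITER = 1000

__all__ = ["HaplotypeFreqs", "LDMatrix", "em_haplotype_freqs", "r_squared",
           "pairwise_r2", "ld_summary"]


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-locus haplotype frequencies (A/a at SNP 1, B/b at SNP 2)."""

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float

    def __post_init__(self) -> None:
        f = np.array(astuple(self))
        if (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"invalid haplotype frequencies {f}")


@dataclass
class LDMatrix:
    """Pairwise r^2 among position-ordered SNPs on one chromosome."""

    snp_ids: list[str]
    values: np.ndarray       # symmetric, NaN where undefined
    mean_r2: float           # unweighted mean over defined upper-triangle pairs
    n_pairs: int             # defined pairs entering the mean
    n_undefined: int


def _counts_3x3(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    n = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            n[i, j] = np.count_nonzero((g1 == i) & (g2 == j))
    return n


def em_haplotype_freqs(geno1, geno2) -> HaplotypeFreqs:
    """ML haplotype frequencies for two SNPs from unphased allele counts.

    ``geno1``/``geno2`` count the A (resp. B) allele per animal; pairs with a
    missing call at either SNP are dropped.  EM starts at linkage equilibrium
    and iterates until the largest frequency change is below 1e-9 (at most
    1000 iterations); the log-likelihood is checked to be non-decreasing.
    Raises on monomorphic input.
    """
    g1 = np.asarray(geno1)
    g2 = np.asarray(geno2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[ok].astype(int), g2[ok].astype(int)
    if g1.size < 2:
        raise ValueError("need >= 2 complete genotype pairs")
    if len(np.unique(g1)) < 2 or len(np.unique(g2)) < 2:
        raise ValueError("monomorphic SNP: haplotype frequencies undefined")

    n = _counts_3x3(g1, g2)
    N = 2.0 * n.sum()
    pA = (2 * n[2, :].sum() + n[1, :].sum()) / N
    pB = (2 * n[:, 2].sum() + n[:, 1].sum()) / N
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB,
                  (1 - pA) * (1 - pB)])  # AB, Ab, aB, ab

    # unambiguous haplotype counts (everything but the double heterozygote)
    base = np.array([
        2 * n[2, 2] + n[2, 1] + n[1, 2],   # AB
        2 * n[2, 0] + n[2, 1] + n[1, 0],   # Ab
        2 * n[0, 2] + n[0, 1] + n[1, 2],   # aB
        2 * n[0, 0] + n[0, 1] + n[1, 0],   # ab
    ], dtype=float)
    n_dh = n[1, 1]

    prev_ll = -np.inf
    for _ in range(EM_MAX_ITER):
        denom = f[0] * f[3] + f[1] * f[2]
        w = f[0] * f[3] / denom if denom > 0 else 0.5
        new = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= new.sum()
        ll = _loglik(base, n_dh, new)
        assert ll >= prev_ll - 1e-8, "EM log-likelihood decreased"
        prev_ll = ll
        if np.abs(new - f).max() < EM_TOL:
            f = new
            break
        f = new
    f = np.clip(f, 0.0, None)
    f /= f.sum()
    return HaplotypeFreqs(*f)


def _loglik(base: np.ndarray, n_dh: float, f: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        lf = np.where(base > 0, np.log(np.where(f > 0, f, 1.0)), 0.0)
    ll = float(base @ lf)
    if n_dh > 0:
        ll += n_dh * np.log(max(f[0] * f[3] + f[1] * f[2], 1e-300))
    return ll


def r_squared(h: HaplotypeFreqs) -> float:
    """r^2 = D^2 / (pA pa pB pb); NaN when either margin is fixed."""
    pA = h.f_AB + h.f_Ab
    pB = h.f_AB + h.f_aB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return np.nan
    d = h.f_AB - pA * pB
    return min(d * d / denom, 1.0)


def pairwise_r2(ds: GenotypeDataset) -> np.ndarray:
    """Symmetric r^2 matrix over all SNP pairs in the dataset (NaN if undefined)."""
    k = ds.n_snps
    out = np.full((k, k), np.nan)
    for i in range(k):
        gi = ds.calls[:, i]
        if len(np.unique(gi[gi != MISSING])) > 1:
            out[i, i] = 1.0
        for j in range(i + 1, k):
            try:
                out[i, j] = out[j, i] = r_squared(
                    em_haplotype_freqs(gi, ds.calls[:, j])
                )
            except ValueError:
                pass
    return out


def ld_summary(ds: GenotypeDataset, selected_ids) -> dict[str, LDMatrix]:
    """Per-chromosome LD among the selected (flagged) SNPs.

    Chromosomes with fewer than two selected SNPs are omitted.  The mean is
    the unweighted average over defined upper-triangle pairs (zero estimates
    included; undefined pairs excluded and counted, never imputed).
    """
    selected = set(selected_ids)
    sel = ds.snps["snp_id"].isin(selected).to_numpy()
    out: dict[str, LDMatrix] = {}
    for chrom, grp in ds.snps[sel].groupby("chrom", sort=False):
        if len(grp) < 2:
            continue
        order = grp.sort_values("pos").index.to_numpy()
        sub = ds.subset(snp_mask=order)
        vals = pairwise_r2(sub)
        iu = np.triu_indices(len(order), k=1)
        upper = vals[iu]
        defined = upper[~np.isnan(upper)]
        out[str(chrom)] = LDMatrix(
            snp_ids=sub.snps["snp_id"].tolist(),
            values=vals,
            mean_r2=float(defined.mean()) if defined.size else np.nan,
            n_pairs=int(defined.size),
            n_undefined=int(np.isnan(upper).sum()),
        )
    return out


def ld_matrix_to_tsv(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.values, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.6g"
    )
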