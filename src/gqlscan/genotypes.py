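"""Genotype container and PLINK-text / trait-file I/O.

Genotype calls are stored as an animals x SNPs ``int8`` matrix counting
copies of ``allele1`` (the first allele seen in the PED file), with ``-1``
for a missing call (PLINK "0 0").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

__all__ = ["GenotypeDataset", "read_plink_text", "write_plink_text",
           "read_trait", "write_trait", "MISSING"]


@dataclass
class GenotypeDataset:
    """Biallelic SNP calls for a cohort.

    ``snps`` has one row per SNP with columns
    ``snp_id, chrom, pos, allele1, allele2`` (``pos`` is bp, 0 = unknown);
    ``calls[i, j]`` counts copies of ``allele1`` of SNP ``j`` in animal ``i``.
    """

    animal_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animal_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snps)} SNPs"
            )
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or missing (-1)")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(self, animals=None, snp_mask=None) -> "GenotypeDataset":
        calls = self.calls
        ids = self.animal_ids
        snps = self.snps
        if animals is not None:
            pos = {a: i for i, a in enumerate(ids)}
            idx = np.array([pos[a] for a in animals])
            calls = calls[idx]
            ids = list(animals)
        if snp_mask is not None:
            snp_mask = np.asarray(snp_mask)
            calls = calls[:, snp_mask]
            snps = snps.loc[snp_mask] if snp_mask.dtype == bool else snps.iloc[snp_mask]
        return GenotypeDataset(ids, snps.reset_index(drop=True), calls)

    def allele_freq(self) -> np.ndarray:
        """Frequency of allele1 per SNP over non-missing calls (nan if none)."""
        obs = self.calls != MISSING
        counts = np.where(obs, self.calls, 0).sum(axis=0)
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, counts / (2.0 * n), np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


def read_plink_text(ped_path, map_path) -> GenotypeDataset:
    """Read PLINK text PED/MAP into a :class:`GenotypeDataset`.

    PED rows carry 6 leading columns (family, animal, sire, dam, sex,
    phenotype) then two allele tokens per SNP; "0 0" is a missing call.
    Raises on allele-column/MAP length mismatch and on >2 alleles at a SNP.
    """
    snps = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype=str,
    )
    snps["pos"] = snps["pos"].astype(np.int64)
    n_snps = len(snps)

    animal_ids: list[str] = []
    rows: list[np.ndarray] = []
    allele1 = np.array([""] * n_snps, dtype=object)
    allele2 = np.array([""] * n_snps, dtype=object)

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_snps} "
                    f"columns for {n_snps} SNPs, got {len(tok)}"
                )
            animal_ids.append(tok[1])
            a = np.array(tok[6::2], dtype=object)
            b = np.array(tok[7::2], dtype=object)
            calls = np.full(n_snps, MISSING, dtype=np.int8)
            for j in range(n_snps):
                x, y = a[j], b[j]
                if x == "0" or y == "0":
                    continue
                for al in (x, y):
                    if al == allele1[j] or al == allele2[j]:
                        continue
                    if allele1[j] == "":
                        allele1[j] = al
                    elif allele2[j] == "":
                        allele2[j] = al
                    else:
                        raise ValueError(
                            f"SNP {snps.snp_id[j]!r}: more than two alleles "
                            f"observed ({allele1[j]},{allele2[j]},{al})"
                        )
                calls[j] = int(x == allele1[j]) + int(y == allele1[j])
            rows.append(calls)

    # monomorphic SNPs may never reveal a second allele
    allele2[allele2 == ""] = "0"
    allele1[allele1 == ""] = "0"
    snps = snps[["snp_id", "chrom", "pos"]].copy()
    snps["allele1"] = allele1
    snps["allele2"] = allele2
    calls = (np.vstack(rows) if rows
             else np.empty((0, n_snps), dtype=np.int8))
    return GenotypeDataset(animal_ids, snps, calls)


def write_plink_text(ds: GenotypeDataset, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for r in ds.snps.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\n")
    a1 = ds.snps["allele1"].to_numpy(dtype=object)
    a2 = ds.snps["allele2"].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(ds.animal_ids):
            calls = ds.calls[i]
            first = np.where(calls >= 1, a1, a2)
            second = np.where(calls == 2, a1, a2)
            miss = calls == MISSING
            first[miss] = "0"
            second[miss] = "0"
            geno = " ".join(f"{x} {y}" for x, y in zip(first, second))
            fh.write(f"FAM {animal} 0 0 0 -9 {geno}\n")


def read_trait(path) -> pd.Series:
    """Read a 2-column (animal id, EBV) delimited text file into a Series."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     comment="#")
    first = str(df.iloc[0, 1])
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    s = pd.Series(
        df.iloc[:, 1].astype(float).to_numpy(),
        index=df.iloc[:, 0].astype(str).to_numpy(),
        name="ebv",
    )
    if s.index.duplicated().any():
        raise ValueError("duplicate animal ids in trait file")
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("non-finite EBV values in trait file")
    return s


def write_trait(trait: pd.Series, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal\tebv\n")
        for a, v in trait.items():
            fh.write(f"{a}\t{v:.6g}\n")
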