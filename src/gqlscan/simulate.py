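"""Synthetic cohort generator: pedigree, gene-dropped genotypes, EBV traits.

Emulates a half-sib-heavy beef-cattle genotyping study: a single genotyped
calf generation out of few sires (large half-sib families) and many dams,
dense biallelic SNPs with block-wise local LD, and EBV-like traits composed
of optional causal SNP effects, a pedigree-structured polygenic value and an
independent residual.

Founder haplotypes are drawn from a small pool of ancestral haplotypes per
LD block (mosaic-with-mutation model), which yields high LD within blocks,
none between, and — crucially for testing — analytically known true allele
and haplotype frequencies, recorded in the truth tables.  Genotypes descend
by Mendelian gene dropping: each gamete picks one parental haplotype per
block (no within-block recombination).  Everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset
from .pedigree import Pedigree, build_relationship_matrix

__all__ = ["SimConfig", "SimTruth", "SimCohort", "simulate_pedigree",
           "gene_drop", "simulate_ebv", "simulate_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters; defaults size the cohort like a typical
    single-generation half-sib design (49 sires, 355 dams, ~400 calves)."""

    seed: int
    sires_per_generation: int = 49
    dams_per_generation: int = 355
    offspring_per_generation: int = 399
    n_generations: int = 1
    n_chromosomes: int = 5
    snps_per_chrom: int = 200
    snp_spacing_bp: int = 50_000
    block_length: int = 10            # SNPs per LD block
    n_ancestral_haps: int = 8         # pool size per block
    mutation_rate: float = 0.02       # per-SNP flip prob when copying
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 0
    causal_effect: float = 0.0        # trait units per allele copy
    causal_maf_min: float = 0.10      # causal SNPs drawn among common SNPs
    polygenic_variance: float = 0.5
    residual_variance: float = 0.5
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for f in ("sires_per_generation", "dams_per_generation",
                  "offspring_per_generation", "n_chromosomes",
                  "snps_per_chrom", "block_length", "n_ancestral_haps"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.polygenic_variance < 0 or self.residual_variance < 0:
            raise ValueError("variances must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate outside [0, 1]")

    @property
    def n_founders(self) -> int:
        return self.sires_per_generation + self.dams_per_generation

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chrom


@dataclass
class SimTruth:
    """Generator ground truth for calibration and recovery tests."""

    true_freq: np.ndarray             # allele1 frequency per SNP
    block_id: np.ndarray              # LD-block index per SNP
    true_r2: pd.DataFrame             # within-block pairs: snp1, snp2, chrom, r2
    causal: pd.DataFrame              # snp_id, effect (trait units/allele)
    raw_calls: np.ndarray             # pre-masking calls of genotyped animals
    all_ids: list[str] | None = None  # every pedigree animal (record order)
    all_calls: np.ndarray | None = None  # pre-masking calls for all_ids


@dataclass
class SimCohort:
    pedigree: Pedigree
    dataset: GenotypeDataset
    trait: pd.Series
    truth: SimTruth
    config: SimConfig


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), stream])


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Multi-generation half-sib pedigree, deterministic given the seed.

    Each offspring draws its sire uniformly from the few active sires
    (half-sib families of mean size offspring/sires) while dams are used
    round-robin, hence mostly once.
    """
    if cfg.n_founders == 0:
        raise ValueError("need at least one founder")
    rng = _rng(cfg, 0)
    rows: list[tuple[str, str | None, str | None]] = []
    sires = [f"S{i + 1:03d}" for i in range(cfg.sires_per_generation)]
    dams = [f"D{i + 1:03d}" for i in range(cfg.dams_per_generation)]
    rows += [(a, None, None) for a in sires + dams]
    for g in range(1, cfg.n_generations + 1):
        kids = []
        dam_order = rng.permutation(len(dams))
        for k in range(cfg.offspring_per_generation):
            kid = f"G{g}_{k + 1:04d}"
            sire = sires[rng.integers(len(sires))]
            dam = dams[dam_order[k % len(dams)]]
            rows.append((kid, sire, dam))
            kids.append(kid)
        if g < cfg.n_generations:
            sex = rng.random(len(kids)) < 0.5
            males = [k for k, s in zip(kids, sex) if s]
            females = [k for k, s in zip(kids, sex) if not s]
            if (len(males) < cfg.sires_per_generation
                    or len(females) < cfg.dams_per_generation):
                raise ValueError("not enough offspring to parent the next "
                                 "generation")
            sires = males[:cfg.sires_per_generation]
            dams = females[:cfg.dams_per_generation]
    return Pedigree.from_records(rows)


def _build_genome(cfg: SimConfig, rng: np.random.Generator):
    """Ancestral haplotype pools and analytic truth per LD block."""
    n = cfg.n_snps
    eps = cfg.mutation_rate
    K = cfg.n_ancestral_haps
    lo, hi = cfg.maf_range

    chrom = np.repeat(np.arange(cfg.n_chromosomes), cfg.snps_per_chrom)
    within = np.tile(np.arange(cfg.snps_per_chrom), cfg.n_chromosomes)
    block_id = chrom * cfg.snps_per_chrom + within // max(cfg.block_length, 1)

    # target allele1 frequency: minor freq uniform, random minor allele
    minor = rng.uniform(lo, hi, n)
    p_target = np.where(rng.random(n) < 0.5, minor, 1.0 - minor)

    # each ancestral hap carries allele1 so that about p_target*K haps do
    anc = np.zeros((K, n), dtype=np.uint8)
    n_carry = np.clip(np.rint(p_target * K).astype(int), 0, K)
    for s in range(n):
        anc[rng.permutation(K)[: n_carry[s]], s] = 1

    pools = {}
    for b in np.unique(block_id):
        w = rng.dirichlet(np.full(K, 1.5))
        pools[int(b)] = w
    # P(allele1 | ancestral hap) after mutation; truth per SNP
    p_given = anc * (1 - eps) + (1 - anc) * eps
    weights = np.vstack([pools[int(b)] for b in block_id]).T  # K x n
    true_freq = (weights * p_given).sum(axis=0)
    return chrom, block_id, anc, pools, p_given, true_freq


def _true_r2_table(cfg, snp_ids, chrom, block_id, pools, p_given,
                   true_freq) -> pd.DataFrame:
    rows = []
    for b in np.unique(block_id):
        idx = np.flatnonzero(block_id == b)
        if len(idx) < 2:
            continue
        w = pools[int(b)]
        for ii, s in enumerate(idx):
            for t in idx[ii + 1:]:
                f_ab = float((w * p_given[:, s] * p_given[:, t]).sum())
                pa, pb = true_freq[s], true_freq[t]
                denom = pa * (1 - pa) * pb * (1 - pb)
                d = f_ab - pa * pb
                rows.append((snp_ids[s], snp_ids[t], str(chrom[s] + 1),
                             int(b), d * d / denom if denom > 0 else np.nan))
    return pd.DataFrame(rows, columns=["snp1", "snp2", "chrom", "block", "r2"])


def gene_drop(ped: Pedigree, cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Drop founder haplotypes through the pedigree; genotype the last
    generation (all non-founders born in the final generation)."""
    rng = _rng(cfg, 1)
    chrom, block_id, anc, pools, p_given, true_freq = _build_genome(cfg, rng)
    n = cfg.n_snps
    eps = cfg.mutation_rate

    blocks = np.unique(block_id)
    block_sizes = np.array([(block_id == b).sum() for b in blocks])
    block_start = np.concatenate([[0], np.cumsum(block_sizes)[:-1]])

    # pre-draw every founder haplotype in one vectorized pass (blocks are
    # contiguous in SNP order)
    founders = [a for a, s, d in ped.records if s is None and d is None]
    H = 2 * len(founders)
    pool_haps = np.empty((H, n), dtype=np.uint8)
    for b, size, start in zip(blocks, block_sizes, block_start):
        ks = rng.choice(cfg.n_ancestral_haps, size=H, p=pools[int(b)])
        pool_haps[:, start:start + size] = anc[ks, start:start + size]
    pool_haps ^= rng.random((H, n)) < eps
    founder_hap = {a: (pool_haps[2 * i], pool_haps[2 * i + 1])
                   for i, a in enumerate(founders)}

    def gamete(h0: np.ndarray, h1: np.ndarray) -> np.ndarray:
        pick = rng.integers(0, 2, len(blocks))
        mask = np.repeat(pick, block_sizes).astype(bool)
        return np.where(mask, h1, h0).astype(np.uint8)

    def fresh_hap() -> np.ndarray:
        # gamete of an unknown parent: fresh population haplotype
        hap = np.empty(n, dtype=np.uint8)
        for b, size, start in zip(blocks, block_sizes, block_start):
            k = rng.choice(cfg.n_ancestral_haps, p=pools[int(b)])
            hap[start:start + size] = anc[k, start:start + size]
        return hap ^ (rng.random(n) < eps)

    haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for animal, sire, dam in ped.records:
        if sire is None and dam is None:
            haps[animal] = founder_hap[animal]
            continue
        pat = gamete(*haps[sire]) if sire is not None else fresh_hap()
        mat = gamete(*haps[dam]) if dam is not None else fresh_hap()
        haps[animal] = (pat, mat)

    last_gen = _last_generation(ped)
    raw = np.vstack([haps[a][0].astype(np.int8) + haps[a][1] for a in last_gen])
    calls = raw.copy()
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    snp_ids = [f"chr{c + 1}_snp{i % cfg.snps_per_chrom + 1}"
               for i, c in enumerate(chrom)]
    snps = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": [str(c + 1) for c in chrom],
        "pos": [(i % cfg.snps_per_chrom + 1) * cfg.snp_spacing_bp
                for i in range(n)],
        "allele1": "A",
        "allele2": "B",
    })
    ds = GenotypeDataset(list(last_gen), snps, calls)

    causal = _pick_causal(cfg, snp_ids, true_freq)
    truth = SimTruth(
        true_freq=true_freq,
        block_id=block_id,
        true_r2=_true_r2_table(cfg, snp_ids, chrom, block_id, pools,
                               p_given, true_freq),
        causal=causal,
        raw_calls=raw,
        all_ids=[a for a, _, _ in ped.records],
        all_calls=np.vstack([haps[a][0].astype(np.int8) + haps[a][1]
                             for a, _, _ in ped.records]),
    )
    return ds, truth


def _last_generation(ped: Pedigree) -> list[str]:
    kids = [a for a, s, d in ped.records if s is not None or d is not None]
    if not kids:
        return list(ped.ids)
    gen = max(a.split("_")[0] for a in kids if a.startswith("G"))
    sel = [a for a in kids if a.startswith(gen + "_")]
    return sorted(sel) if sel else kids


def _pick_causal(cfg: SimConfig, snp_ids, true_freq) -> pd.DataFrame:
    if cfg.n_causal == 0:
        return pd.DataFrame(columns=["snp_id", "effect"])
    rng = _rng(cfg, 2)
    maf = np.minimum(true_freq, 1 - true_freq)
    eligible = np.flatnonzero(maf >= cfg.causal_maf_min)
    if len(eligible) < cfg.n_causal:
        raise ValueError("not enough common SNPs to place causal effects")
    pick = rng.choice(eligible, cfg.n_causal, replace=False)
    return pd.DataFrame({"snp_id": [snp_ids[i] for i in pick],
                         "effect": cfg.causal_effect})


def simulate_ebv(
    ped: Pedigree, ds: GenotypeDataset, truth: SimTruth, cfg: SimConfig
) -> pd.Series:
    """EBV-like trait: causal SNP effects + pedigree polygenic value + noise.

    The polygenic value follows the additive recursion (child = mid-parent +
    Mendelian deviation with variance sigma_a^2 * (1 - (F_s + F_d)/2) / 2),
    so its covariance is sigma_a^2 * A by construction.  Causal effects use
    the pre-masking allele counts.
    """
    rng = _rng(cfg, 3)
    A = build_relationship_matrix(ped)
    F = {a: A.values[i, i] - 1.0 for i, a in enumerate(A.ids)}

    sa = np.sqrt(cfg.polygenic_variance)
    u: dict[str, float] = {}
    for animal, sire, dam in ped.records:
        if sire is None and dam is None:
            u[animal] = sa * rng.standard_normal()
        else:
            mid = 0.5 * (u.get(sire, 0.0) + u.get(dam, 0.0))
            f_s = F.get(sire, 0.0) if sire else 0.0
            f_d = F.get(dam, 0.0) if dam else 0.0
            known = (sire is not None) + (dam is not None)
            # a missing parent contributes a full founder-gamete variance
            var_ms = cfg.polygenic_variance * (
                0.5 - 0.25 * (f_s + f_d) + 0.25 * (2 - known)
            )
            u[animal] = mid + np.sqrt(max(var_ms, 0.0)) * rng.standard_normal()

    x = np.array([u[a] for a in ds.animal_ids])
    if len(truth.causal):
        pos = {s: j for j, s in enumerate(ds.snps["snp_id"])}
        for r in truth.causal.itertuples(index=False):
            if r.snp_id not in pos:
                raise ValueError(f"causal SNP {r.snp_id!r} not in dataset")
            x = x + r.effect * truth.raw_calls[:, pos[r.snp_id]]
    x = x + np.sqrt(cfg.residual_variance) * rng.standard_normal(len(x))
    return pd.Series(x, index=ds.animal_ids, name="ebv")


def simulate_cohort(cfg: SimConfig) -> SimCohort:
    """Pedigree + genotypes + trait in one deterministic call."""
    ped = simulate_pedigree(cfg)
    ds, truth = gene_drop(ped, cfg)
    trait = simulate_ebv(ped, ds, truth, cfg)
    return SimCohort(ped, ds, trait, truth, cfg)
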