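"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different route from the library code:
recursive kinship coefficients instead of the tabular matrix recursion,
literal dense evaluation of the score-statistic formula, exact-fraction
enumeration for the HWE conditional distribution, exhaustive-threshold BH,
and a grid-search likelihood maximizer for two-locus haplotype frequencies.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np

from gqlscan.pedigree import Pedigree


# ---------------------------------------------------------------- kinship

def kinship_matrix_recursive(ped: Pedigree) -> np.ndarray:
    """A = 2 * kinship, via the classic coancestry recursion.

    phi(i,i) = (1 + phi(s,d)) / 2; for i later-born than j,
    phi(i,j) = (phi(s,j) + phi(d,j)) / 2, unknown parents contributing 0.
    """
    order = {a: k for k, (a, _, _) in enumerate(ped.records)}

    @lru_cache(maxsize=None)
    def phi(i: str, j: str) -> float:
        if order[i] < order[j]:
            i, j = j, i
        s, d = ped.parents_of(i)
        if i == j:
            psd = phi(s, d) if s is not None and d is not None else 0.0
            return 0.5 * (1.0 + psd)
        acc = 0.0
        if s is not None:
            acc += 0.5 * phi(s, j)
        if d is not None:
            acc += 0.5 * phi(d, j)
        return acc

    ids = ped.ids
    n = len(ids)
    A = np.empty((n, n))
    for a in range(n):
        for b in range(a, n):
            A[a, b] = A[b, a] = 2.0 * phi(ids[a], ids[b])
    return A


# ------------------------------------------------------------------- GQLS

def wg_dense(x: np.ndarray, y: np.ndarray, ainv: np.ndarray) -> float:
    """Literal matrix-expression evaluation of the score statistic."""
    x = np.asarray(x, float).reshape(-1, 1)
    y = np.asarray(y, float).reshape(-1, 1)
    one = np.ones_like(x)
    mu = (np.linalg.inv(one.T @ ainv @ one) @ (one.T @ ainv @ y)).item()
    s = x.T @ ainv @ (y - mu * one)
    m = (x.T @ ainv @ x
         - (x.T @ ainv @ one) @ np.linalg.inv(one.T @ ainv @ one)
         @ (one.T @ ainv @ x))
    return (2.0 / (mu * (1.0 - mu)) * s.T @ np.linalg.inv(m) @ s).item()


# -------------------------------------------------------------------- HWE

def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact HWE p-value with exact rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    rare = min(nA, 2 * n - nA)
    if rare == 0:
        return 1.0

    def weight(h: int) -> int:
        hr = (rare - h) // 2
        hc = (2 * n - rare - h) // 2
        # multinomial count of genotype configurations times 2^h
        num = Fraction(1)
        for k in range(1, n + 1):
            num *= k
        for grp in (hr, h, hc):
            for k in range(1, grp + 1):
                num /= k
        return num * 2 ** h

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: weight(h) for h in hets}
    total = sum(probs.values())
    obs = probs[n_Aa]
    p = sum(v for v in probs.values() if v <= obs) / total
    return float(p)


# --------------------------------------------------------------------- BH

def bh_exhaustive(p: np.ndarray, q: float) -> np.ndarray:
    """Try every observed p as the rejection threshold, keep the largest
    threshold whose implied rejection set satisfies t <= |set| * q / m."""
    p = np.asarray(p, float)
    m = p.size
    best: np.ndarray = np.array([], dtype=int)
    for t in np.unique(p):
        sel = np.flatnonzero(p <= t)
        if t <= len(sel) * q / m and len(sel) > len(best):
            best = sel
    return best


# --------------------------------------------------------------------- LD

def em_grid_search(g1: np.ndarray, g2: np.ndarray, step: float = 1e-5):
    """Grid-search maximizer of the two-locus multinomial likelihood.

    Allele margins are fully observed (only phase is ambiguous), so the ML
    margins equal the sample allele frequencies and the likelihood is a
    one-dimensional function of f_AB on its Frechet interval; the grid walks
    that interval.  Returns (f_AB, f_Ab, f_aB, f_ab).
    """
    ok = (g1 >= 0) & (g2 >= 0)
    g1, g2 = np.asarray(g1)[ok], np.asarray(g2)[ok]
    n = len(g1)
    counts = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        counts[a, b] += 1
    pA = g1.sum() / (2.0 * n)
    pB = g2.sum() / (2.0 * n)

    def loglik(fab: float) -> float:
        f = np.array([fab, pA - fab, pB - fab, 1 - pA - pB + fab])
        if (f < -1e-12).any():
            return -np.inf
        f = np.clip(f, 1e-300, None)
        # genotype-class probabilities under random union of haplotypes
        hap_geno = [(1, 1), (1, 0), (0, 1), (0, 0)]  # (A-count, B-count)
        P = np.zeros((3, 3))
        for u, (au, bu) in enumerate(hap_geno):
            for v, (av, bv) in enumerate(hap_geno):
                P[au + av, bu + bv] += f[u] * f[v]
        with np.errstate(divide="ignore"):
            lp = np.where(counts > 0, np.log(np.clip(P, 1e-300, None)), 0.0)
        return float((counts * lp).sum())

    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    grid = np.arange(lo, hi + step, step)
    best = grid[int(np.argmax([loglik(f) for f in grid]))]
    return best, pA - best, pB - best, 1 - pA - pB + best


# ------------------------------------------------------------- annotation

def nearest_genes_brute(chrom: str, pos: int, genes) -> tuple[list[str], float]:
    """Scan every gene on the chromosome; return co-nearest symbols and
    edge distance in kb (0.0 when inside a span)."""
    cands = genes.by_chrom.get(str(chrom), [])
    if not cands:
        return [], float("nan")
    dists = []
    for g in cands:
        if g.start <= pos <= g.end:
            d = 0
        elif pos < g.start:
            d = g.start - pos
        else:
            d = pos - g.end
        dists.append(d)
    dmin = min(dists)
    return ([g.symbol for g, d in zip(cands, dists) if d == dmin],
            dmin / 1000.0)
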