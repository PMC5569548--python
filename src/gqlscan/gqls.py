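"""Generalized Quasi-Likelihood Score (GQLS) association test.

The test regresses the genotype proportion ``Y in {0, 1/2, 1}`` (half the
allele count) on a continuous covariate ``X`` (here, an estimated breeding
value) through a logistic link, accounting for relatedness by weighting with
``A^-1``, the inverse of the numerator relationship matrix of the analyzed
animals.  Under the null hypothesis of no association the score statistic

    WG = 2 / (mu(1-mu)) * s' M^-1 s,
    s  = X' A^-1 (Y - mu 1),
    M  = X' A^-1 X - (X' A^-1 1)(1' A^-1 1)^-1 (1' A^-1 X),
    mu = (1' A^-1 1)^-1 1' A^-1 Y,

is chi-squared with one degree of freedom.  The slope of the logistic link
is never estimated: only its score at the null enters, so a single linear
solve per missingness pattern suffices and the per-SNP work is O(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genotypes import MISSING, GenotypeDataset
from .pedigree import InverseRelationship, RelationshipMatrix, subset_and_invert

MONO_TOL = 1e-12       # mu within this of {0,1} -> monomorphic status
M_COND_TOL = 1e10      # relative condition threshold for degenerate covariate

__all__ = ["GqlsResult", "encode_genotypes", "estimate_null_frequency",
           "gqls_statistic", "run_scan"]


@dataclass(frozen=True)
class GqlsResult:
    """Single-SNP test result; ``p_value`` is the upper chi2_1 tail of WG."""

    mu_hat: float
    wg: float
    p_value: float
    n_used: int
    status: str  # "ok" | "monomorphic" | "degenerate_covariate"


def encode_genotypes(calls) -> np.ndarray:
    """Map allele counts {0,1,2} to genotype proportions {0, 1/2, 1}.

    Missing calls (``-1`` or NaN) become NaN.
    """
    calls = np.asarray(calls, dtype=float)
    y = calls / 2.0
    y[np.isnan(calls) | (calls == MISSING)] = np.nan
    if np.nanmin(y, initial=0.0) < 0.0 or np.nanmax(y, initial=0.0) > 1.0:
        raise ValueError("allele counts outside {0,1,2,missing}")
    return y


def estimate_null_frequency(y: np.ndarray, ainv: np.ndarray | InverseRelationship) -> float:
    """A^-1-weighted generalized mean of Y: (1'A^-1 1)^-1 1'A^-1 Y."""
    W = ainv.values if isinstance(ainv, InverseRelationship) else np.asarray(ainv)
    y = np.asarray(y, dtype=float)
    if W.shape != (y.size, y.size):
        raise ValueError(f"A^-1 shape {W.shape} does not conform to n={y.size}")
    w1 = W.sum(axis=1)
    return float(w1 @ y / w1.sum())


def gqls_statistic(
    x: np.ndarray,
    y: np.ndarray,
    ainv: np.ndarray | InverseRelationship,
) -> GqlsResult:
    """Compute WG and its chi2_1 p-value for one SNP.

    ``x``: covariate (EBV) per animal; ``y``: genotype proportion per animal;
    ``ainv``: inverse relationship matrix over the same animals in the same
    order.  Degenerate inputs are reported as statuses, not raised.
    """
    W = ainv.values if isinstance(ainv, InverseRelationship) else np.asarray(ainv)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n or W.shape != (n, n):
        raise ValueError("x, y and A^-1 must conform over the same animals")
    if n < 3:
        raise ValueError(f"need >= 3 animals, got {n}")

    w1 = W.sum(axis=1)          # A^-1 1
    s11 = w1.sum()              # 1' A^-1 1
    mu = float(w1 @ y / s11)
    if mu < MONO_TOL or mu > 1.0 - MONO_TOL:
        return GqlsResult(mu, np.nan, np.nan, n, "monomorphic")

    wx = W @ x                  # A^-1 X
    s1x = float(w1 @ x)
    m = float(x @ wx - s1x * s1x / s11)
    scale = float(x @ wx) if x @ wx != 0 else 1.0
    if not np.isfinite(m) or abs(m) <= abs(scale) / M_COND_TOL:
        return GqlsResult(mu, np.nan, np.nan, n, "degenerate_covariate")

    s = float(wx @ y - mu * s1x)   # X' A^-1 (Y - mu 1)
    wg = 2.0 / (mu * (1.0 - mu)) * s * s / m
    wg = max(wg, 0.0)
    return GqlsResult(mu, wg, float(chi2.sf(wg, df=1)), n, "ok")


def run_scan(
    ds: GenotypeDataset,
    trait: pd.Series,
    relationship: RelationshipMatrix | None = None,
) -> pd.DataFrame:
    """Scan every SNP, one at a time, against one trait's EBVs.

    Animals are the intersection of the dataset and the trait file.  Per SNP,
    animals with a missing call are dropped and the A-submatrix of the
    remaining animals is re-inverted exactly; inversions and the covariate
    cross-products are cached per missingness pattern.  ``relationship=None``
    treats animals as unrelated (identity A).

    Returns the association table: one row per SNP with
    ``snp_id, chrom, pos, n_used, maf, mu_hat, wg, p_value, status``.
    """
    animals = [a for a in ds.animal_ids if a in trait.index]
    if len(animals) < 3:
        raise ValueError(
            f"only {len(animals)} animals shared between genotypes and trait"
        )
    ds = ds.subset(animals=animals)
    x_all = trait.loc[animals].to_numpy(dtype=float)
    if relationship is not None:
        A_all = relationship.submatrix(animals).values
    else:
        A_all = np.eye(len(animals))

    y_all = encode_genotypes(ds.calls)
    maf = ds.minor_allele_freq()

    # All quantities entering WG are quadratic forms u' (A_oo)^-1 v over the
    # observed animals o.  With W = A^-1 and zero-extended vectors u0, v0,
    # the Schur identity gives
    #   u' (A_oo)^-1 v = u0' W v0 - (W v0)_m' W_mm^-1 (W u0)_m,
    # so each SNP costs one matvec plus O(n k + k^3) for k missing animals
    # and never materializes a submatrix inverse.  Exactly equivalent to
    # complete-case re-inversion (covered by tests against brute force).
    W = np.linalg.inv(A_all)
    one = np.ones(len(animals))
    w1 = W @ one
    wx = W @ x_all

    rows = []
    for j in range(ds.n_snps):
        y = y_all[:, j]
        obs = ~np.isnan(y)
        n_used = int(obs.sum())
        if n_used < 3:
            rows.append((n_used, np.nan, np.nan, np.nan, "insufficient_n"))
            continue
        m = np.flatnonzero(~obs)
        yo = np.where(obs, y, 0.0)
        ty = W @ yo
        if m.size:
            Wm = W[:, m]
            t1 = w1 - Wm @ one[m]
            tx = wx - Wm @ x_all[m]
            rhs = np.column_stack([t1[m], tx[m], ty[m]])
            Z = np.linalg.solve(W[np.ix_(m, m)], rhs)
            z1, zx, zy = Z.T
            s11 = t1[obs].sum() - t1[m] @ z1
            s1x = x_all[obs] @ t1[obs] - tx[m] @ z1
            sxx = x_all[obs] @ tx[obs] - tx[m] @ zx
            s1y = yo[obs] @ t1[obs] - ty[m] @ z1
            sxy = yo[obs] @ tx[obs] - ty[m] @ zx
        else:
            s11 = w1 @ one
            s1x = w1 @ x_all
            sxx = x_all @ wx
            s1y = w1 @ yo
            sxy = wx @ yo
        mu = s1y / s11
        if mu < MONO_TOL or mu > 1.0 - MONO_TOL:
            rows.append((n_used, mu, np.nan, np.nan, "monomorphic"))
            continue
        mm = sxx - s1x * s1x / s11
        scale = sxx if sxx != 0 else 1.0
        if not np.isfinite(mm) or abs(mm) <= abs(scale) / M_COND_TOL:
            rows.append((n_used, mu, np.nan, np.nan, "degenerate_covariate"))
            continue
        s = sxy - mu * s1x
        wg = max(2.0 / (mu * (1.0 - mu)) * s * s / mm, 0.0)
        rows.append((n_used, mu, wg, float(chi2.sf(wg, df=1)), "ok"))

    out = ds.snps[["snp_id", "chrom", "pos"]].copy()
    out[["n_used", "mu_hat", "wg", "p_value", "status"]] = pd.DataFrame(
        rows, columns=["n_used", "mu_hat", "wg", "p_value", "status"]
    )
    out.insert(3, "maf", maf)
    out["n_used"] = out["n_used"].astype(int)
    return out
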