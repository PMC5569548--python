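"""Multiple-testing correction: BH FDR at two scopes, plus Bonferroni.

Significance is declared at FDR 5% ("significant") and FDR 10%
("suggestive"), each both genome-wide (m = all tested SNPs) and
chromosome-wise (m = tested SNPs on the chromosome).  SNPs whose test did
not produce a p-value (monomorphic, degenerate covariate) are excluded from
m.  The BH boundary case P(i) = i*q/m counts as rejected; for continuous
p-values the choice is immaterial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

DEFAULT_LEVELS = (0.05, 0.10)

__all__ = ["bh_reject", "bonferroni_reject", "classify", "flag_summary",
           "DEFAULT_LEVELS"]

FLAG_COLUMNS = ["gw_fdr05", "gw_fdr10", "cw_fdr05", "cw_fdr10",
                "gw_bonferroni"]


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.isnan(p).any() or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_reject(p, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns indices of rejected hypotheses.

    Rejects ranks 1..k where k = max{i : P(i) <= i*q/m}; tied p-values share
    their fate.
    """
    p = _check_p(p)
    if not 0.0 < q < 1.0:
        raise ValueError(f"FDR level q={q} outside (0, 1)")
    if p.size == 0:
        return np.array([], dtype=int)
    reject = multipletests(p, alpha=q, method="fdr_bh")[0]
    return np.flatnonzero(reject)


def bonferroni_reject(p, alpha: float) -> np.ndarray:
    """Bonferroni: reject where p <= alpha / m."""
    p = _check_p(p)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1)")
    if p.size == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(p <= alpha / p.size)


def classify(
    assoc: pd.DataFrame, levels: tuple[float, float] = DEFAULT_LEVELS
) -> pd.DataFrame:
    """Append genome-wide/chromosome-wise FDR and Bonferroni flags.

    Expects an association table with ``chrom``, ``p_value`` and ``status``
    columns; rows with status != "ok" get all-False flags and do not count
    toward m at either scope.  Returns a copy with the five boolean flag
    columns and per-scope ``m_gw`` / ``m_cw`` counts appended.
    """
    q05, q10 = levels
    out = assoc.copy()
    ok = (out["status"] == "ok").to_numpy()
    p = out["p_value"].to_numpy(dtype=float)
    n = len(out)
    for col in FLAG_COLUMNS:
        out[col] = False

    p_ok = p[ok]
    idx_ok = np.flatnonzero(ok)
    for col, q in (("gw_fdr05", q05), ("gw_fdr10", q10)):
        flags = np.zeros(n, dtype=bool)
        flags[idx_ok[bh_reject(p_ok, q)]] = True
        out[col] = flags
    gw_bonf = np.zeros(n, dtype=bool)
    gw_bonf[idx_ok[bonferroni_reject(p_ok, q05)]] = True
    out["gw_bonferroni"] = gw_bonf
    out["m_gw"] = int(ok.sum())

    out["m_cw"] = 0
    for col in ("cw_fdr05", "cw_fdr10"):
        out[col] = False
    for chrom, grp in out.groupby("chrom", sort=False):
        sel = np.flatnonzero((out["chrom"] == chrom).to_numpy() & ok)
        out.loc[out["chrom"] == chrom, "m_cw"] = len(sel)
        for col, q in (("cw_fdr05", q05), ("cw_fdr10", q10)):
            rej = sel[bh_reject(p[sel], q)]
            out.loc[out.index[rej], col] = True
    return out


def flag_summary(flagged: pd.DataFrame) -> pd.DataFrame:
    """Rejection counts and m per scope/level for the run manifest."""
    rows = [
        ("genome-wide", "fdr05", int(flagged["gw_fdr05"].sum()),
         int(flagged["m_gw"].iloc[0]) if len(flagged) else 0),
        ("genome-wide", "fdr10", int(flagged["gw_fdr10"].sum()),
         int(flagged["m_gw"].iloc[0]) if len(flagged) else 0),
        ("genome-wide", "bonferroni05", int(flagged["gw_bonferroni"].sum()),
         int(flagged["m_gw"].iloc[0]) if len(flagged) else 0),
        ("chromosome-wise", "fdr05", int(flagged["cw_fdr05"].sum()),
         int(flagged["m_gw"].iloc[0]) if len(flagged) else 0),
        ("chromosome-wise", "fdr10", int(flagged["cw_fdr10"].sum()),
         int(flagged["m_gw"].iloc[0]) if len(flagged) else 0),
    ]
    # per-chromosome m values live in the flagged table's m_cw column
    return pd.DataFrame(rows, columns=["scope", "level", "n_rejected", "m"])
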