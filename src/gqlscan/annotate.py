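"""Nearest-gene annotation of associated SNPs.

A SNP inside a gene span (1-based inclusive) is intragenic, distance 0.00 kb,
sub-classified as exon / 5'UTR / 3'UTR when such intervals are provided and
as intron otherwise.  An intergenic SNP is assigned its nearest gene(s) by
edge distance (kilobases, two decimals by convention in the output tables),
with direction labelled relative to the gene's strand: a SNP beyond the
gene's 5' end is "upstream", beyond the 3' end "downstream".  Equidistant
genes are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

__all__ = ["GeneModelSet", "AnnotationHit", "load_gene_models",
           "annotate_snp", "annotate_table"]

_UTR5 = {"five_prime_utr", "five_prime_UTR", "5'UTR"}
_UTR3 = {"three_prime_utr", "three_prime_UTR", "3'UTR"}


@dataclass(frozen=True)
class Gene:
    gene_id: str
    symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()


@dataclass
class GeneModelSet:
    """Genes indexed by chromosome, sorted by start position."""

    by_chrom: dict[str, list[Gene]] = field(default_factory=dict)

    def add(self, gene: Gene) -> None:
        self.by_chrom.setdefault(gene.chrom, []).append(gene)

    def finalize(self) -> "GeneModelSet":
        for genes in self.by_chrom.values():
            genes.sort(key=lambda g: (g.start, g.end))
        return self

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_chrom.values())


@dataclass(frozen=True)
class AnnotationHit:
    snp_id: str
    chrom: str
    pos: int
    genes: tuple[str, ...]          # symbols of the (co-)nearest gene(s)
    category: str                   # intron|exon|5'UTR|3'UTR|intragenic|
                                    # upstream|downstream|no_gene
    distance_kb: float              # 0.0 iff intragenic; NaN if no gene


def load_gene_models(path) -> GeneModelSet:
    """Load gene spans (and exon/UTR sub-features if present) from GFF3."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    out = GeneModelSet()
    for g in db.features_of_type("gene"):
        if g.end < g.start:
            raise ValueError(f"gene {g.id}: end < start at line {g.start}")
        exons, utr5, utr3 = [], [], []
        for child in db.children(g.id):
            iv = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype in _UTR5:
                utr5.append(iv)
            elif child.featuretype in _UTR3:
                utr3.append(iv)
        symbol = (g.attributes.get("Name") or g.attributes.get("gene_name")
                  or [g.id])[0]
        out.add(Gene(g.id, symbol, str(g.seqid), g.start, g.end,
                     g.strand or "+", tuple(exons), tuple(utr5), tuple(utr3)))
    return out.finalize()


def _subtype(gene: Gene, pos: int) -> str:
    for lo, hi in gene.utr5:
        if lo <= pos <= hi:
            return "5'UTR"
    for lo, hi in gene.utr3:
        if lo <= pos <= hi:
            return "3'UTR"
    if gene.exons:
        for lo, hi in gene.exons:
            if lo <= pos <= hi:
                return "exon"
        return "intron"
    return "intragenic"


def annotate_snp(chrom: str, pos: int, genes: GeneModelSet) -> AnnotationHit:
    """Annotate one SNP position against the gene models."""
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    cands = genes.by_chrom.get(str(chrom), [])
    if not cands:
        return AnnotationHit("", str(chrom), pos, (), "no_gene", np.nan)

    inside = [g for g in cands if g.start <= pos <= g.end]
    if inside:
        # several overlapping genes may contain the SNP; report all,
        # classify by the first (most 5' span)
        return AnnotationHit("", str(chrom), pos,
                             tuple(g.symbol for g in inside),
                             _subtype(inside[0], pos), 0.0)

    dist = [g.start - pos if pos < g.start else pos - g.end for g in cands]
    dmin = int(min(dist))  # Python int: decimal rounding below, not numpy's
    nearest = [g for g, d in zip(cands, dist) if d == dmin]
    g0 = nearest[0]
    before = pos < g0.start  # SNP on the lower-coordinate side
    upstream = (before and g0.strand == "+") or (not before and g0.strand == "-")
    return AnnotationHit("", str(chrom), pos,
                         tuple(g.symbol for g in nearest),
                         "upstream" if upstream else "downstream",
                         round(dmin / 1000.0, 2))


def annotate_table(assoc: pd.DataFrame, genes: GeneModelSet) -> pd.DataFrame:
    """Annotate each association row; returns the output-table schema.

    Columns: snp_id, chrom, pos_mb, gene(s) joined by ';', category,
    distance_kb, p_value.
    """
    rows = []
    for r in assoc.itertuples(index=False):
        hit = annotate_snp(str(r.chrom), int(r.pos), genes)
        rows.append({
            "snp_id": r.snp_id,
            "chrom": r.chrom,
            "pos_mb": round(r.pos / 1e6, 2),
            "genes": ";".join(hit.genes) if hit.genes else ".",
            "category": hit.category,
            "distance_kb": hit.distance_kb,
            "p_value": getattr(r, "p_value", np.nan),
        })
    return pd.DataFrame(rows)
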