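"""End-to-end orchestration: QC -> kinship -> GQLS scan per trait -> FDR ->
LD among flagged SNPs -> nearest-gene annotation.

``run_pipeline`` consumes files (pedigree, PLINK text PED/MAP, one trait
file per trait, optional GFF3) and writes, per trait, the association table
with significance flags, LD summaries, annotation and a Manhattan-ready
table, plus a QC report and a run manifest recording thresholds, per-scope
test counts and the documented analysis assumptions.  Given fixed inputs the
outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_table, load_gene_models
from .genotypes import read_plink_text, read_trait
from .ld import ld_matrix_to_tsv, ld_summary
from .multiple_testing import DEFAULT_LEVELS, classify, flag_summary
from .gqls import run_scan
from .pedigree import build_relationship_matrix, read_pedigree
from .qc import QcThresholds, apply_qc

log = logging.getLogger("gqlscan")

__all__ = ["PipelineConfig", "run_pipeline", "manhattan_table"]


@dataclass
class PipelineConfig:
    pedigree: str
    ped: str
    map: str
    traits: dict[str, str]            # trait name -> trait file path
    gff3: str | None = None
    out_dir: str = "results"
    qc: QcThresholds = field(default_factory=QcThresholds)
    fdr_levels: tuple[float, float] = DEFAULT_LEVELS
    ld_flag_set: str = "cw_fdr10"     # flag column selecting SNPs for LD
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        qc = QcThresholds(**raw.pop("qc", {}))
        levels = tuple(raw.pop("fdr_levels", DEFAULT_LEVELS))
        return cls(qc=qc, fdr_levels=levels, **raw)

    def validate(self) -> None:
        for name, p in [("pedigree", self.pedigree), ("ped", self.ped),
                        ("map", self.map)] + list(self.traits.items()):
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.gff3 and not Path(self.gff3).exists():
            raise FileNotFoundError(f"gff3: {self.gff3} does not exist")
        for q in self.fdr_levels:
            if not 0.0 < q < 1.0:
                raise ValueError(f"FDR level {q} outside (0, 1)")


def manhattan_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """Manhattan-plot-ready rows: chrom, pos, p, -log10 p and flags.

    Rows whose test produced no p-value keep a missing transform.  Within
    each chromosome the input position order is preserved.
    """
    out = assoc.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    out.loc[out["status"] != "ok", "neg_log10_p"] = np.nan
    cols = ["snp_id", "chrom", "pos", "p_value", "neg_log10_p"]
    cols += [c for c in out.columns if c.startswith(("gw_", "cw_"))]
    return out[cols]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage for every trait; returns the result bundle.

    The bundle maps trait name -> dict with the flagged association table,
    LD matrices, annotation table and Manhattan table; "qc_report" and
    "manifest" are shared entries.  All tables are also written as TSV under
    ``cfg.out_dir``.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("reading genotypes %s / %s", cfg.ped, cfg.map)
    ds = read_plink_text(cfg.ped, cfg.map)
    ds, qc_report = apply_qc(ds, cfg.qc)
    qc_report.to_frame().to_csv(out_dir / "qc_report.tsv", sep="\t",
                                index=False)
    log.info("QC: retained %d SNPs, %d animals",
             qc_report.n_snps_retained, qc_report.n_animals_retained)

    ped = read_pedigree(cfg.pedigree)
    missing_ped = [a for a in ds.animal_ids if a not in ped]
    if missing_ped:
        raise ValueError(f"genotyped animals absent from pedigree: "
                         f"{missing_ped[:5]}")
    A = build_relationship_matrix(ped)
    genes = load_gene_models(cfg.gff3) if cfg.gff3 else None

    bundle: dict = {"qc_report": qc_report}
    manifest = {
        "package_version": __version__,
        "qc_thresholds": qc_report.thresholds,
        "fdr_levels": list(cfg.fdr_levels),
        "ld_flag_set": cfg.ld_flag_set,
        "n_snps": ds.n_snps,
        "n_animals": ds.n_animals,
        "assumptions": [
            "relationship matrix: full-pedigree tabular A, analyzed-animal "
            "submatrix inverted densely",
            "per-SNP complete-case analysis with exact re-inversion per "
            "missingness pattern",
            "monomorphic/degenerate SNPs excluded from multiple-testing m",
            "BH boundary P(i) = i*q/m counted as rejected",
        ],
        "traits": {},
    }

    for trait_name, trait_path in cfg.traits.items():
        log.info("trait %s: association scan", trait_name)
        try:
            trait = read_trait(trait_path)
        except Exception as exc:
            raise RuntimeError(
                f"stage trait-input failed for trait {trait_name!r}: {exc}"
            ) from exc
        assoc = run_scan(ds, trait, A)
        flagged = classify(assoc, cfg.fdr_levels)
        flagged.to_csv(out_dir / f"assoc_{trait_name}.tsv", sep="\t",
                       index=False, float_format="%.6g")
        summary = flag_summary(flagged)
        summary.to_csv(out_dir / f"fdr_summary_{trait_name}.tsv", sep="\t",
                       index=False)

        selected = flagged.loc[flagged[cfg.ld_flag_set], "snp_id"]
        ld = ld_summary(ds, selected)
        ld_rows = [(trait_name, c, len(m.snp_ids), m.n_pairs, m.n_undefined,
                    m.mean_r2) for c, m in ld.items()]
        ld_df = pd.DataFrame(ld_rows, columns=[
            "trait", "chrom", "n_snps", "n_pairs", "n_undefined", "mean_r2"])
        ld_df.to_csv(out_dir / f"ld_summary_{trait_name}.tsv", sep="\t",
                     index=False, float_format="%.4f")
        for c, m in ld.items():
            ld_matrix_to_tsv(m, out_dir / f"ld_{trait_name}_chr{c}.tsv")

        ann = None
        if genes is not None:
            ann = annotate_table(flagged[flagged[cfg.ld_flag_set]], genes)
            ann.to_csv(out_dir / f"annotation_{trait_name}.tsv", sep="\t",
                       index=False, float_format="%.6g")

        mh = manhattan_table(flagged)
        mh.to_csv(out_dir / f"manhattan_{trait_name}.tsv", sep="\t",
                  index=False, float_format="%.6g")

        bundle[trait_name] = {"assoc": flagged, "fdr_summary": summary,
                              "ld": ld, "annotation": ann, "manhattan": mh}
        manifest["traits"][trait_name] = {
            "m_genome_wide": int(flagged["m_gw"].iloc[0]) if len(flagged) else 0,
            "m_per_chromosome": {
                str(c): int(g["m_cw"].iloc[0])
                for c, g in flagged.groupby("chrom", sort=False)
            },
            "rejections": {r.scope + "_" + r.level: int(r.n_rejected)
                           for r in summary.itertuples(index=False)},
        }

    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    bundle["manifest"] = manifest
    return bundle
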