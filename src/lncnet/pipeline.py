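"""End-to-end orchestration of the lncRNA-mRNA network pipeline.

Stages: differential expression (size factors, RPKM, NB Wald test, DE filter)
-> lncRNA-mRNA coexpression -> cis / trans / ceRNA layers -> functional
enrichment -> qPCR quantification and sequencing concordance. Each stage is a
pure function of its inputs and the configuration; ``run_pipeline`` wires
them together and writes every artifact (TSV tables, SIF networks, a summary)
into a run directory. Every stage is also exposed on the command line (see
:mod:`lncnet.cli`).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrichment, networks, qpcr
from .io import (
    read_counts,
    read_ct_table,
    read_gmt,
    read_gtf,
    read_mirna_targets,
    read_table,
    write_network,
    write_table,
)
from .networks import ce_edges, cis_edges, coexpression_edges, trans_edges

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_groups"]


@dataclass
class PipelineConfig:
    """Input paths, output directory and every decision threshold of a run."""

    counts: str = "counts.tsv"
    samples: str = "samples.tsv"
    gtf: str = "annotation.gtf"
    tf_gmt: str = "tf_targets.gmt"
    terms_gmt: str = "terms.gmt"
    mirna: str = "mirna_targets.tsv"
    ct: str = "qpcr_ct.tsv"
    outdir: str = "run"
    # thresholds (printed-method defaults)
    lfc_threshold: float = 1.0
    de_adj_p: float = 0.05
    coexpr_r: float = 0.9
    coexpr_p: float = 0.01
    cis_window_bp: int = 100_000
    trans_adj_p: float = 0.05
    enrich_adj_p: float = 0.05
    qpcr_p: float = 0.05
    # options
    bh_family: str = "separate"
    coexpr_transform: str = "log2"  # log2 | none
    ce_positive_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.coexpr_r < 1 or not 0 < self.coexpr_p < 1:
            raise ValueError("coexpression thresholds must lie in (0, 1)")
        for name in ("de_adj_p", "trans_adj_p", "enrich_adj_p", "qpcr_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.lfc_threshold < 0 or self.cis_window_bp < 0:
            raise ValueError("lfc_threshold and cis_window_bp must be >= 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    """In-memory results of a full run, mirroring the files on disk."""

    size_factors: pd.Series
    de_results: pd.DataFrame
    de_up: list[str]
    de_down: list[str]
    coexpression: list
    cis: list
    trans: list
    ce: list
    enrichment: pd.DataFrame
    qpcr_results: pd.DataFrame | None
    concordance: pd.DataFrame | None
    concordance_r: float | None
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def load_groups(path) -> dict[str, str]:
    """Read a samples TSV (sample_id, group) into a mapping."""
    df = read_table(path)
    return dict(zip(df["sample_id"], df["group"]))


def coexpression_input(cm, sf, transform: str = "log2") -> pd.DataFrame:
    """Expression matrix the coexpression stage correlates.

    Size-factor-normalised counts, log2(x+1)-transformed by default
    (``transform='none'`` correlates normalised counts directly).
    """
    q = diffexpr.normalized_counts(cm, sf)
    if transform == "log2":
        return np.log2(q + 1.0)
    if transform == "none":
        return q
    raise ValueError("coexpr_transform must be 'log2' or 'none'")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all artifacts under ``cfg.outdir``."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config_used.yaml")

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # annotate which stage died
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        return result

    # ---- load inputs
    groups = load_groups(cfg.samples)
    cm = stage("read_counts", lambda: read_counts(cfg.counts, groups))
    ann = stage("read_gtf", lambda: read_gtf(cfg.gtf))

    # ---- differential expression
    sf = stage("size_factors", lambda: diffexpr.size_factors(cm))
    write_table(sf.rename_axis("sample_id").reset_index(), out / "size_factors.tsv")
    rpkm_table = diffexpr.rpkm(cm)
    rpkm_table.index.name = "gene_id"
    rpkm_table.to_csv(out / "rpkm.tsv", sep="\t", float_format="%.6g")
    opts = diffexpr.DEOptions(
        lfc_threshold=cfg.lfc_threshold,
        adj_p_threshold=cfg.de_adj_p,
        bh_family=cfg.bh_family,
    )
    de = stage("nb_wald_test", lambda: diffexpr.nb_wald_test(cm, sf, opts))
    de.reset_index().to_csv(out / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
    up, down = diffexpr.filter_de(de)
    logger.info("DE: %d up, %d down of %d genes", len(up), len(down), len(de))

    de_sig = set(up) | set(down)
    de_lnc = [g for g in de.index if g in de_sig and de.loc[g, "biotype"] == "lncRNA"]
    de_mrna = [g for g in de.index if g in de_sig and de.loc[g, "biotype"] == "mRNA"]

    # ---- coexpression
    expr = coexpression_input(cm, sf, cfg.coexpr_transform)
    pairs = stage(
        "coexpression",
        lambda: networks.coexpression_pairs(
            expr, de_lnc, de_mrna, r_threshold=cfg.coexpr_r, p_threshold=cfg.coexpr_p
        ),
    )
    write_network(coexpression_edges(pairs), out / "coexpression.sif")
    write_table(
        pd.DataFrame([dataclasses.asdict(p) for p in pairs]), out / "coexpression.tsv"
    )

    # ---- cis layer
    cis = stage("cis_network", lambda: networks.cis_network(pairs, ann, cfg.cis_window_bp))
    write_network(cis_edges(cis), out / "cis.sif")
    write_table(
        pd.DataFrame(
            [
                {"lnc_id": p.lnc_id, "mrna_id": p.mrna_id, "distance_bp": p.distance_bp}
                for p in cis
            ]
        ),
        out / "cis_distances.tsv",
    )

    # ---- trans layer
    universe = {
        g for g in de.index if de.loc[g, "biotype"] == "mRNA" and not pd.isna(de.loc[g, "p"])
    }
    de_mrna_set = set(de_mrna)
    tf_sets = read_gmt(cfg.tf_gmt)
    trans = stage(
        "trans_network",
        lambda: networks.trans_network(pairs, tf_sets, de_mrna_set, cfg.trans_adj_p),
    )
    write_network(trans_edges(trans), out / "trans.sif")
    write_table(networks.trans_test_table(pairs, tf_sets, de_mrna_set), out / "trans_tests.tsv")

    # ---- ceRNA layer
    mt = read_mirna_targets(cfg.mirna)
    ce = stage(
        "ce_network",
        lambda: networks.ce_network(pairs, mt, positive_only=cfg.ce_positive_only),
    )
    write_network(ce_edges(ce), out / "ce.sif")
    write_table(pd.DataFrame([dataclasses.asdict(t) for t in ce]), out / "ce_triples.tsv")

    # ---- enrichment (DEmRNAs against the term collection)
    terms = read_gmt(cfg.terms_gmt)
    directions = de.loc[list(de_sig), "direction"].to_dict()
    if de_mrna_set:
        enr = stage(
            "enrichment",
            lambda: enrichment.ora(
                de_mrna_set, terms, universe, cfg.enrich_adj_p, directions
            ),
        )
    else:
        enr = pd.DataFrame()
        logger.warning("no DEmRNAs; enrichment skipped")
    write_table(enr, out / "enrichment.tsv")

    # ---- qPCR
    qpcr_results = concord = None
    concordance_r = None
    if cfg.ct and Path(cfg.ct).exists():
        records = read_ct_table(cfg.ct)
        quant = stage("ddct", lambda: qpcr.ddct(records))
        write_table(quant, out / "qpcr_quantities.tsv")
        qpcr_results = qpcr.qpcr_group_test(quant, cfg.qpcr_p)
        write_table(qpcr_results, out / "qpcr_results.tsv")
        shared = [t for t in qpcr_results["target_id"] if t in de.index]
        if shared:
            seq_lfc = de.loc[shared, "log2fc"]
            qpcr_lfc = qpcr_results.set_index("target_id")["log2fc"]
            concord, concordance_r = qpcr.concordance(seq_lfc, qpcr_lfc)
            concord = concord.copy()
            concord["pearson_r"] = concordance_r
            write_table(concord, out / "concordance.tsv")

    # ---- summary
    de_lnc_up = [g for g in up if de.loc[g, "biotype"] == "lncRNA"]
    de_mrna_up = [g for g in up if de.loc[g, "biotype"] == "mRNA"]
    summary = pd.DataFrame(
        [
            ("n_genes", len(de)),
            ("n_de_mrna", len(de_mrna)),
            ("n_de_mrna_up", len(de_mrna_up)),
            ("n_de_mrna_down", len(de_mrna) - len(de_mrna_up)),
            ("n_de_lnc", len(de_lnc)),
            ("n_de_lnc_up", len(de_lnc_up)),
            ("n_de_lnc_down", len(de_lnc) - len(de_lnc_up)),
            ("n_coexpression_pairs", len(pairs)),
            ("n_cis_pairs", len(cis)),
            ("n_trans_triples", len(trans)),
            ("n_trans_target_mrnas", len({m for t in trans for m in t.mrna_ids})),
            ("n_ce_triples", len(ce)),
            ("n_enriched_terms", int(enr["significant"].sum()) if len(enr) else 0),
        ],
        columns=["quantity", "value"],
    )
    write_table(summary, out / "summary.tsv")
    return PipelineResult(
        size_factors=sf,
        de_results=de,
        de_up=up,
        de_down=down,
        coexpression=pairs,
        cis=cis,
        trans=trans,
        ce=ce,
        enrichment=enr,
        qpcr_results=qpcr_results,
        concordance=concord,
        concordance_r=concordance_r,
        summary=summary,
    )
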