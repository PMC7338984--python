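"""Synthetic cohort generator with planted, recoverable ground truth.

Emulates the data layout of a small two-group blood RNA-seq study (5 patients
vs 5 controls) over mRNA and lncRNA features. Counts follow a negative
binomial model: mu_ij = s_j * base_i * 2^(log2fc_i * patient_j + o_ij) with a
per-gene dispersion, where o_ij is a latent log2-scale factor shared within
planted coexpression groups so that planted lncRNA-mRNA pairs reach a target
correlation rho. The generator plants, and records in a truth manifest:

* up/down-regulated genes at |log2FC| in {1.5, 2, 3} (downregulation
  predominates, as in bone-marrow-failure cohorts);
* coexpressed lncRNA-mRNA pairs at exact genomic distances below and above
  the 100 kb cis window, and on different chromosomes;
* a hub lncRNA whose coexpressed mRNAs are exactly one TF's target set
  (plus decoy TFs), for trans-layer recovery;
* lncRNA-mRNA pairs sharing a targeting miRNA (plus decoys and one
  anticorrelated shared-miRNA pair that must NOT become a ceRNA triple);
* an enriched functional term among decoy terms;
* qPCR Ct values consistent with the planted fold changes
  (Ct = baseline - log2fc * patient + noise, flat reference gene).

Every emitted file goes through :mod:`lncnet.io` writers, and all randomness
derives from one seeded generator, so same-seed runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneAnnotation,
    GeneSetCollection,
    write_counts,
    write_ct_table,
    write_gmt,
    write_gtf,
    write_mirna_targets,
    write_table,
)

__all__ = ["SimulationConfig", "TruthManifest", "SyntheticCohort", "simulate_cohort", "table2_fixture"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort. Defaults are the study conditions.

    Scale: 5 patients vs 5 controls; 800 mRNAs and 200 lncRNAs with
    log-normal base means (median 100) and gamma dispersions (mean 0.1,
    floor 0.01). Planted pair members use a stronger, cleaner signal (base
    mean 500, dispersion 0.01, shared latent factor of 0.7 log2 units) so
    the target correlation 0.98 survives counting noise; planted pair
    members are downregulated at log2FC -3.
    """

    seed: int = 0
    n_patients: int = 5
    n_controls: int = 5
    n_mrna: int = 800
    n_lnc: int = 200
    # per-gene NB parameters
    base_mean_log_mean: float = float(np.log(100.0))
    base_mean_log_sd: float = 1.0
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.05
    dispersion_floor: float = 0.01
    true_size_factor_sd: float = 0.15
    # free (non-pair) planted DE genes
    n_de_mrna: int = 100
    n_de_lnc: int = 24
    de_effect_magnitudes: tuple[float, ...] = (1.5, 2.0, 3.0)
    de_down_fraction: float = 0.85
    # per-gene biological variability (log2 sd) for genes outside planted
    # coexpression groups; keeps unrelated DE genes below the 0.9
    # coexpression threshold, as gene-specific variation does in real cohorts
    gene_biological_sd: float = 0.9
    # planted coexpression pairs
    pair_rho: float = 0.98
    pair_log2fc: float = -3.0
    pair_base_mean: float = 500.0
    pair_dispersion: float = 0.01
    pair_latent_sd: float = 0.7
    pair_gene_length: int = 1000
    n_cis_pairs: int = 4
    cis_distance_bp: int = 50_000
    n_far_pairs: int = 2
    far_distance_bp: int = 250_000
    n_diffchrom_pairs: int = 1
    n_ce_triples: int = 3
    include_anti_pair: bool = True
    # trans layer
    trans_hub_size: int = 8
    tf_extra_targets: int = 2
    n_tf_decoys: int = 5
    tf_decoy_size: int = 10
    # miRNA table decoys
    n_mirna_decoys: int = 15
    # enrichment terms
    enrich_term_size: int = 15
    n_enrich_decoys: int = 10
    enrich_decoy_size: int = 20
    # qPCR
    qpcr_n_targets: int = 6
    qpcr_noise_sd: float = 0.3
    qpcr_reference_ct: float = 18.0
    # genome layout
    gene_length_min: int = 500
    gene_length_max: int = 3000
    filler_spacing_bp: int = 300_000
    planted_spacing_bp: int = 2_000_000


@dataclass
class TruthManifest:
    """Planted ground truth, recorded at generation time.

    genes: per-gene truth (biotype, true_log2fc, true_base_mean, role);
    pairs: planted coexpression pairs with kind in
    {cis, far, diffchrom, ce, anti, hub} and exact planted distance
    (-1 across chromosomes); tf: the planted TF, its lncRNA and target set;
    ce_triples: planted (lnc, mirna, mrna); enrich_term: the planted term;
    qpcr_targets: validation targets with their true log2 fold changes.
    """

    genes: pd.DataFrame
    pairs: pd.DataFrame
    tf: dict
    ce_triples: list[dict]
    enrich_term: dict
    qpcr_targets: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="records"),
            "pairs": self.pairs.to_dict(orient="records"),
            "tf": self.tf,
            "ce_triples": self.ce_triples,
            "enrich_term": self.enrich_term,
            "qpcr_targets": self.qpcr_targets.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            genes=pd.DataFrame(payload["genes"]),
            pairs=pd.DataFrame(payload["pairs"]),
            tf=payload["tf"],
            ce_triples=payload["ce_triples"],
            enrich_term=payload["enrich_term"],
            qpcr_targets=pd.DataFrame(payload["qpcr_targets"]),
        )


@dataclass
class SyntheticCohort:
    """Paths of the emitted files plus the in-memory objects and manifest."""

    counts_path: Path
    gtf_path: Path
    tf_gmt_path: Path
    terms_gmt_path: Path
    mirna_path: Path
    ct_path: Path
    samples_path: Path
    manifest_path: Path
    count_matrix: CountMatrix
    annotation: GeneAnnotation
    groups: dict[str, str]
    manifest: TruthManifest


def _pair_kinds(cfg: SimulationConfig) -> list[str]:
    kinds = (
        ["cis"] * cfg.n_cis_pairs
        + ["far"] * cfg.n_far_pairs
        + ["diffchrom"] * cfg.n_diffchrom_pairs
        + ["ce"] * cfg.n_ce_triples
        + (["anti"] if cfg.include_anti_pair else [])
    )
    return kinds


def simulate_cohort(cfg: SimulationConfig, outdir) -> SyntheticCohort:
    """Generate a complete cohort under ``cfg`` and write it to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_patients + cfg.n_controls
    samples = [f"P{i+1}" for i in range(cfg.n_patients)] + [
        f"C{i+1}" for i in range(cfg.n_controls)
    ]
    groups = {s: ("patient" if s.startswith("P") else "control") for s in samples}
    is_patient = np.array([1.0 if groups[s] == "patient" else 0.0 for s in samples])

    mrna_ids = [f"M{i+1:04d}" for i in range(cfg.n_mrna)]
    lnc_ids = [f"L{i+1:04d}" for i in range(cfg.n_lnc)]
    gene_ids = mrna_ids + lnc_ids
    n_genes = len(gene_ids)
    biotype = pd.Series(
        ["mRNA"] * cfg.n_mrna + ["lncRNA"] * cfg.n_lnc, index=gene_ids, name="biotype"
    )

    # --- per-gene NB parameters -------------------------------------------
    base_mean = pd.Series(
        rng.lognormal(cfg.base_mean_log_mean, cfg.base_mean_log_sd, size=n_genes),
        index=gene_ids,
    )
    dispersion = pd.Series(
        np.maximum(
            rng.gamma(cfg.dispersion_shape, cfg.dispersion_scale, size=n_genes),
            cfg.dispersion_floor,
        ),
        index=gene_ids,
    )
    log2fc = pd.Series(0.0, index=gene_ids)
    role = pd.Series("null", index=gene_ids)

    # --- planted pair allocation ------------------------------------------
    kinds = _pair_kinds(cfg)
    pair_rows = []
    pair_lnc = [lnc_ids[i] for i in range(len(kinds))]
    pair_mrna = [mrna_ids[i] for i in range(len(kinds))]
    hub_lnc = lnc_ids[len(kinds)] if cfg.trans_hub_size > 0 else None
    hub_mrnas = mrna_ids[len(kinds) : len(kinds) + cfg.trans_hub_size]

    # free planted DE genes, after the pair/hub block
    free_de_mrna = mrna_ids[
        len(kinds) + cfg.trans_hub_size : len(kinds) + cfg.trans_hub_size + cfg.n_de_mrna
    ]
    free_de_lnc = lnc_ids[len(kinds) + 1 : len(kinds) + 1 + cfg.n_de_lnc]
    for gid in free_de_mrna + free_de_lnc:
        mag = rng.choice(cfg.de_effect_magnitudes)
        sign = -1.0 if rng.random() < cfg.de_down_fraction else 1.0
        log2fc[gid] = sign * mag
        role[gid] = "free_de"

    planted_members: dict[str, tuple[int, float]] = {}  # gene -> (group idx, latent sign)
    for gi, (kind, lnc, mrna) in enumerate(zip(kinds, pair_lnc, pair_mrna)):
        for gid in (lnc, mrna):
            base_mean[gid] = cfg.pair_base_mean
            dispersion[gid] = cfg.pair_dispersion
            role[gid] = f"pair_{kind}"
        if kind == "anti":
            log2fc[lnc] = cfg.pair_log2fc
            log2fc[mrna] = -cfg.pair_log2fc
            planted_members[lnc] = (gi, 1.0)
            planted_members[mrna] = (gi, -1.0)
        else:
            log2fc[lnc] = cfg.pair_log2fc
            log2fc[mrna] = cfg.pair_log2fc
            planted_members[lnc] = (gi, 1.0)
            planted_members[mrna] = (gi, 1.0)
    hub_group = len(kinds)
    for gid in ([hub_lnc, *hub_mrnas] if hub_lnc else []):
        base_mean[gid] = cfg.pair_base_mean
        dispersion[gid] = cfg.pair_dispersion
        log2fc[gid] = cfg.pair_log2fc
        role[gid] = "hub"
        planted_members[gid] = (hub_group, 1.0)

    # --- genome layout ----------------------------------------------------
    lengths = pd.Series(
        rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1, size=n_genes),
        index=gene_ids,
    )
    coords: dict[str, tuple[str, int, int]] = {}

    def place_pair(chrom: str, cursor: int, lnc: str, mrna: str, gap: int) -> int:
        L = cfg.pair_gene_length
        lengths[lnc] = L
        lengths[mrna] = L
        coords[lnc] = (chrom, cursor, cursor + L)
        m_start = cursor + L + gap
        coords[mrna] = (chrom, m_start, m_start + L)
        return m_start + L + cfg.planted_spacing_bp

    cursors = {f"chr{i}": 1_000_000 for i in range(1, 23)}
    dist_of_kind = {"cis": cfg.cis_distance_bp, "far": cfg.far_distance_bp}
    for kind, lnc, mrna in zip(kinds, pair_lnc, pair_mrna):
        if kind in dist_of_kind:
            chrom = "chr1" if kind == "cis" else "chr2"
            cursors[chrom] = place_pair(chrom, cursors[chrom], lnc, mrna, dist_of_kind[kind])
            dist = dist_of_kind[kind]
        else:  # diffchrom / ce / anti: members on different chromosomes
            ca, cb = ("chr3", "chr4") if kind in ("diffchrom", "anti") else ("chr5", "chr6")
            L = cfg.pair_gene_length
            lengths[lnc] = L
            lengths[mrna] = L
            coords[lnc] = (ca, cursors[ca], cursors[ca] + L)
            coords[mrna] = (cb, cursors[cb], cursors[cb] + L)
            cursors[ca] += cfg.planted_spacing_bp
            cursors[cb] += cfg.planted_spacing_bp
            dist = -1
        pair_rows.append(
            {
                "lnc_id": lnc,
                "mrna_id": mrna,
                "kind": kind,
                "rho": -cfg.pair_rho if kind == "anti" else cfg.pair_rho,
                "distance_bp": dist,
            }
        )
    # hub: lncRNA on chr7, its mRNAs on chr8 (never within the cis window)
    if hub_lnc:
        coords[hub_lnc] = ("chr7", cursors["chr7"], cursors["chr7"] + int(lengths[hub_lnc]))
        cursors["chr7"] += cfg.planted_spacing_bp
    for gid in hub_mrnas:
        coords[gid] = ("chr8", cursors["chr8"], cursors["chr8"] + int(lengths[gid]))
        cursors["chr8"] += cfg.planted_spacing_bp
        pair_rows.append(
            {
                "lnc_id": hub_lnc,
                "mrna_id": gid,
                "kind": "hub",
                "rho": cfg.pair_rho,
                "distance_bp": -1,
            }
        )
    # everything else: round-robin over chr9..chr22, spaced beyond the window
    filler_chroms = [f"chr{i}" for i in range(9, 23)]
    ci = 0
    for gid in gene_ids:
        if gid in coords:
            continue
        chrom = filler_chroms[ci % len(filler_chroms)]
        ci += 1
        start = cursors[chrom]
        coords[gid] = (chrom, start, start + int(lengths[gid]))
        cursors[chrom] = start + int(lengths[gid]) + cfg.filler_spacing_bp

    strands = pd.Series(np.where(rng.random(n_genes) < 0.5, "+", "-"), index=gene_ids)
    ann_table = pd.DataFrame(
        {
            "chrom": {g: coords[g][0] for g in gene_ids},
            "start": {g: coords[g][1] for g in gene_ids},
            "end": {g: coords[g][2] for g in gene_ids},
            "strand": strands,
            "biotype": biotype,
        }
    )
    ann_table.index.name = "gene_id"
    annotation = GeneAnnotation(table=ann_table)

    # --- counts -----------------------------------------------------------
    sf_true = rng.lognormal(0.0, cfg.true_size_factor_sd, size=n_samples)
    sf_true /= np.exp(np.mean(np.log(sf_true)))

    n_groups = len(kinds) + 1
    # bounded (uniform, unit-variance) latent factors for planted groups:
    # moderate shared biological covariation without single-sample outliers
    # that would swamp a pair member's within-group variance
    _unit_uniform = lambda size: rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=size)
    latent_shared = _unit_uniform((n_groups, n_samples))
    offsets = np.zeros((n_genes, n_samples))
    rho = cfg.pair_rho
    for i, gid in enumerate(gene_ids):
        if gid in planted_members:
            grp, sign = planted_members[gid]
            eps = _unit_uniform(n_samples)
            offsets[i] = cfg.pair_latent_sd * (
                sign * np.sqrt(rho) * latent_shared[grp] + np.sqrt(1.0 - rho) * eps
            )
        else:
            offsets[i] = cfg.gene_biological_sd * rng.normal(size=n_samples)
    # centre the latent offsets within each group: the realised group-mean
    # shift of every gene then equals its planted log2fc exactly, so null
    # genes are exactly null and planted effects are not perturbed
    for idx in (is_patient == 1.0, is_patient == 0.0):
        offsets[:, idx] -= offsets[:, idx].mean(axis=1, keepdims=True)
    mu = (
        base_mean.to_numpy()[:, None]
        * np.power(2.0, log2fc.to_numpy()[:, None] * is_patient[None, :] + offsets)
        * sf_true[None, :]
    )
    size_nb = 1.0 / dispersion.to_numpy()[:, None]
    counts = rng.negative_binomial(size_nb, size_nb / (size_nb + mu))
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        group=pd.Series(groups),
        biotype=biotype,
        gene_length_bp=lengths,
    )

    # --- TF target sets ---------------------------------------------------
    planted_de_mrnas = [g for g in mrna_ids if log2fc[g] != 0]
    decoy_pool = planted_de_mrnas if len(planted_de_mrnas) >= cfg.tf_decoy_size else mrna_ids
    extra = [g for g in free_de_mrna[: cfg.tf_extra_targets]]
    tf_sets = {
        "TF_PLANTED": set(hub_mrnas) | set(extra)
        if hub_mrnas
        else set(rng.choice(mrna_ids, size=cfg.tf_decoy_size, replace=False).tolist())
    }
    descriptions = {"TF_PLANTED": "planted hub regulator"}
    for d in range(cfg.n_tf_decoys):
        members = rng.choice(decoy_pool, size=cfg.tf_decoy_size, replace=False)
        tf_sets[f"TF_DECOY{d+1:02d}"] = set(members.tolist())
        descriptions[f"TF_DECOY{d+1:02d}"] = "decoy regulator"
    tf_gmt = GeneSetCollection(sets=tf_sets, descriptions=descriptions)

    # --- enrichment terms -------------------------------------------------
    term_members = free_de_mrna[: cfg.enrich_term_size]
    if not term_members:  # nothing planted: the "planted" term is a decoy too
        term_members = rng.choice(mrna_ids, size=cfg.enrich_term_size, replace=False).tolist()
    terms = {"TERM_PLANTED": set(term_members)}
    term_desc = {"TERM_PLANTED": "planted enriched process"}
    for d in range(cfg.n_enrich_decoys):
        members = rng.choice(mrna_ids, size=cfg.enrich_decoy_size, replace=False)
        terms[f"TERM_DECOY{d+1:02d}"] = set(members.tolist())
        term_desc[f"TERM_DECOY{d+1:02d}"] = "decoy process"
    terms_gmt = GeneSetCollection(sets=terms, descriptions=term_desc)

    # --- miRNA target table ------------------------------------------------
    mirna_rows = []
    ce_triples = []
    mir_i = 0
    for row in pair_rows:
        if row["kind"] in ("ce", "anti"):
            mir_i += 1
            mir = f"hsa-miR-{5000 + mir_i}"
            mirna_rows.append({"mirna_id": mir, "gene_id": row["lnc_id"], "gene_class": "lncRNA"})
            mirna_rows.append({"mirna_id": mir, "gene_id": row["mrna_id"], "gene_class": "mRNA"})
            if row["kind"] == "ce":
                ce_triples.append(
                    {"lnc_id": row["lnc_id"], "mirna_id": mir, "mrna_id": row["mrna_id"]}
                )
    for d in range(cfg.n_mirna_decoys):
        mir = f"hsa-miR-{6000 + d}"
        gid = str(rng.choice(gene_ids))
        mirna_rows.append(
            {
                "mirna_id": mir,
                "gene_id": gid,
                "gene_class": str(biotype[gid]),
            }
        )
    mirna_table = pd.DataFrame(mirna_rows).drop_duplicates(subset=["mirna_id", "gene_id"])

    # --- qPCR Ct values ----------------------------------------------------
    # validation panel: downregulated planted genes spanning the planted
    # effect magnitudes, half mRNA half lncRNA, restricted to well-expressed
    # genes so the sequencing fold change is stable
    qpcr_targets: list[str] = []
    per_biotype = cfg.qpcr_n_targets // 2
    for pool in (free_de_mrna, free_de_lnc):
        chosen: list[str] = []
        for mag in sorted(cfg.de_effect_magnitudes, reverse=True):
            for gid in pool:
                if gid in chosen:
                    continue
                if log2fc[gid] == -mag and base_mean[gid] >= 100.0:
                    chosen.append(gid)
                    break
            if len(chosen) == per_biotype:
                break
        for gid in pool:  # top up if some magnitude had no candidate
            if len(chosen) == per_biotype:
                break
            if gid not in chosen and log2fc[gid] < 0 and base_mean[gid] >= 100.0:
                chosen.append(gid)
        qpcr_targets.extend(chosen)
    ct_rows = []
    for target in qpcr_targets:
        baseline = float(rng.uniform(22.0, 28.0))
        noise = rng.normal(0.0, cfg.qpcr_noise_sd, size=n_samples)
        for j, s in enumerate(samples):
            ct_rows.append(
                {
                    "sample_id": s,
                    "group": groups[s],
                    "target_id": target,
                    "ct_target": baseline - log2fc[target] * is_patient[j] + noise[j],
                    "ct_reference": cfg.qpcr_reference_ct,
                }
            )
    ct_table = pd.DataFrame(ct_rows)

    # --- manifest -----------------------------------------------------------
    genes_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": biotype.to_numpy(),
            "true_log2fc": log2fc.to_numpy(),
            "true_base_mean": base_mean.to_numpy(),
            "role": role.to_numpy(),
        }
    )
    manifest = TruthManifest(
        genes=genes_truth,
        pairs=pd.DataFrame(pair_rows),
        tf={"name": "TF_PLANTED", "lnc_id": hub_lnc, "targets": sorted(tf_sets["TF_PLANTED"])},
        ce_triples=ce_triples,
        enrich_term={"name": "TERM_PLANTED", "members": sorted(terms["TERM_PLANTED"])},
        qpcr_targets=pd.DataFrame(
            {"target_id": qpcr_targets, "true_log2fc": [log2fc[t] for t in qpcr_targets]}
        ),
    )

    # --- write everything ----------------------------------------------------
    paths = {
        "counts_path": outdir / "counts.tsv",
        "gtf_path": outdir / "annotation.gtf",
        "tf_gmt_path": outdir / "tf_targets.gmt",
        "terms_gmt_path": outdir / "terms.gmt",
        "mirna_path": outdir / "mirna_targets.tsv",
        "ct_path": outdir / "qpcr_ct.tsv",
        "samples_path": outdir / "samples.tsv",
        "manifest_path": outdir / "truth_manifest.json",
    }
    write_counts(cm, paths["counts_path"])
    write_gtf(annotation, paths["gtf_path"])
    write_gmt(tf_gmt, paths["tf_gmt_path"])
    write_gmt(terms_gmt, paths["terms_gmt_path"])
    write_mirna_targets(mirna_table, paths["mirna_path"])
    write_ct_table(ct_table, paths["ct_path"])
    write_table(
        pd.DataFrame({"sample_id": samples, "group": [groups[s] for s in samples]}),
        paths["samples_path"],
    )
    manifest.to_json(paths["manifest_path"])
    return SyntheticCohort(
        **paths,
        count_matrix=cm,
        annotation=annotation,
        groups=groups,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# In-study fixture


_TABLE2 = [
    ("DHRS9", -2.37, "AC007556.1", "Cis/Ce"),
    ("HRH4", -2.64, "AC007922.2", "Cis"),
    ("PDGFA", -3.05, "AC147651.1", "Cis"),
    ("GFI1B", -2.69, "AC111000.4", "Trans"),
    ("IDO1", -4.87, "AC007991.2", "Cis"),
    ("SEMA7A", -1.49, "RHOXF1P1", "Trans"),
]


def table2_fixture() -> pd.DataFrame:
    """The six published immune/hematopoietic lncRNA-mRNA validation pairs.

    Columns: mrna_id, log2fc (sequencing, patient vs control), lnc_id,
    regulation_type. All six mRNAs were reported downregulated in patients.
    """
    return pd.DataFrame(
        _TABLE2, columns=["mrna_id", "log2fc", "lnc_id", "regulation_type"]
    )
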