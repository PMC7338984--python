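"""Readers and writers for every external format the pipeline touches.

Formats: TSV count matrix (with per-gene biotype and length columns), GTF gene
annotation, GMT gene-set collections, TSV miRNA-target tables, TSV qPCR Ct
tables, and SIF + attribute-TSV network exports. This module is the single
place where format dialects and the coordinate convention are decided:
internally every interval is 0-based half-open; GTF input (1-based inclusive)
is converted on read and converted back on write.

Biotype resolution: a gene is ``lncRNA`` iff its annotation biotype is in
:data:`LNCRNA_ALIASES`; anything in :data:`MRNA_ALIASES` is ``mRNA``; genes
with any other biotype are excluded with a logged warning (the alias sets are
module-level and may be extended by callers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pyranges

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GeneAnnotation",
    "GeneSetCollection",
    "Edge",
    "LNCRNA_ALIASES",
    "MRNA_ALIASES",
    "resolve_biotype",
    "read_counts",
    "write_counts",
    "read_gtf",
    "write_gtf",
    "read_gmt",
    "write_gmt",
    "read_mirna_targets",
    "write_mirna_targets",
    "read_ct_table",
    "write_ct_table",
    "read_network",
    "write_network",
    "read_table",
    "write_table",
]

#: annotation biotypes mapped to the internal ``lncRNA`` class
LNCRNA_ALIASES = {"lncRNA", "lincRNA", "antisense", "processed_transcript-lnc"}
#: annotation biotypes mapped to the internal ``mRNA`` class
MRNA_ALIASES = {"mRNA", "protein_coding"}

GROUPS = ("patient", "control")


def resolve_biotype(raw: str) -> str | None:
    """Map an annotation biotype string to ``mRNA``/``lncRNA`` or None."""
    if raw in MRNA_ALIASES:
        return "mRNA"
    if raw in LNCRNA_ALIASES:
        return "lncRNA"
    return None


# ---------------------------------------------------------------------------
# CountMatrix


@dataclass
class CountMatrix:
    """Integer RNA-seq counts, genes x samples, with group and gene metadata.

    Attributes
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts; index gene ids, columns sample ids.
    group : pandas.Series
        Per-sample label in {patient, control}, indexed by sample id.
    biotype : pandas.Series
        Per-gene label in {mRNA, lncRNA}, indexed by gene id.
    gene_length_bp : pandas.Series
        Positive per-gene length used for RPKM.
    """

    counts: pd.DataFrame
    group: pd.Series
    biotype: pd.Series
    gene_length_bp: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.empty:
            raise ValueError("empty count matrix")
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = c = c.round().astype(np.int64)
            vals = c.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(c.columns) - set(self.group.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        self.group = self.group.reindex(c.columns)
        bad = set(self.group.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in GROUPS:
            if (self.group == g).sum() == 0:
                raise ValueError(f"group '{g}' has no samples")
        self.biotype = self.biotype.reindex(c.index)
        if self.biotype.isna().any():
            raise ValueError("every gene needs a biotype")
        self.gene_length_bp = self.gene_length_bp.reindex(c.index)
        if self.gene_length_bp.isna().any() or (self.gene_length_bp < 1).any():
            raise ValueError("gene_length_bp must be present and >= 1")
        self.gene_length_bp = self.gene_length_bp.astype(np.int64)
        self.counts.index.name = "gene_id"
        self.counts.columns.name = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in(self, group: str) -> pd.Index:
        return self.group.index[self.group == group]

    def genes_of(self, biotype: str) -> pd.Index:
        return self.biotype.index[self.biotype == biotype]


def read_counts(path, groups: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count matrix into a validated :class:`CountMatrix`.

    The TSV has the gene id in the first column; the columns ``biotype`` and
    ``gene_length_bp`` carry per-gene metadata and every other column is a
    sample. ``groups`` maps each sample id to ``patient`` or ``control``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = [c for c in ("biotype", "gene_length_bp") if c in df.columns]
    if "biotype" not in meta_cols or "gene_length_bp" not in meta_cols:
        raise ValueError("count TSV must carry 'biotype' and 'gene_length_bp' columns")
    biotype = df["biotype"]
    length = df["gene_length_bp"]
    counts = df.drop(columns=meta_cols)
    if not counts.columns.size:
        raise ValueError("no sample columns in count TSV")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("non-numeric count cells")
    if np.issubdtype(arr.dtype, np.floating) and not np.allclose(arr, np.round(arr)):
        raise ValueError("non-integer count cells")
    group = pd.Series({s: groups[s] for s in counts.columns if s in groups})
    missing = set(counts.columns) - set(group.index)
    if missing:
        raise ValueError(f"no group given for samples: {sorted(missing)}")
    return CountMatrix(
        counts=counts.astype(np.int64),
        group=group,
        biotype=biotype,
        gene_length_bp=length,
    )


def write_counts(cm: CountMatrix, path) -> None:
    """Write a CountMatrix as TSV (gene_id, biotype, gene_length_bp, samples)."""
    out = cm.counts.copy()
    out.insert(0, "gene_length_bp", cm.gene_length_bp)
    out.insert(0, "biotype", cm.biotype)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GeneAnnotation / GTF


@dataclass
class GeneAnnotation:
    """Per-gene genomic intervals, 0-based half-open.

    ``table`` is indexed by gene id with columns chrom, start, end, strand,
    biotype (already resolved to mRNA/lncRNA).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if (t["start"] < 0).any() or (t["start"] >= t["end"]).any():
            raise ValueError("intervals must satisfy 0 <= start < end")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    def interval(self, gene_id: str) -> tuple[str, int, int]:
        row = self.table.loc[gene_id]
        return str(row["chrom"]), int(row["start"]), int(row["end"])


_BIOTYPE_ATTRS = ("gene_biotype", "gene_type", "biotype")


def read_gtf(path) -> GeneAnnotation:
    """Read gene annotation from GTF, one interval per gene.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    A gene spanning several feature lines gets the envelope interval
    (min start, max end). Features without a gene_id raise; genes with an
    unrecognised biotype are dropped with a warning.
    """
    gr = pyranges.read_gtf(path)
    df = gr.df
    if df.empty:
        raise ValueError(f"no features in GTF {path}")
    if "gene_id" not in df.columns or df["gene_id"].isna().any():
        raise ValueError("GTF feature missing gene_id attribute")
    attr = next((a for a in _BIOTYPE_ATTRS if a in df.columns), None)
    if attr is None:
        raise ValueError("GTF carries no biotype attribute")
    rows = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        chroms = sub["Chromosome"].unique()
        if len(chroms) > 1:
            raise ValueError(f"gene {gene_id} spans multiple chromosomes")
        raw = sub[attr].iloc[0]
        biotype = resolve_biotype(raw)
        if biotype is None:
            logger.warning("gene %s: unrecognised biotype %r, excluded", gene_id, raw)
            continue
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": str(chroms[0]),
                "start": int(sub["Start"].min()),
                "end": int(sub["End"].max()),
                "strand": str(sub["Strand"].iloc[0]),
                "biotype": biotype,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    return GeneAnnotation(table=table)


def write_gtf(ann: GeneAnnotation, path, source: str = "lncnet") -> None:
    """Write one gene-level GTF line per annotation entry (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene_id, row in ann.table.iterrows():
            raw_biotype = "protein_coding" if row["biotype"] == "mRNA" else "lncRNA"
            attrs = f'gene_id "{gene_id}"; gene_biotype "{raw_biotype}";'
            fh.write(
                "\t".join(
                    [
                        row["chrom"],
                        source,
                        "gene",
                        str(int(row["start"]) + 1),
                        str(int(row["end"])),
                        ".",
                        row["strand"],
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GeneSetCollection / GMT


@dataclass
class GeneSetCollection:
    """Named gene sets (TF targets, GO/KEGG-style terms)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set '{name}' is empty")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: tab-separated name, description, member genes."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise ValueError(f"duplicate gene-set name '{name}'")
            if not members:
                raise ValueError(f"gene set '{name}' is empty")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gsc.sets):
            desc = gsc.descriptions.get(name, "na")
            members = "\t".join(sorted(gsc.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# miRNA targets


def read_mirna_targets(path) -> pd.DataFrame:
    """Read a miRNA-target TSV (mirna_id, gene_id, gene_class), deduplicated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "gene_id", "gene_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"miRNA table needs columns {sorted(required)}")
    bad = set(df["gene_class"].unique()) - {"mRNA", "lncRNA"}
    if bad:
        raise ValueError(f"unknown gene_class values: {sorted(bad)}")
    df = df.drop_duplicates(subset=["mirna_id", "gene_id"]).reset_index(drop=True)
    return df


def write_mirna_targets(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qPCR Ct table


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR Ct TSV (sample_id, group, target_id, ct_target, ct_reference)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "target_id", "ct_target", "ct_reference"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if df[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct value")
    if (df[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be finite and > 0")
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Network edge lists (SIF + attribute sidecar)

INTERACTION_TYPES = ("coexpr", "cis", "trans_tf", "ce_mirna")


@dataclass(frozen=True)
class Edge:
    """A typed network edge with numeric attributes (r, p, distance_bp, ...)."""

    source: str
    interaction: str
    target: str
    attributes: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-edge on {self.source}")
        if self.interaction not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction!r}")
        # canonical attribute order so equality is insensitive to input order
        object.__setattr__(self, "attributes", tuple(sorted(self.attributes)))


def write_network(edges: list[Edge], sif_path, attr_path=None) -> None:
    """Write edges as SIF (source, interaction, target) + TSV attribute sidecar."""
    sif_path = Path(sif_path)
    if attr_path is None:
        attr_path = sif_path.with_suffix(sif_path.suffix + ".attrs.tsv")
    keys: list[str] = []
    for e in edges:
        for k, _ in e.attributes:
            if k not in keys:
                keys.append(k)
    with open(sif_path, "w") as fh:
        for e in edges:
            fh.write(f"{e.source}\t{e.interaction}\t{e.target}\n")
    with open(attr_path, "w") as fh:
        fh.write("\t".join(["source", "interaction", "target", *keys]) + "\n")
        for e in edges:
            attrs = dict(e.attributes)
            vals = [repr(attrs[k]) if k in attrs else "" for k in keys]
            fh.write("\t".join([e.source, e.interaction, e.target, *vals]) + "\n")


def read_network(sif_path, attr_path=None) -> list[Edge]:
    sif_path = Path(sif_path)
    if attr_path is None:
        attr_path = sif_path.with_suffix(sif_path.suffix + ".attrs.tsv")
    edges: list[Edge] = []
    with open(attr_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        keys = header[3:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            src, inter, tgt = parts[0], parts[1], parts[2]
            attrs = tuple(
                (k, float(v)) for k, v in zip(keys, parts[3:]) if v != ""
            )
            edges.append(Edge(source=src, interaction=inter, target=tgt, attributes=attrs))
    with open(sif_path) as fh:
        n_sif = sum(1 for line in fh if line.strip())
    if n_sif != len(edges):
        raise ValueError("SIF and attribute sidecar disagree on edge count")
    return edges


# ---------------------------------------------------------------------------
# Generic TSV tables


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as UTF-8 TSV with header."""
    df.to_csv(path, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
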