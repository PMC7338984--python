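"""Coexpression graph and the three lncRNA regulatory layers.

From the differentially expressed (DE) gene sets three layers are derived:

* **cis** — coexpressed DElncRNA-DEmRNA pairs whose gene bodies lie within a
  symmetric genomic window (default 100 kb) on the same chromosome;
* **trans** — lncRNAs whose coexpressed mRNA sets over-represent the target
  set of a transcription factor (hypergeometric upper tail, BH-adjusted);
* **ceRNA** — positively coexpressed pairs in which lncRNA and mRNA share a
  predicted targeting miRNA, i.e. the lncRNA may sponge the miRNA away from
  the mRNA.

Coexpression is Pearson correlation on log2(normalised counts + 1) across all
samples; a pair is retained only when both |r| exceeds the correlation
threshold and the t-based p-value is below the p threshold.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Edge, GeneAnnotation, GeneSetCollection
from .stats import bh_adjust, hypergeom_sf, pearson_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionPair",
    "CisPair",
    "TransTriple",
    "CeTriple",
    "SeedSite",
    "coexpression_pairs",
    "genomic_distance",
    "cis_network",
    "trans_network",
    "ce_network",
    "seed_match_scan",
    "coexpression_edges",
    "cis_edges",
    "trans_edges",
    "ce_edges",
]


@dataclass(frozen=True)
class CoexpressionPair:
    lnc_id: str
    mrna_id: str
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class CisPair:
    lnc_id: str
    mrna_id: str
    distance_bp: int
    r: float
    p: float


@dataclass(frozen=True)
class TransTriple:
    lnc_id: str
    tf_name: str
    mrna_ids: tuple[str, ...]
    N: int
    K: int
    n: int
    k: int
    p: float
    adj_p: float


@dataclass(frozen=True)
class CeTriple:
    lnc_id: str
    mirna_id: str
    mrna_id: str
    r: float


def coexpression_pairs(
    expr: pd.DataFrame,
    lnc_ids,
    mrna_ids,
    r_threshold: float = 0.9,
    p_threshold: float = 0.01,
) -> list[CoexpressionPair]:
    """All lncRNA x mRNA pairs with |r| > r_threshold and p < p_threshold.

    ``expr`` holds one expression row per DE gene (already normalised and
    log-transformed) over all samples. Constant rows have an undefined
    correlation and are skipped with a warning. Exhaustive over the two id
    lists; both threshold conditions are strict.
    """
    lnc_ids = [g for g in lnc_ids if g in expr.index]
    mrna_ids = [g for g in mrna_ids if g in expr.index]
    if not lnc_ids or not mrna_ids:
        return []
    n = expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")

    def _standardised(ids):
        mat = expr.loc[ids].to_numpy(dtype=float)
        sd = mat.std(axis=1)
        keep = sd > 0
        for g, ok in zip(ids, keep):
            if not ok:
                logger.warning("gene %s: constant expression, skipped", g)
        mat = mat[keep]
        mat = mat - mat.mean(axis=1, keepdims=True)
        mat /= np.linalg.norm(mat, axis=1, keepdims=True)
        return [g for g, ok in zip(ids, keep) if ok], mat

    lnc_kept, lmat = _standardised(lnc_ids)
    mrna_kept, mmat = _standardised(mrna_ids)
    if not lnc_kept or not mrna_kept:
        return []
    rmat = np.clip(lmat @ mmat.T, -1.0, 1.0)
    pmat = pearson_pvalues(rmat, n)
    pairs = []
    for i, lnc in enumerate(lnc_kept):
        for j, mrna in enumerate(mrna_kept):
            r, p = float(rmat[i, j]), float(pmat[i, j])
            if abs(r) > r_threshold and p < p_threshold:
                pairs.append(CoexpressionPair(lnc_id=lnc, mrna_id=mrna, r=r, p=p, n=n))
    return pairs


def genomic_distance(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> int | None:
    """Gap in bases between two gene-body intervals, or None across chromosomes.

    Intervals are (chrom, start, end), 0-based half-open. Overlapping or
    abutting intervals have distance 0; otherwise the distance is the number
    of bases strictly between them. Strand-agnostic.
    """
    chrom_a, start_a, end_a = a
    chrom_b, start_b, end_b = b
    if chrom_a != chrom_b:
        return None
    return max(0, max(start_a, start_b) - min(end_a, end_b))


def cis_network(
    pairs: list[CoexpressionPair],
    ann: GeneAnnotation,
    window_bp: int = 100_000,
) -> list[CisPair]:
    """Coexpressed pairs whose gene bodies lie within window_bp (inclusive).

    Pairs with a member missing from the annotation are skipped with a
    warning; pairs on different chromosomes are never cis.
    """
    out = []
    for pair in pairs:
        missing = [g for g in (pair.lnc_id, pair.mrna_id) if g not in ann]
        if missing:
            logger.warning("cis: no annotation for %s, pair skipped", missing)
            continue
        d = genomic_distance(ann.interval(pair.lnc_id), ann.interval(pair.mrna_id))
        if d is not None and d <= window_bp:
            out.append(
                CisPair(
                    lnc_id=pair.lnc_id,
                    mrna_id=pair.mrna_id,
                    distance_bp=d,
                    r=pair.r,
                    p=pair.p,
                )
            )
    return out


def trans_network(
    pairs: list[CoexpressionPair],
    tf_sets: GeneSetCollection,
    universe: set[str],
    adj_p_threshold: float = 0.05,
) -> list[TransTriple]:
    """lncRNA-TF links by hypergeometric overlap of coexpressed and TF-target mRNAs.

    For each (lncRNA, TF): the universe is the DEmRNA set (size N), the
    category is the TF's targets within the universe (K), the draw is the
    lncRNA's coexpressed mRNAs (n) and k their overlap. p-values are
    BH-adjusted across all performed (lncRNA, TF) tests; triples with
    adj_p < adj_p_threshold are returned, carrying the overlap genes as the
    trans-regulated targets. Tests with K = 0 or n = 0 are skipped.
    """
    if not universe:
        raise ValueError("empty DEmRNA universe")
    coexpr: dict[str, set[str]] = {}
    for pair in pairs:
        coexpr.setdefault(pair.lnc_id, set()).add(pair.mrna_id)
    N = len(universe)
    tests = []
    for lnc, mrnas in sorted(coexpr.items()):
        drawn = mrnas & universe
        if not drawn:
            continue
        for tf in sorted(tf_sets):
            targets = tf_sets[tf] & universe
            if not targets:
                continue
            overlap = tuple(sorted(drawn & targets))
            p = hypergeom_sf(N, len(targets), len(drawn), len(overlap))
            tests.append((lnc, tf, overlap, len(targets), len(drawn), p))
    if not tests:
        return []
    adj = bh_adjust([t[5] for t in tests])
    out = []
    for (lnc, tf, overlap, K, n, p), ap in zip(tests, adj):
        if ap < adj_p_threshold:
            out.append(
                TransTriple(
                    lnc_id=lnc, tf_name=tf, mrna_ids=overlap,
                    N=N, K=K, n=n, k=len(overlap), p=p, adj_p=float(ap),
                )
            )
    return out


def trans_test_table(
    pairs: list[CoexpressionPair],
    tf_sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """All performed (lncRNA, TF) hypergeometric tests as a table."""
    triples = trans_network(pairs, tf_sets, universe, adj_p_threshold=np.inf)
    return pd.DataFrame(
        [
            {
                "lnc_id": t.lnc_id, "tf_name": t.tf_name, "N": t.N, "K": t.K,
                "n": t.n, "k": t.k, "p": t.p, "adj_p": t.adj_p,
            }
            for t in triples
        ]
    )


def ce_network(
    pairs: list[CoexpressionPair], mt: pd.DataFrame, positive_only: bool = True
) -> list[CeTriple]:
    """Competing-endogenous triples: shared miRNA over a positive coexpressed pair.

    For each coexpressed pair with r > 0, one triple is emitted per miRNA in
    the target table that targets both the lncRNA and the mRNA. Negatively
    correlated pairs are excluded by default: the sponge model implies
    co-directional expression of lncRNA and mRNA (set ``positive_only=False``
    to lift the sign requirement).
    """
    by_gene: dict[str, set[str]] = {}
    for row in mt.itertuples(index=False):
        by_gene.setdefault(row.gene_id, set()).add(row.mirna_id)
    out = []
    for pair in pairs:
        if positive_only and pair.r <= 0:
            continue
        shared = by_gene.get(pair.lnc_id, set()) & by_gene.get(pair.mrna_id, set())
        for mirna in sorted(shared):
            out.append(
                CeTriple(lnc_id=pair.lnc_id, mirna_id=mirna, mrna_id=pair.mrna_id, r=pair.r)
            )
    return out


# ---------------------------------------------------------------------------
# Canonical miRNA seed-match scanning (optional stand-in for a target table)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SeedSite:
    """A canonical seed-match site on a target, 0-based [start, end)."""

    kind: str  # 6mer | 7mer-A1 | 7mer-m8 | 8mer
    start: int
    end: int


def _normalise(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    if s and not re.fullmatch(r"[ACGT]+", s):
        raise ValueError(f"{what} contains characters outside A/C/G/U/T")
    return s


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def seed_match_scan(mirna_seq: str, target_seq: str) -> list[SeedSite]:
    """Scan a target for canonical seed matches to a miRNA (both 5'->3').

    Site classes follow the canonical hierarchy: the core 6mer is the exact
    Watson-Crick match to miRNA positions 2-7; position 8 pairing extends it
    on the target's 5' side (m8) and an adenine opposite miRNA position 1
    extends it on the 3' side (A1); both together make an 8mer. Each core
    match is reported once with its strongest class. U and T are equivalent
    and case is ignored.
    """
    m = _normalise(mirna_seq, "miRNA")
    t = _normalise(target_seq, "target")
    if len(m) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    if not t:
        return []
    core = _revcomp(m[1:7])  # positions 2-7
    m8_base = m[7].translate(_COMPLEMENT)  # complement of position 8
    sites = []
    for i in range(len(t) - 5):
        if t[i : i + 6] != core:
            continue
        has_m8 = i > 0 and t[i - 1] == m8_base
        has_a1 = i + 6 < len(t) and t[i + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite("8mer", i - 1, i + 7))
        elif has_m8:
            sites.append(SeedSite("7mer-m8", i - 1, i + 6))
        elif has_a1:
            sites.append(SeedSite("7mer-A1", i, i + 7))
        else:
            sites.append(SeedSite("6mer", i, i + 6))
    return sites


# ---------------------------------------------------------------------------
# Edge-list exports


def coexpression_edges(pairs: list[CoexpressionPair]) -> list[Edge]:
    return [
        Edge(
            source=p.lnc_id, interaction="coexpr", target=p.mrna_id,
            attributes=(("r", float(p.r)), ("p", float(p.p)), ("n", float(p.n))),
        )
        for p in pairs
    ]


def cis_edges(pairs: list[CisPair]) -> list[Edge]:
    return [
        Edge(
            source=p.lnc_id, interaction="cis", target=p.mrna_id,
            attributes=(
                ("distance_bp", float(p.distance_bp)),
                ("r", float(p.r)), ("p", float(p.p)),
            ),
        )
        for p in pairs
    ]


def trans_edges(triples: list[TransTriple]) -> list[Edge]:
    """lnc->TF and TF->mRNA edges for each significant trans triple."""
    edges = []
    for t in triples:
        edges.append(
            Edge(
                source=t.lnc_id, interaction="trans_tf", target=t.tf_name,
                attributes=(("k", float(t.k)), ("adj_p", float(t.adj_p))),
            )
        )
        for mrna in t.mrna_ids:
            edges.append(
                Edge(
                    source=t.tf_name, interaction="trans_tf", target=mrna,
                    attributes=(("adj_p", float(t.adj_p)),),
                )
            )
    return edges


def ce_edges(triples: list[CeTriple]) -> list[Edge]:
    """lnc->miRNA and miRNA->mRNA edges for each ceRNA triple."""
    edges = []
    for t in triples:
        edges.append(
            Edge(
                source=t.lnc_id, interaction="ce_mirna", target=t.mirna_id,
                attributes=(("r", float(t.r)),),
            )
        )
        edges.append(
            Edge(
                source=t.mirna_id, interaction="ce_mirna", target=t.mrna_id,
                attributes=(("r", float(t.r)),),
            )
        )
    return edges
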