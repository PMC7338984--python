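"""Normalisation and a minimal negative-binomial Wald differential-expression test.

The test follows the classical NB pipeline: median-of-ratios size factors,
normalised counts, a method-of-moments dispersion per gene, a Wald statistic
on the (pseudocounted) log2 fold change, and Benjamini-Hochberg adjustment.
It deliberately does NOT reproduce full DESeq2 numerics — no Cox-Reid
dispersion shrinkage, no fold-change shrinkage, no independent filtering —
but shares its model (counts ~ NB with variance mu + alpha * mu^2) and its
normalisation, so calls agree with DESeq2-style tools on strong effects.

Fold changes are patient over control: a negative log2FC means the gene is
lower in patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import CountMatrix
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "DEOptions",
    "size_factors",
    "normalized_counts",
    "rpkm",
    "nb_wald_test",
    "filter_de",
]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class DEOptions:
    """Tunable parameters of the DE stage.

    lfc_threshold and adj_p_threshold define the significance filter
    (|log2FC| > lfc_threshold AND adj_p < adj_p_threshold, both strict).
    pseudocount is added to group-mean normalised counts before the log
    ratio; alpha_min floors the method-of-moments dispersion. bh_family
    selects whether mRNA and lncRNA p-values are adjusted as separate
    families ("separate", default) or one joint family ("joint").
    """

    lfc_threshold: float = 1.0
    adj_p_threshold: float = 0.05
    pseudocount: float = 0.5
    alpha_min: float = 0.01
    bh_family: str = "separate"


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over genes with all-positive
    counts of count / (gene-wise geometric mean across samples). If no gene
    is positive in every sample, falls back to library-size ratios with a
    warning.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        logc = np.log(counts[all_positive])
        log_geomean = logc.mean(axis=1, keepdims=True)
        ratios = np.exp(logc - log_geomean)
        sf = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no gene with positive counts in every sample; "
            "falling back to library-size ratios"
        )
        sf = cm.library_sizes.to_numpy(dtype=float)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def normalized_counts(cm: CountMatrix, sf: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if sf is None:
        sf = size_factors(cm)
    return cm.counts / sf.reindex(cm.sample_ids)


def rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM_ij = count_ij / ((library_size_j / 1e6) * (length_i / 1e3)).
    """
    lib = cm.library_sizes.to_numpy(dtype=float)
    if (lib == 0).any():
        raise ValueError("zero library size")
    length_kb = cm.gene_length_bp.to_numpy(dtype=float) / 1e3
    vals = cm.counts.to_numpy(dtype=float) / (lib[None, :] / 1e6) / length_kb[:, None]
    return pd.DataFrame(vals, index=cm.gene_ids, columns=cm.sample_ids)


def _moments_dispersion(q: np.ndarray, groups: list[np.ndarray], alpha_min: float) -> np.ndarray:
    """Method-of-moments NB dispersion per gene, pooled within groups.

    Residual variance is pooled across the two groups (df = n - 2); the
    dispersion solves var = mu + alpha * mu^2 at the overall mean, floored
    at alpha_min.
    """
    n = q.shape[1]
    ss = np.zeros(q.shape[0])
    for idx in groups:
        sub = q[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / (n - 2)
    mu = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, alpha_min)
    return np.maximum(alpha, alpha_min)


def nb_wald_test(
    cm: CountMatrix,
    sf: pd.Series | None = None,
    options: DEOptions = DEOptions(),
) -> pd.DataFrame:
    """Per-gene NB Wald test of patient vs control.

    Returns a DataFrame indexed by gene id with columns biotype, base_mean,
    log2fc, p, adj_p, significant, direction. Genes with all-zero counts are
    excluded from testing and from the BH family (NaN p/adj_p, never
    significant). The Wald statistic divides the pseudocounted log2 fold
    change by a delta-method standard error propagated from the NB variance
    mu + alpha * mu^2 of each group mean.
    """
    patients = cm.samples_in("patient")
    controls = cm.samples_in("control")
    if len(patients) < 2 or len(controls) < 2:
        raise ValueError("each group needs at least 2 samples")
    if sf is None:
        sf = size_factors(cm)
    q = normalized_counts(cm, sf).to_numpy(dtype=float)
    cols = list(cm.sample_ids)
    ipat = np.array([cols.index(s) for s in patients])
    ictl = np.array([cols.index(s) for s in controls])

    tested = cm.counts.to_numpy().sum(axis=1) > 0
    c = options.pseudocount
    m_pat = q[:, ipat].mean(axis=1)
    m_ctl = q[:, ictl].mean(axis=1)
    log2fc = np.log2((m_pat + c) / (m_ctl + c))
    base_mean = q.mean(axis=1)

    alpha = _moments_dispersion(q, [ipat, ictl], options.alpha_min)
    # delta method: Var(log2(m + c)) ~= Var(m) / ((m + c) ln2)^2,
    # Var(m_g) = (mu_g + alpha mu_g^2) / n_g with mu_g estimated by m_g
    var_pat = (m_pat + alpha * m_pat**2) / len(ipat)
    var_ctl = (m_ctl + alpha * m_ctl**2) / len(ictl)
    se = np.sqrt(
        var_pat / ((m_pat + c) * LN2) ** 2 + var_ctl / ((m_ctl + c) * LN2) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * scipy.stats.norm.sf(np.abs(wald))
    p[~tested] = np.nan

    res = pd.DataFrame(
        {
            "biotype": cm.biotype,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
        },
        index=cm.gene_ids,
    )
    res["adj_p"] = np.nan
    if options.bh_family == "separate":
        families = [res.index[tested & (cm.biotype == b).to_numpy()] for b in ("mRNA", "lncRNA")]
    elif options.bh_family == "joint":
        families = [res.index[tested]]
    else:
        raise ValueError("bh_family must be 'separate' or 'joint'")
    for fam in families:
        if len(fam):
            res.loc[fam, "adj_p"] = bh_adjust(res.loc[fam, "p"].to_numpy())
    res["significant"] = (
        (res["log2fc"].abs() > options.lfc_threshold)
        & (res["adj_p"] < options.adj_p_threshold)
    ).fillna(False)
    res["direction"] = np.where(res["log2fc"] > 0, "up", "down")
    res.index.name = "gene_id"
    return res


def filter_de(results: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Partition significant genes into (up, down) id lists."""
    if results.empty:
        return [], []
    sig = results[results["significant"]]
    up = sig.index[sig["direction"] == "up"].tolist()
    down = sig.index[sig["direction"] == "down"].tolist()
    return up, down
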