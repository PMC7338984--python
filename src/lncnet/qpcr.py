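"""Relative qPCR quantification by the 2^-ddCt method and seq/qPCR concordance.

Per (sample, target): dCt = Ct(target) - Ct(reference); ddCt subtracts the
mean control-group dCt of that target (the calibrator); the relative quantity
is 2^-ddCt, so the control group has geometric-mean RQ 1 by construction.
Group comparison is a pooled-variance Student t-test on dCt values (the
approximately normal, log2 scale) and the per-target qPCR log2 fold change is
-(mean patient dCt - mean control dCt) exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import pearson, two_sample_t

__all__ = ["ddct", "qpcr_group_test", "concordance", "stars"]


def ddct(records: pd.DataFrame) -> pd.DataFrame:
    """2^-ddCt relative quantities from a long-format Ct table.

    ``records`` columns: sample_id, group, target_id, ct_target, ct_reference.
    Technical replicates (duplicate sample/target rows) are mean-collapsed
    first. Requires >= 2 control samples per target. Returns one row per
    (sample, target) with delta_ct, delta_delta_ct and rq columns.
    """
    required = {"sample_id", "group", "target_id", "ct_target", "ct_reference"}
    if not required.issubset(records.columns):
        raise ValueError(f"Ct records need columns {sorted(required)}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct value")
    df = (
        records.groupby(["sample_id", "group", "target_id"], as_index=False)[
            ["ct_target", "ct_reference"]
        ].mean()
    )
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    out = []
    for target, sub in df.groupby("target_id", sort=True):
        ctl = sub.loc[sub["group"] == "control", "delta_ct"]
        if len(ctl) < 2:
            raise ValueError(f"target {target}: need >= 2 control samples")
        calibrator = ctl.mean()
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - calibrator
        sub["rq"] = 2.0 ** (-sub["delta_delta_ct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def stars(p: float) -> str:
    """Significance stars: ** for p < 0.01, * for p < 0.05, else empty."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def qpcr_group_test(quant: pd.DataFrame, p_threshold: float = 0.05) -> pd.DataFrame:
    """Per-target patient-vs-control comparison of a :func:`ddct` result.

    The t-test operates on dCt values. Reported per target: qPCR log2 fold
    change (patient vs control), mean RQ per group with SDs of both RQ and
    dCt, the t statistic, p, significance stars.
    """
    rows = []
    for target, sub in quant.groupby("target_id", sort=True):
        pat = sub.loc[sub["group"] == "patient", "delta_ct"].to_numpy()
        ctl = sub.loc[sub["group"] == "control", "delta_ct"].to_numpy()
        t, p = two_sample_t(pat, ctl)
        # higher dCt = fewer transcripts, hence the sign flip
        log2fc = -(pat.mean() - ctl.mean())
        rq_pat = sub.loc[sub["group"] == "patient", "rq"]
        rq_ctl = sub.loc[sub["group"] == "control", "rq"]
        rows.append(
            {
                "target_id": target,
                "log2fc": log2fc,
                "rq_patient_mean": rq_pat.mean(),
                "rq_patient_sd": rq_pat.std(ddof=1),
                "rq_control_mean": rq_ctl.mean(),
                "rq_control_sd": rq_ctl.std(ddof=1),
                "dct_patient_sd": np.std(pat, ddof=1),
                "dct_control_sd": np.std(ctl, ddof=1),
                "t": t,
                "p": p,
                "significant": p < p_threshold,
                "stars": stars(p),
            }
        )
    return pd.DataFrame(rows)


def concordance(
    seq_log2fc: pd.Series, qpcr_log2fc: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Sign agreement and Pearson r between sequencing and qPCR log2FC.

    Both series are indexed by target id; only shared targets are compared
    (>= 3 required for the correlation; >= 1 for sign agreement). Returns a
    per-target table and the correlation of the two fold-change vectors.
    """
    shared = seq_log2fc.index.intersection(qpcr_log2fc.index)
    if len(shared) == 0:
        raise ValueError("no shared targets")
    a = seq_log2fc.loc[shared].astype(float)
    b = qpcr_log2fc.loc[shared].astype(float)
    table = pd.DataFrame(
        {
            "target_id": shared,
            "seq_log2fc": a.to_numpy(),
            "qpcr_log2fc": b.to_numpy(),
            "sign_agree": np.sign(a.to_numpy()) == np.sign(b.to_numpy()),
        }
    )
    r = pearson(a.to_numpy(), b.to_numpy()).r if len(shared) >= 3 else np.nan
    return table, float(r)
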