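"""Relative quantification of qPCR data by the comparative-Ct (ddCt) method.

Per sample: dCt = Ct(target) - Ct(reference gene, Gapdh); ddCt subtracts
the arithmetic mean dCt of the reference group (control), so the control
group sits at a geometric-mean fold change of 1; relative expression is
2^(-ddCt), assuming perfect doubling per cycle.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["delta_delta_ct", "summarize_groups"]


def delta_delta_ct(
    records: pd.DataFrame, reference_group: str = "control"
) -> pd.DataFrame:
    """Compute dCt, ddCt and relative expression per sample and target.

    ``records`` columns: sample_id, target_gene, ct_target, ct_reference,
    group.  Samples with a missing Ct are dropped with a warning.  The
    reference-group centering is done per target gene.
    """
    required = {"sample_id", "target_gene", "ct_target", "ct_reference", "group"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    df = records.copy()
    bad = df["ct_target"].isna() | df["ct_reference"].isna()
    if bad.any():
        for sid in df.loc[bad, "sample_id"]:
            logger.warning("sample %s missing a Ct value; dropped", sid)
        df = df[~bad]
    if not (df["group"] == reference_group).any():
        raise ValueError(f"reference group {reference_group!r} is empty")
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    ref_means = (
        df[df["group"] == reference_group]
        .groupby("target_gene")["delta_ct"]
        .mean()
    )
    df["delta_delta_ct"] = df["delta_ct"] - df["target_gene"].map(ref_means)
    if df["delta_delta_ct"].isna().any():
        tgt = df.loc[df["delta_delta_ct"].isna(), "target_gene"].iloc[0]
        raise ValueError(
            f"target {tgt!r} has no measurement in the reference group"
        )
    df["rel_expr"] = 2.0 ** (-df["delta_delta_ct"])
    return df


def summarize_groups(ddct: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- sem of relative expression per target gene."""
    def sem(x: pd.Series) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    return (
        ddct.groupby(["target_gene", "group"])["rel_expr"]
        .agg(mean="mean", sem=sem, n="count")
        .reset_index()
    )
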