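"""Fold-change classification across layers and driver attribution.

Two measured layers are compared between conditions with pure ratio
thresholds (no significance test — condition means over replicates only):

* mRNA layer: Gapdh-normalized expression (norm_expr); up when the
  KO/control ratio exceeds the up threshold (2.0 by default, 2.5 for the
  brown-fat style analysis), down when below 0.5.  Strict inequalities.
* pre-mRNA layer: iFPKM, same 2.0/0.5 thresholds.

The stability layer (half-life ratios) comes from :mod:`mrnafate.decay`.
The attribution step then asks, per gene with a changed mRNA level, which
layer explains the change: a concordant half-life change with quiet
transcription is a stability effect; a concordant pre-mRNA change with
unchanged half-life is transcriptional; both concordant is "both"; an
opposing call in either layer is "discordant"; anything else (including
genes with no usable call in either explanatory layer) is "unexplained".
A gene filtered out of a layer has no call there — never "unchanged".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FoldChangeRecord",
    "AttributionRecord",
    "fold_change",
    "attribute",
    "attribute_table",
    "summarize_layers",
    "UP_THRESHOLD",
    "DOWN_THRESHOLD",
]

UP_THRESHOLD = 2.0
DOWN_THRESHOLD = 0.5

NO_CALL = "no_call"

_LAYER_VALUE = {"mRNA": "norm_expr", "pre-mRNA": "ifpkm"}
_LAYER_FLAG = {"mRNA": "passes_expr_filter", "pre-mRNA": "passes_intronic_filter"}


@dataclass
class FoldChangeRecord:
    gene_id: str
    layer: str
    mean_control: float
    mean_ko: float
    ratio: float
    klass: str  # up | down | unchanged | undefined


@dataclass
class AttributionRecord:
    gene_id: str
    expr_klass: str
    stability_klass: str
    premrna_klass: str
    driver: str  # stability | transcription | both | discordant | unexplained


def classify_ratio(
    ratio: float,
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float = DOWN_THRESHOLD,
) -> str:
    if not np.isfinite(ratio):
        return "undefined"
    if ratio > up_threshold:
        return "up"
    if ratio < down_threshold:
        return "down"
    return "unchanged"


def fold_change(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    layer: str,
    control: str = "control",
    ko: str = "KO",
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float = DOWN_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene KO/control ratio of condition means on one layer.

    Only genes passing the layer's filter are classified.  Genes with a
    zero control mean get klass ``undefined`` (ratio has no value) and are
    reported separately rather than silently dropped.
    """
    if layer not in _LAYER_VALUE:
        raise ValueError(f"unknown layer: {layer!r} (use 'mRNA' or 'pre-mRNA')")
    value, flag = _LAYER_VALUE[layer], _LAYER_FLAG[layer]
    if flag not in expr.columns:
        raise ValueError(f"expression table lacks filter flag {flag}; run filters first")
    passing = expr[expr[flag]]
    merged = passing.merge(samples[["sample_id", "condition"]], on="sample_id")
    merged = merged[merged["condition"].isin([control, ko])]
    means = (
        merged.groupby(["gene_id", "condition"])[value].mean().unstack("condition")
    )
    if means.empty:
        return pd.DataFrame(
            columns=["gene_id", "layer", "mean_control", "mean_ko", "ratio", "klass"]
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = means[ko] / means[control]
    ratio[means[control] == 0] = np.nan
    out = pd.DataFrame(
        {
            "gene_id": means.index,
            "layer": layer,
            "mean_control": means[control].to_numpy(),
            "mean_ko": means[ko].to_numpy(),
            "ratio": ratio.to_numpy(),
        }
    )
    out["klass"] = [
        classify_ratio(r, up_threshold, down_threshold) for r in out["ratio"]
    ]
    return out.reset_index(drop=True)


_DIRECTION = {
    "up": "up",
    "down": "down",
    "stabilized": "up",
    "destabilized": "down",
    "unchanged": "unchanged",
    NO_CALL: NO_CALL,
    "undefined": NO_CALL,
}


def _driver(expr_dir: str, stab_dir: str, pre_dir: str) -> str:
    opposite = "down" if expr_dir == "up" else "up"
    if stab_dir == opposite or pre_dir == opposite:
        return "discordant"
    stab_concordant = stab_dir == expr_dir
    pre_concordant = pre_dir == expr_dir
    if stab_concordant and pre_concordant:
        return "both"
    if stab_concordant and pre_dir in ("unchanged", NO_CALL):
        return "stability"
    if pre_concordant and stab_dir in ("unchanged", NO_CALL):
        return "transcription"
    return "unexplained"


def attribute(
    expr_klass: str, stability_klass: str, premrna_klass: str
) -> str:
    """Driver of one gene's expression change per the concordance rule table.

    ``expr_klass`` must be ``up`` or ``down``; the other two may also be
    ``unchanged`` or ``no_call``.  Stabilized counts as the up direction,
    destabilized as down.
    """
    if expr_klass not in ("up", "down"):
        raise ValueError("attribution is defined only for changed expression")
    return _driver(
        expr_klass, _DIRECTION[stability_klass], _DIRECTION[premrna_klass]
    )


def attribute_table(
    fc_mrna: pd.DataFrame,
    fc_premrna: pd.DataFrame,
    stability_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Attribution records for every gene whose mRNA class is up or down."""
    pre_map = (
        dict(zip(fc_premrna["gene_id"], fc_premrna["klass"]))
        if len(fc_premrna)
        else {}
    )
    stab_map = (
        dict(zip(stability_calls["gene_id"], stability_calls["klass"]))
        if len(stability_calls)
        else {}
    )
    rows = []
    for gid, klass in zip(fc_mrna["gene_id"], fc_mrna["klass"]):
        if klass not in ("up", "down"):
            continue
        stab = stab_map.get(gid, NO_CALL)
        pre = pre_map.get(gid, NO_CALL)
        rows.append(
            {
                "gene_id": gid,
                "expr_klass": klass,
                "stability_klass": stab,
                "premrna_klass": pre,
                "driver": attribute(klass, stab, pre),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "expr_klass", "stability_klass", "premrna_klass", "driver"],
    )


def summarize_layers(
    fc_mrna: pd.DataFrame,
    fc_premrna: pd.DataFrame,
    stability_calls: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class counts per layer plus the scatter-plot-ready long table.

    Returns ``(summary, long_table)``.  ``summary`` rows: (layer, klass,
    n_genes); counts within a layer sum to the number of genes with calls
    in that layer.  ``long_table`` stacks per-gene (layer, control value,
    KO value, klass) rows for plotting.
    """
    pieces = []
    for layer, df, klass_col in (
        ("mRNA", fc_mrna, "klass"),
        ("pre-mRNA", fc_premrna, "klass"),
        ("stability", stability_calls, "klass"),
    ):
        if len(df):
            counts = df[klass_col].value_counts()
            for klass, n in counts.items():
                pieces.append({"layer": layer, "klass": klass, "n_genes": int(n)})
    summary = pd.DataFrame(pieces, columns=["layer", "klass", "n_genes"])

    long_rows = []
    for layer, df in (("mRNA", fc_mrna), ("pre-mRNA", fc_premrna)):
        for rec in df.itertuples(index=False):
            long_rows.append(
                {
                    "gene_id": rec.gene_id,
                    "layer": layer,
                    "value_control": rec.mean_control,
                    "value_ko": rec.mean_ko,
                    "klass": rec.klass,
                }
            )
    for rec in stability_calls.itertuples(index=False):
        long_rows.append(
            {
                "gene_id": rec.gene_id,
                "layer": "stability",
                "value_control": rec.hl_control,
                "value_ko": rec.hl_ko,
                "klass": rec.klass,
            }
        )
    long_table = pd.DataFrame(
        long_rows,
        columns=["gene_id", "layer", "value_control", "value_ko", "klass"],
    )
    return summary, long_table
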