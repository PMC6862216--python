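"""Exonic/intronic read counting and FPKM-family normalizations.

The pipeline measures three layers per gene: mature-mRNA abundance (exonic
FPKM, normalized to the Gapdh internal control), and nascent transcription
(intronic FPKM, iFPKM — reads falling in introns normalized by total
intronic reads and summed intron length, a standard pre-mRNA proxy for
transcription rate).

Assignment rule for a read interval:

* entirely inside a gene's exon union            -> exonic for that gene
* overlapping any intronic base of exactly 1 gene -> intronic for that gene
* overlapping no gene, or more than one gene      -> unassigned

FPKM = count x 1e9 / (exon_union_length x total_exonic_reads_in_sample);
iFPKM applies the identical density formula on the intronic compartment.
The 1e9 scale constant for iFPKM mirrors FPKM; any constant cancels in the
KO/control ratios used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMeta",
    "QuantifyError",
    "read_sample_sheet",
    "read_bed_reads",
    "assign_reads",
    "fpkm",
    "ifpkm",
    "fpkm_table",
    "normalize_to_reference",
    "filter_expression",
    "filter_intronic",
    "quantify_counts",
]

DEFAULT_REFERENCE_GENE = "Gapdh"
EXPR_MIN_FPKM = 0.1
IFPKM_MIN = 0.001
INTRON_MIN_BP = 150


class QuantifyError(ValueError):
    """Raised for degenerate quantification inputs."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str
    tissue: str = "iWAT"
    replicate: int = 1
    time_point_h: float | None = None


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet TSV (sample_id, condition, tissue, replicate, time_point_h)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise QuantifyError(f"sample sheet missing columns: {sorted(missing)}")
    if "time_point_h" not in df.columns:
        df["time_point_h"] = np.nan
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if "tissue" not in df.columns:
        df["tissue"] = "iWAT"
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise QuantifyError(f"duplicate sample_id in sample sheet: {dup}")
    return df


def read_bed_reads(path: str | Path) -> pd.DataFrame:
    """Read BED-like read positions: chrom, start, end, sample_id."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "sample_id"],
        dtype={"chrom": str, "sample_id": str},
    )
    bad = df["end"] <= df["start"]
    if bad.any():
        row = df[bad].iloc[0]
        raise QuantifyError(
            f"read with end <= start: {row.chrom}:{row.start}-{row.end}"
        )
    return df


def _gene_trees(models: dict[str, GeneModel]):
    """Per-chromosome interval trees over gene spans, plus exon/intron trees per gene."""
    span_trees: dict[str, IntervalTree] = {}
    exon_trees: dict[str, IntervalTree] = {}
    intron_trees: dict[str, IntervalTree] = {}
    for gid, gm in models.items():
        span = gm.span
        span_trees.setdefault(gm.chrom, IntervalTree()).addi(span.start, span.end, gid)
        et = IntervalTree()
        for iv in gm.exons:
            et.addi(iv.start, iv.end)
        exon_trees[gid] = et
        it = IntervalTree()
        for iv in gm.introns:
            it.addi(iv.start, iv.end)
        intron_trees[gid] = it
    return span_trees, exon_trees, intron_trees


def _covered_length(tree: IntervalTree, start: int, end: int) -> int:
    return sum(min(iv.end, end) - max(iv.begin, start) for iv in tree.overlap(start, end))


def assign_reads(
    reads: pd.DataFrame, models: dict[str, GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign read intervals to gene compartments.

    Returns ``(counts, unassigned)``: a long count table
    (gene_id, sample_id, exonic_count, intronic_count) covering every
    (gene, sample) pair, and a per-sample tally of unassigned reads with
    reasons (no_gene, multi_gene, partial_overlap).
    """
    if (reads["end"] <= reads["start"]).any():
        raise QuantifyError("read with end <= start")
    span_trees, exon_trees, intron_trees = _gene_trees(models)
    known_chroms = set(span_trees)

    counts: dict[tuple[str, str], list[int]] = {}
    unassigned: dict[tuple[str, str], int] = {}

    def tally(sample: str, reason: str) -> None:
        unassigned[(sample, reason)] = unassigned.get((sample, reason), 0) + 1

    for chrom, start, end, sample in reads[
        ["chrom", "start", "end", "sample_id"]
    ].itertuples(index=False):
        if chrom not in known_chroms:
            logger.warning("read on unknown chromosome %s; unassigned", chrom)
            tally(sample, "no_gene")
            continue
        hits = {iv.data for iv in span_trees[chrom].overlap(start, end)}
        # Reads poking just outside a span may still touch a gene's intron?
        # No: introns lie strictly inside the span, so span overlap is complete.
        if not hits:
            tally(sample, "no_gene")
            continue
        if len(hits) > 1:
            tally(sample, "multi_gene")
            continue
        gid = hits.pop()
        length = end - start
        if _covered_length(exon_trees[gid], start, end) == length:
            key = (gid, sample)
            counts.setdefault(key, [0, 0])[0] += 1
        elif _covered_length(intron_trees[gid], start, end) > 0:
            key = (gid, sample)
            counts.setdefault(key, [0, 0])[1] += 1
        else:
            # partially exonic but extending outside the gene span
            tally(sample, "partial_overlap")

    sample_ids = sorted(reads["sample_id"].unique())
    rows = [
        {
            "gene_id": gid,
            "sample_id": sid,
            "exonic_count": counts.get((gid, sid), (0, 0))[0],
            "intronic_count": counts.get((gid, sid), (0, 0))[1],
        }
        for gid in sorted(models)
        for sid in sample_ids
    ]
    un_rows = [
        {"sample_id": sid, "reason": reason, "n_reads": n}
        for (sid, reason), n in sorted(unassigned.items())
    ]
    return pd.DataFrame(rows), pd.DataFrame(
        un_rows, columns=["sample_id", "reason", "n_reads"]
    )


def fpkm(count: float, length_bp: float, total_reads: float) -> float:
    """Reads per kilobase of feature per million assigned reads."""
    if length_bp <= 0:
        raise QuantifyError("feature length must be positive")
    if total_reads <= 0:
        raise QuantifyError("total reads must be positive (degenerate sample)")
    return count * 1e9 / (length_bp * total_reads)


def ifpkm(count: float, intron_length_sum: float, total_intronic_reads: float) -> float:
    """The FPKM density formula restricted to the intronic compartment."""
    return fpkm(count, intron_length_sum, total_intronic_reads)


def fpkm_table(
    counts: pd.DataFrame,
    models: dict[str, GeneModel],
    mapped_totals: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Compute fpkm and ifpkm per (gene, sample) from a count table.

    ``mapped_totals`` optionally supplies per-sample library totals for the
    FPKM denominator; by default the denominator is the total of reads
    assigned to exonic compartments in that sample (and analogously the
    total intronic assignment for iFPKM).
    """
    df = counts.copy()
    df["exon_union_length"] = df["gene_id"].map(
        {g: m.exon_union_length for g, m in models.items()}
    )
    df["intron_length_sum"] = df["gene_id"].map(
        {g: m.intron_length_sum for g, m in models.items()}
    )
    if df["exon_union_length"].isna().any():
        unknown = df.loc[df["exon_union_length"].isna(), "gene_id"].iloc[0]
        raise QuantifyError(f"count table references unknown gene: {unknown}")

    exonic_totals = df.groupby("sample_id")["exonic_count"].transform("sum")
    intronic_totals = df.groupby("sample_id")["intronic_count"].transform("sum")
    if mapped_totals is not None:
        denom = df["sample_id"].map(mapped_totals)
        if denom.isna().any():
            missing = df.loc[denom.isna(), "sample_id"].iloc[0]
            raise QuantifyError(f"no mapped total supplied for sample {missing}")
    else:
        denom = exonic_totals
    if (denom <= 0).any():
        bad = df.loc[denom <= 0, "sample_id"].iloc[0]
        raise QuantifyError(f"zero total exonic reads in sample {bad}")

    df["fpkm"] = df["exonic_count"] * 1e9 / (df["exon_union_length"] * denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ifpkm"] = np.where(
            (df["intron_length_sum"] > 0) & (intronic_totals > 0),
            df["intronic_count"]
            * 1e9
            / (df["intron_length_sum"] * intronic_totals.replace(0, np.nan)),
            np.nan,
        )
    return df


def normalize_to_reference(
    expr: pd.DataFrame, reference_gene_id: str = DEFAULT_REFERENCE_GENE
) -> pd.DataFrame:
    """Divide each gene's FPKM by the internal-control gene's FPKM per sample."""
    ref = expr.loc[expr["gene_id"] == reference_gene_id, ["sample_id", "fpkm"]]
    all_samples = set(expr["sample_id"].unique())
    missing = all_samples - set(ref["sample_id"])
    if missing:
        raise QuantifyError(
            f"reference gene {reference_gene_id} absent in sample "
            f"{sorted(missing)[0]}"
        )
    zero = ref.loc[ref["fpkm"] <= 0, "sample_id"]
    if len(zero):
        raise QuantifyError(
            f"reference gene {reference_gene_id} has zero FPKM in sample {zero.iloc[0]}"
        )
    ref_map = dict(zip(ref["sample_id"], ref["fpkm"]))
    out = expr.copy()
    out["norm_expr"] = out["fpkm"] / out["sample_id"].map(ref_map)
    return out


def _condition_means(
    expr: pd.DataFrame, samples: pd.DataFrame, value: str
) -> pd.DataFrame:
    merged = expr.merge(samples[["sample_id", "condition"]], on="sample_id")
    return (
        merged.groupby(["gene_id", "condition"])[value]
        .mean()
        .unstack("condition")
    )


def filter_expression(
    expr: pd.DataFrame,
    models: dict[str, GeneModel],
    samples: pd.DataFrame,
    min_fpkm: float = EXPR_MIN_FPKM,
    scope: str = "all",
) -> pd.DataFrame:
    """Set ``passes_expr_filter``: protein-coding and condition-mean FPKM >= min.

    The threshold is evaluated on the per-condition replicate-mean FPKM; a
    gene passes when that mean clears the threshold in every condition
    (``scope='all'``, default) or in at least one (``scope='any'``).
    Strict boundary: exactly 0.1 passes, anything below is excluded.
    """
    if scope not in {"all", "any"}:
        raise QuantifyError(f"unknown filter scope: {scope}")
    means = _condition_means(expr, samples, "fpkm")
    ok = (means >= min_fpkm).all(axis=1) if scope == "all" else (means >= min_fpkm).any(axis=1)
    coding = {g for g, m in models.items() if m.biotype == "protein_coding"}
    out = expr.copy()
    out["passes_fpkm_floor"] = out["gene_id"].map(ok).fillna(False)
    out["passes_expr_filter"] = out["passes_fpkm_floor"] & out["gene_id"].isin(coding)
    return out


def filter_intronic(
    expr: pd.DataFrame,
    models: dict[str, GeneModel],
    samples: pd.DataFrame,
    min_fpkm: float = EXPR_MIN_FPKM,
    min_ifpkm: float = IFPKM_MIN,
    min_intron_bp: float = INTRON_MIN_BP,
    scope: str = "all",
) -> pd.DataFrame:
    """Set ``passes_intronic_filter`` for the pre-mRNA layer.

    A gene is retained when condition-mean FPKM >= 0.1, condition-mean
    iFPKM >= 0.001, and summed intron length >= 150 bp; genes failing any
    are eliminated.  Genes without introns have undefined iFPKM and never
    pass.
    """
    fmeans = _condition_means(expr, samples, "fpkm")
    imeans = _condition_means(expr, samples, "ifpkm")
    agg = "all" if scope == "all" else "any"
    f_ok = getattr((fmeans >= min_fpkm), agg)(axis=1)
    i_ok = getattr((imeans >= min_ifpkm), agg)(axis=1) & imeans.notna().all(axis=1)
    intron_ok = {
        g: m.intron_length_sum >= min_intron_bp for g, m in models.items()
    }
    out = expr.copy()
    out["passes_intronic_filter"] = (
        out["gene_id"].map(f_ok).fillna(False)
        & out["gene_id"].map(i_ok).fillna(False)
        & out["gene_id"].map(intron_ok).fillna(False)
    )
    return out


def quantify_counts(
    counts: pd.DataFrame,
    models: dict[str, GeneModel],
    samples: pd.DataFrame,
    reference_gene_id: str = DEFAULT_REFERENCE_GENE,
    mapped_totals: dict[str, float] | None = None,
    min_fpkm: float = EXPR_MIN_FPKM,
    min_ifpkm: float = IFPKM_MIN,
    min_intron_bp: float = INTRON_MIN_BP,
    filter_scope: str = "all",
) -> pd.DataFrame:
    """Full quantification: FPKM + iFPKM + reference normalization + filters.

    Returns the long expression table with one row per (gene, sample).
    """
    expr = fpkm_table(counts, models, mapped_totals=mapped_totals)
    expr = normalize_to_reference(expr, reference_gene_id)
    expr = filter_expression(
        expr, models, samples, min_fpkm=min_fpkm, scope=filter_scope
    )
    expr = filter_intronic(
        expr,
        models,
        samples,
        min_fpkm=min_fpkm,
        min_ifpkm=min_ifpkm,
        min_intron_bp=min_intron_bp,
        scope=filter_scope,
    )
    return expr
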