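"""End-to-end orchestration: quantify -> decay -> classify -> enrich -> report.

A :class:`RunConfig` carries every input path and every threshold of the
analysis (all defaults are the study's stated values: FPKM >= 0.1, iFPKM
>= 0.001, intron >= 150 bp, half-life window [0, 50] h, fold-change
thresholds 2.0 (up) / 0.5 (down), FDR < 0.05, shortlist of 6).
``run_all`` executes the stages, writes every intermediate TSV, a
markdown report with stage summaries and the filter-attrition funnel, and
a machine-readable MANIFEST.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation, decay, diffexpr, enrich, quantify

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_all", "attrition_table"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class Thresholds:
    expr_min_fpkm: float = 0.1
    ifpkm_min: float = 0.001
    intron_min_bp: float = 150.0
    hl_min: float = 0.0
    hl_max: float = 50.0
    up: float = 2.0
    down: float = 0.5
    stabilized_ratio: float = 2.0
    destabilized_ratio: float = 0.5
    fdr: float = 0.05
    max_terms: int = 6


@dataclass
class RunConfig:
    annotation: str = ""
    steady_counts: str = ""
    steady_samples: str = ""
    chase_counts: str = ""
    chase_samples: str = ""
    gene_sets: str = ""  # optional GMT
    reads: str = ""  # optional BED alternative to steady_counts
    out_dir: str = "results"
    reference_gene: str = quantify.DEFAULT_REFERENCE_GENE
    control: str = "control"
    ko: str = "KO"
    stranded: bool = False
    per_replicate_fit: bool = False
    denominator: str = "assigned"  # assigned | mapped
    expr_filter_scope: str = "all"
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# provenance of each default threshold, echoed verbatim in the report
THRESHOLD_NOTES = {
    "expr_min_fpkm": "genes with <0.1 FPKM excluded (protein-coding only)",
    "ifpkm_min": "genes with iFPKM <0.001 eliminated from the pre-mRNA layer",
    "intron_min_bp": "genes with summed intron length <150 bp eliminated",
    "hl_min": "half-lives less than 0 h excluded",
    "hl_max": "half-lives longer than 50 h excluded",
    "up": "upregulated when KO/control ratio >2.0 (2.5 for the BAT-style analysis)",
    "down": "downregulated when KO/control ratio <0.5",
    "stabilized_ratio": "stabilized when KO/control half-life ratio >2.0",
    "destabilized_ratio": "destabilized when KO/control half-life ratio <0.5",
    "fdr": "enrichment shortlist at FDR <0.05",
    "max_terms": "at most six terms reported per query",
}


def attrition_table(
    models: dict,
    expr_steady: pd.DataFrame,
    fits: pd.DataFrame | None = None,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Per-filter gene attrition funnel.

    The expression funnel runs biotype -> FPKM; the pre-mRNA funnel
    continues iFPKM -> intron length (genes with no intronic compartment
    fall at the intron-length step); the stability funnel (when fits are
    given) counts genes losing a call to fit failure, the half-life
    window, or the decay-layer FPKM floor.  Counts are additive within
    each funnel.
    """
    thr = thresholds or Thresholds()
    per_gene = expr_steady.drop_duplicates("gene_id").set_index("gene_id")
    gene_ids = list(per_gene.index)
    n_input = len(gene_ids)
    coding = [g for g in gene_ids if models[g].biotype == "protein_coding"]
    removed_biotype = n_input - len(coding)
    expr_pass = set(per_gene.index[per_gene["passes_expr_filter"]])
    removed_fpkm = len([g for g in coding if g not in expr_pass])
    rows = [
        ("input_genes", n_input),
        ("removed_biotype", removed_biotype),
        ("removed_low_fpkm", removed_fpkm),
        ("mrna_retained", len(expr_pass)),
    ]

    # pre-mRNA funnel: FPKM floor -> iFPKM -> intron length; genes without
    # an intronic compartment (undefined iFPKM) fall at the length step
    intron_pass = set(per_gene.index[per_gene["passes_intronic_filter"]])
    fpkm_floor = set(per_gene.index[per_gene["passes_fpkm_floor"]])
    candidates = [g for g in gene_ids if g in fpkm_floor]
    removed_intronic_fpkm = n_input - len(candidates)
    defined = [g for g in candidates if models[g].intron_length_sum > 0]
    low_ifpkm = [
        g
        for g in defined
        if models[g].intron_length_sum >= thr.intron_min_bp and g not in intron_pass
    ]
    short = [
        g for g in candidates if models[g].intron_length_sum < thr.intron_min_bp
    ]
    rows += [
        ("removed_intronic_low_fpkm", removed_intronic_fpkm),
        ("removed_low_ifpkm", len(low_ifpkm)),
        ("removed_short_intron", len(short)),
        ("intronic_retained", len(intron_pass)),
    ]

    if fits is not None and len(fits):
        by_gene = fits.groupby("gene_id")
        n_with_fits = len(by_gene)
        no_fit = window = low_fpkm = retained = 0
        for _, grp in by_gene:
            reasons = set(grp.loc[grp["excluded"], "reason"])
            if not reasons:
                retained += 1
            elif any("half-life" in r for r in reasons):
                window += 1
            elif any("FPKM" in r for r in reasons):
                low_fpkm += 1
            else:
                no_fit += 1
        rows += [
            ("genes_with_chase_fits", n_with_fits),
            ("removed_no_fit", no_fit),
            ("removed_half_life_window", window),
            ("removed_decay_low_fpkm", low_fpkm),
            ("stability_retained", retained),
        ]
    return pd.DataFrame(rows, columns=["stage", "n_genes"])


def _timed(stage: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    logger.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    return result


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the MANIFEST dict.

    Partial outputs are kept on failure, with the MANIFEST noting which
    stage failed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {"complete": False, "failed_stage": None, "outputs": {}}

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = str(path)

    try:
        models = _timed("annotation", annotation.parse_annotation, config.annotation)
        annotation.write_gene_geometry(models, out / "gene_geometry.tsv")
        manifest["outputs"]["gene_geometry"] = str(out / "gene_geometry.tsv")

        steady_samples = _timed(
            "quantify", quantify.read_sample_sheet, config.steady_samples
        )
        if config.reads:
            reads = quantify.read_bed_reads(config.reads)
            steady_counts, unassigned = _timed(
                "quantify", quantify.assign_reads, reads, models
            )
            save("unassigned_reads", unassigned)
        else:
            steady_counts = pd.read_csv(config.steady_counts, sep="\t")
        expr = _timed(
            "quantify",
            quantify.quantify_counts,
            steady_counts,
            models,
            steady_samples,
            reference_gene_id=config.reference_gene,
            min_fpkm=thr.expr_min_fpkm,
            min_ifpkm=thr.ifpkm_min,
            min_intron_bp=thr.intron_min_bp,
            filter_scope=config.expr_filter_scope,
        )
        save("expression", expr)

        fits = None
        stability = pd.DataFrame(columns=["gene_id", "hl_control", "hl_ko", "ratio", "klass"])
        if config.chase_counts:
            chase_samples = quantify.read_sample_sheet(config.chase_samples)
            chase_counts = pd.read_csv(config.chase_counts, sep="\t")
            chase_expr = _timed(
                "decay",
                lambda: quantify.normalize_to_reference(
                    quantify.fpkm_table(chase_counts, models),
                    config.reference_gene,
                ),
            )
            fits = _timed(
                "decay",
                decay.fit_decay_table,
                chase_expr,
                chase_samples,
                per_replicate=config.per_replicate_fit,
            )
            # decay-layer FPKM floor: t=0 condition-mean FPKM, per condition
            t0_samples = chase_samples[chase_samples["time_point_h"] == 0]
            t0 = chase_expr.merge(
                t0_samples[["sample_id", "condition"]], on="sample_id"
            )
            t0_means = t0.groupby(["gene_id", "condition"])["fpkm"].mean()
            parts = []
            for cond, grp in fits.groupby("condition"):
                fmap = t0_means.xs(cond, level="condition")
                parts.append(
                    decay.filter_half_lives(
                        grp,
                        fpkm_t0=fmap,
                        min_fpkm=thr.expr_min_fpkm,
                        hl_min=thr.hl_min,
                        hl_max=thr.hl_max,
                    )
                )
            fits = pd.concat(parts, ignore_index=True)
            save("half_lives", fits)
            stability = decay.stability_table(
                fits,
                control=config.control,
                ko=config.ko,
                stabilized_ratio=thr.stabilized_ratio,
                destabilized_ratio=thr.destabilized_ratio,
            )
            save("stability_calls", stability)

        fc_mrna = _timed(
            "classify",
            diffexpr.fold_change,
            expr,
            steady_samples,
            "mRNA",
            control=config.control,
            ko=config.ko,
            up_threshold=thr.up,
            down_threshold=thr.down,
        )
        fc_pre = diffexpr.fold_change(
            expr,
            steady_samples,
            "pre-mRNA",
            control=config.control,
            ko=config.ko,
            up_threshold=thr.up,
            down_threshold=thr.down,
        )
        save("fold_change_mrna", fc_mrna)
        save("fold_change_premrna", fc_pre)
        attribution = diffexpr.attribute_table(fc_mrna, fc_pre, stability)
        save("attribution", attribution)
        summary, long_table = diffexpr.summarize_layers(fc_mrna, fc_pre, stability)
        save("summary", summary)
        save("scatter_long", long_table)

        enrich_results = {}
        if config.gene_sets:
            sets = enrich.read_gmt(config.gene_sets)
            universe_mrna = set(fc_mrna["gene_id"])
            universe_pre = set(fc_pre["gene_id"])
            queries = {
                "mrna_up": (set(fc_mrna.loc[fc_mrna["klass"] == "up", "gene_id"]), universe_mrna),
                "mrna_down": (set(fc_mrna.loc[fc_mrna["klass"] == "down", "gene_id"]), universe_mrna),
                "premrna_up": (set(fc_pre.loc[fc_pre["klass"] == "up", "gene_id"]), universe_pre),
                "premrna_down": (set(fc_pre.loc[fc_pre["klass"] == "down", "gene_id"]), universe_pre),
            }
            if len(stability):
                universe_stab = set(stability["gene_id"])
                queries["stabilized"] = (
                    set(stability.loc[stability["klass"] == "stabilized", "gene_id"]),
                    universe_stab,
                )
                queries["destabilized"] = (
                    set(stability.loc[stability["klass"] == "destabilized", "gene_id"]),
                    universe_stab,
                )
            for name, (query, universe) in queries.items():
                res = _timed(
                    "enrich", enrich.hypergeom_enrich, query, sets, universe
                )
                enrich_results[name] = res
                save(f"enrichment_{name}", res)
                save(
                    f"enrichment_{name}_top",
                    enrich.top_terms(res, thr.fdr, thr.max_terms),
                )

        attrition = attrition_table(models, expr, fits=fits, thresholds=thr)
        save("attrition", attrition)
        _write_report(out, config, attrition, summary, enrich_results)
        manifest["outputs"]["report"] = str(out / "report.md")
        manifest["complete"] = True
    except PipelineError as exc:
        manifest["failed_stage"] = str(exc)
        with (out / "MANIFEST.json").open("w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with (out / "MANIFEST.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _write_report(
    out: Path,
    config: RunConfig,
    attrition: pd.DataFrame,
    summary: pd.DataFrame,
    enrich_results: dict,
) -> None:
    thr = asdict(config.thresholds)
    lines = ["# Transcript-fate analysis report", ""]
    lines += ["## Configuration (threshold ledger)", ""]
    lines += ["| threshold | value | meaning |", "|---|---|---|"]
    for key, value in thr.items():
        lines.append(f"| {key} | {value} | {THRESHOLD_NOTES.get(key, '')} |")
    lines += ["", "## Filter attrition", ""]
    lines += ["| stage | n_genes |", "|---|---|"]
    for rec in attrition.itertuples(index=False):
        lines.append(f"| {rec.stage} | {rec.n_genes} |")
    lines += ["", "## Class summary", ""]
    if len(summary):
        lines += ["| layer | class | n_genes |", "|---|---|---|"]
        for rec in summary.itertuples(index=False):
            lines.append(f"| {rec.layer} | {rec.klass} | {rec.n_genes} |")
    else:
        lines.append("(no classifications)")
    if enrich_results:
        lines += ["", "## Enrichment (top term per query)", ""]
        for name, res in enrich_results.items():
            if len(res):
                top = res.iloc[0]
                lines.append(
                    f"- {name}: {top.term_id} (k={top.k}/{top.K}, FDR={top.fdr:.3g})"
                )
            else:
                lines.append(f"- {name}: no terms tested")
    lines.append("")
    (out / "report.md").write_text("\n".join(lines))
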