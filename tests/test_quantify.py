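"""Read assignment, FPKM/iFPKM arithmetic, reference normalization, filters."""

import numpy as np
import pandas as pd
import pytest

from mrnafate.annotation import GenomicInterval, build_gene_model
from mrnafate.quantify import (
    QuantifyError,
    assign_reads,
    filter_expression,
    filter_intronic,
    fpkm,
    fpkm_table,
    ifpkm,
    normalize_to_reference,
    quantify_counts,
)
from mrnafate.synthetic import simulate_reads_bed


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def two_gene_models():
    # gene A: exons [0,100) and [200,300), intron [100,200)
    # gene B: exons [1000,1100) and [1300,1400), intron [1100,1300)
    a = build_gene_model("A", [iv(0, 100), iv(200, 300)])
    b = build_gene_model("B", [iv(1000, 1100), iv(1300, 1400)])
    return {"A": a, "B": b}


def reads_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_id"])


class TestAssignReads:
    def test_read_inside_exon_is_exonic(self):
        counts, _ = assign_reads(
            reads_df([("chr1", 10, 60, "s1")]), two_gene_models()
        )
        row = counts.set_index(["gene_id", "sample_id"]).loc[("A", "s1")]
        assert (row.exonic_count, row.intronic_count) == (1, 0)

    def test_read_spanning_exon_intron_boundary_is_intronic(self):
        counts, _ = assign_reads(
            reads_df([("chr1", 90, 130, "s1")]), two_gene_models()
        )
        row = counts.set_index(["gene_id", "sample_id"]).loc[("A", "s1")]
        assert (row.exonic_count, row.intronic_count) == (0, 1)

    def test_read_touching_two_genes_unassigned(self):
        models = {
            "A": build_gene_model("A", [iv(0, 100), iv(300, 400)]),
            "B": build_gene_model("B", [iv(150, 250), iv(350, 450)]),
        }
        counts, unassigned = assign_reads(reads_df([("chr1", 120, 260, "s1")]), models)
        assert counts[["exonic_count", "intronic_count"]].to_numpy().sum() == 0
        assert unassigned.loc[0, "reason"] == "multi_gene"

    def test_read_outside_all_genes_unassigned(self):
        counts, unassigned = assign_reads(
            reads_df([("chr1", 500, 600, "s1"), ("chrX", 0, 50, "s1")]),
            two_gene_models(),
        )
        assert counts[["exonic_count", "intronic_count"]].to_numpy().sum() == 0
        assert unassigned["n_reads"].sum() == 2

    def test_invalid_read_interval_rejected(self):
        with pytest.raises(QuantifyError, match="end <= start"):
            assign_reads(reads_df([("chr1", 60, 60, "s1")]), two_gene_models())

    def test_round_trip_with_simulated_reads(self, small_sim):
        """Placing counted reads in compartments and re-assigning them
        reproduces the count table exactly on non-overlapping models."""
        bed = simulate_reads_bed(
            small_sim.steady_counts, small_sim.models, small_sim.config
        )
        counts, unassigned = assign_reads(bed, small_sim.models)
        merged = small_sim.steady_counts.merge(
            counts, on=["gene_id", "sample_id"], suffixes=("_true", "_got")
        )
        assert (merged.exonic_count_true == merged.exonic_count_got).all()
        assert (merged.intronic_count_true == merged.intronic_count_got).all()
        assert unassigned.empty


class TestDensityFormulas:
    @pytest.mark.parametrize(
        "count, length, total, expected",
        [(100, 1000, 1e6, 100.0), (0, 1000, 1e6, 0.0), (250, 2500, 5e6, 20.0)],
    )
    def test_fpkm_values(self, count, length, total, expected):
        assert fpkm(count, length, total) == pytest.approx(expected)

    def test_ifpkm_is_the_same_density_on_introns(self):
        assert ifpkm(50, 5000, 1e5) == pytest.approx(100.0)
        assert ifpkm(0, 5000, 1e5) == 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(QuantifyError):
            fpkm(1, 0, 1e6)
        with pytest.raises(QuantifyError):
            fpkm(1, 1000, 0)

    def test_count_conservation(self, small_sim):
        """sum(fpkm x length) / 1e9 x total recovers the exonic counts."""
        expr = fpkm_table(small_sim.steady_counts, small_sim.models)
        for sid, grp in expr.groupby("sample_id"):
            total = grp["exonic_count"].sum()
            back = (grp["fpkm"] * grp["exon_union_length"]).sum() / 1e9 * total
            assert back == pytest.approx(total)

    def test_ifpkm_invariant_under_global_intronic_rescale(self, small_sim):
        base = fpkm_table(small_sim.steady_counts, small_sim.models)
        doubled_counts = small_sim.steady_counts.copy()
        doubled_counts["intronic_count"] *= 2
        doubled = fpkm_table(doubled_counts, small_sim.models)
        pd.testing.assert_series_equal(base["ifpkm"], doubled["ifpkm"])


class TestReferenceNormalization:
    def make_expr(self):
        return pd.DataFrame(
            {
                "gene_id": ["g", "Gapdh", "g", "Gapdh"],
                "sample_id": ["s1", "s1", "s2", "s2"],
                "fpkm": [50.0, 100.0, 30.0, 60.0],
            }
        )

    def test_ratio_to_reference(self):
        out = normalize_to_reference(self.make_expr())
        assert list(out["norm_expr"]) == pytest.approx([0.5, 1.0, 0.5, 1.0])

    def test_reference_is_always_one(self, small_sim):
        expr = normalize_to_reference(
            fpkm_table(small_sim.steady_counts, small_sim.models)
        )
        gapdh = expr[expr["gene_id"] == "Gapdh"]
        assert np.allclose(gapdh["norm_expr"], 1.0)

    def test_scale_invariance(self):
        expr = self.make_expr()
        scaled = expr.copy()
        scaled.loc[scaled["sample_id"] == "s1", "fpkm"] *= 7.3
        pd.testing.assert_series_equal(
            normalize_to_reference(expr)["norm_expr"],
            normalize_to_reference(scaled)["norm_expr"],
        )

    def test_missing_reference_names_sample(self):
        expr = self.make_expr()
        expr = expr[~((expr.gene_id == "Gapdh") & (expr.sample_id == "s2"))]
        with pytest.raises(QuantifyError, match="s2"):
            normalize_to_reference(expr)


def _flag_expr(fpkm_by_gene, ifpkm_by_gene=None):
    genes = list(fpkm_by_gene)
    rows = []
    for sid in ("c1", "k1"):
        for g in genes:
            rows.append(
                {
                    "gene_id": g,
                    "sample_id": sid,
                    "fpkm": fpkm_by_gene[g],
                    "ifpkm": (ifpkm_by_gene or {}).get(g, np.nan),
                }
            )
    expr = pd.DataFrame(rows)
    samples = pd.DataFrame(
        {"sample_id": ["c1", "k1"], "condition": ["control", "KO"]}
    )
    return expr, samples


class TestFilters:
    def test_expression_filter_boundaries_and_biotype(self):
        models = {
            "low": build_gene_model("low", [iv(0, 100)]),
            "edge": build_gene_model("edge", [iv(0, 100)]),
            "nc": build_gene_model("nc", [iv(0, 100)], biotype="lincRNA"),
        }
        expr, samples = _flag_expr({"low": 0.09, "edge": 0.1, "nc": 5.0})
        out = filter_expression(expr, models, samples).drop_duplicates("gene_id")
        flags = dict(zip(out["gene_id"], out["passes_expr_filter"]))
        assert flags == {"low": False, "edge": True, "nc": False}

    def test_intronic_filter_conjunction_of_boundaries(self):
        def gm(name, intron_len):
            if intron_len == 0:
                return build_gene_model(name, [iv(0, 100)])
            return build_gene_model(name, [iv(0, 100), iv(100 + intron_len, 200 + intron_len)])

        models = {
            "ok": gm("ok", 2000),
            "low_ifpkm": gm("low_ifpkm", 2000),
            "short": gm("short", 149),
            "edge": gm("edge", 150),
            "at_thresholds": gm("at_thresholds", 150),
            "no_intron": gm("no_intron", 0),
        }
        expr, samples = _flag_expr(
            {g: 1.0 for g in models} | {"at_thresholds": 0.1},
            {
                "ok": 0.01,
                "low_ifpkm": 0.0005,
                "short": 0.01,
                "edge": 0.001,
                "at_thresholds": 0.001,
            },
        )
        out = filter_intronic(expr, models, samples).drop_duplicates("gene_id")
        flags = dict(zip(out["gene_id"], out["passes_intronic_filter"]))
        assert flags == {
            "ok": True,
            "low_ifpkm": False,
            "short": False,
            "edge": True,
            "at_thresholds": True,  # all three exactly at threshold: retained
            "no_intron": False,
        }

    def test_norm_expr_invariant_under_global_sample_rescale(self, small_sim):
        """Doubling every count in one sample changes no normalized value."""
        counts = small_sim.steady_counts.copy()
        sid = counts["sample_id"].iloc[0]
        mask = counts["sample_id"] == sid
        counts.loc[mask, ["exonic_count", "intronic_count"]] *= 2
        base = quantify_counts(
            small_sim.steady_counts, small_sim.models, small_sim.steady_samples
        )
        scaled = quantify_counts(counts, small_sim.models, small_sim.steady_samples)
        pd.testing.assert_series_equal(base["norm_expr"], scaled["norm_expr"])
        pd.testing.assert_series_equal(base["ifpkm"], scaled["ifpkm"])
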