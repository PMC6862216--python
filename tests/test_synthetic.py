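"""Ground-truth generator: determinism, kinetic consistency, noise model."""

import numpy as np
import pandas as pd
import pytest

from mrnafate.annotation import parse_annotation
from mrnafate.synthetic import (
    GAPDH_ID,
    SimConfig,
    simulate_annotation,
    simulate_chase,
    simulate_dataset,
    simulate_steady_counts,
    simulate_truth,
    write_dataset,
)

LN2 = np.log(2)


class TestTruth:
    def test_abundance_follows_rate_times_half_life(self):
        truth = simulate_truth(SimConfig(seed=1, n_genes=100))
        np.testing.assert_allclose(
            truth["abundance_control"],
            truth["rate_control"] * truth["half_life_control"] / LN2,
        )
        np.testing.assert_allclose(
            truth["abundance_ko"], truth["rate_ko"] * truth["half_life_ko"] / LN2
        )

    def test_designed_classes_perturb_one_parameter(self):
        truth = simulate_truth(SimConfig(seed=1, n_genes=200)).set_index("gene_id")
        stab = truth[truth["designed_class"] == "stabilized"]
        np.testing.assert_allclose(
            stab["half_life_ko"] / stab["half_life_control"], 4.0
        )
        np.testing.assert_allclose(stab["rate_ko"], stab["rate_control"])
        tdown = truth[truth["designed_class"] == "transcription_down"]
        np.testing.assert_allclose(tdown["rate_ko"] / tdown["rate_control"], 0.25)
        np.testing.assert_allclose(tdown["half_life_ko"], tdown["half_life_control"])

    def test_gapdh_is_a_stable_unperturbed_control(self):
        truth = simulate_truth(SimConfig(seed=1)).set_index("gene_id")
        g = truth.loc[GAPDH_ID]
        assert g["half_life_control"] == g["half_life_ko"] > 50
        assert g["rate_control"] == g["rate_ko"]

    def test_fraction_overflow_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(fractions={"stabilized": 0.8, "destabilized": 0.4})


class TestAnnotation:
    def test_round_trips_through_parser(self, tmp_path, small_sim):
        paths = write_dataset(small_sim, tmp_path / "sim")
        models = parse_annotation(paths["annotation"])
        assert set(models) == set(small_sim.models)
        for gid, gm in models.items():
            assert gm.exons == small_sim.models[gid].exons

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=9, n_genes=30, depth=1e4, chase_depth=1e4)
        p1 = write_dataset(simulate_dataset(cfg), tmp_path / "a")
        p2 = write_dataset(simulate_dataset(cfg), tmp_path / "b")
        for key in p1:
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()

    def test_degenerate_geometry_only_in_null_genes(self, default_sim):
        truth = default_sim.truth.set_index("gene_id")
        single_exon = [
            g for g, m in default_sim.models.items() if len(m.exons) == 1
        ]
        assert single_exon, "null genes should include single-exon models"
        assert all(truth.loc[g, "designed_class"] == "null" for g in single_exon)
        designed = truth[truth["designed_class"] != "null"].index
        assert all(
            default_sim.models[g].intron_length_sum >= 150 for g in designed
        )

    def test_genes_do_not_overlap(self, default_sim):
        by_chrom: dict[str, list] = {}
        for gm in default_sim.models.values():
            by_chrom.setdefault(gm.chrom, []).append(gm.span)
        for spans in by_chrom.values():
            spans.sort(key=lambda s: s.start)
            for a, b in zip(spans, spans[1:]):
                assert a.end <= b.start


class TestCountModel:
    def test_effect_ratios_exact_in_expectations(self, default_sim):
        """Relative to null genes, designed expectations shift by exactly
        the effect ratio in the perturbed compartment and not the other."""
        exp = default_sim.steady_expected.pivot_table(
            index="gene_id", columns="condition",
            values=["expected_exonic", "expected_intronic"],
        )
        truth = default_sim.truth.set_index("gene_id")
        ex_ratio = exp[("expected_exonic", "KO")] / exp[("expected_exonic", "control")]
        null_ref = ex_ratio[truth["designed_class"] == "null"].iloc[0]
        for klass, ex_fold, in_fold in [
            ("stabilized", 4.0, 1.0),
            ("destabilized", 0.25, 1.0),
            ("transcription_up", 4.0, 4.0),
            ("transcription_down", 0.25, 0.25),
        ]:
            genes = truth.index[truth["designed_class"] == klass]
            np.testing.assert_allclose(
                ex_ratio[genes] / null_ref, ex_fold, rtol=1e-9
            )
            with_introns = [
                g for g in genes if default_sim.models[g].intron_length_sum > 0
            ]
            in_ratio = (
                exp[("expected_intronic", "KO")][with_introns]
                / exp[("expected_intronic", "control")][with_introns]
            )
            null_in = [
                g
                for g in truth.index[truth["designed_class"] == "null"]
                if default_sim.models[g].intron_length_sum > 0
            ]
            null_in_ref = (
                exp[("expected_intronic", "KO")][null_in[0]]
                / exp[("expected_intronic", "control")][null_in[0]]
            )
            np.testing.assert_allclose(in_ratio / null_in_ref, in_fold, rtol=1e-9)

    def test_poisson_draws_track_expectations(self):
        """Empirical replicate means stay within 4 sigma of the Poisson
        expectation (a seeded Monte Carlo sanity check)."""
        cfg = SimConfig(seed=2, n_genes=20, replicates=40, depth=1e5)
        truth = simulate_truth(cfg)
        models = simulate_annotation(cfg, truth)
        counts, samples, expected = simulate_steady_counts(models, truth, cfg)
        merged = counts.merge(
            samples[["sample_id", "condition"]], on="sample_id"
        ).merge(expected, on=["gene_id", "condition"])
        g = merged.groupby(["gene_id", "condition"])
        mean = g["exonic_count"].mean()
        lam = g["expected_exonic"].first()
        sem = np.sqrt(lam / 40)
        ok = (mean - lam).abs() <= 4 * np.maximum(sem, 1e-9)
        assert ok.mean() > 0.99

    def test_noiseless_counts_equal_expectations(self):
        cfg = SimConfig(seed=2, n_genes=20, poisson_noise=False, replicates=1)
        truth = simulate_truth(cfg)
        models = simulate_annotation(cfg, truth)
        counts, samples, expected = simulate_steady_counts(models, truth, cfg)
        merged = counts.merge(
            samples[["sample_id", "condition"]], on="sample_id"
        ).merge(expected, on=["gene_id", "condition"])
        np.testing.assert_allclose(merged["exonic_count"], merged["expected_exonic"])

    def test_chase_decays_with_designed_half_life(self):
        """Noiseless chase counts fall as 2^(-t/half-life) relative to the
        stable reference gene."""
        cfg = SimConfig(seed=4, n_genes=30, poisson_noise=False, replicates=1)
        truth = simulate_truth(cfg)
        models = simulate_annotation(cfg, truth)
        counts, samples = simulate_chase(models, truth, cfg)
        merged = counts.merge(samples, on="sample_id")
        ctrl = merged[merged["condition"] == "control"].pivot_table(
            index="gene_id", columns="time_point_h", values="exonic_count"
        )
        rel = ctrl.div(ctrl[0.0], axis=0)
        rel = rel.div(rel.loc[GAPDH_ID], axis=1)  # reference-normalized
        hl = truth.set_index("gene_id")["half_life_control"]
        for t in (4.0, 8.0):
            np.testing.assert_allclose(
                rel[t], 2 ** (-t / hl[rel.index]), rtol=1e-4
            )

    def test_overdispersion_inflates_variance(self):
        base = SimConfig(seed=6, n_genes=10, replicates=60, depth=2e4)
        over = SimConfig(seed=6, n_genes=10, replicates=60, depth=2e4, dispersion=0.5)

        def var_sum(cfg):
            truth = simulate_truth(cfg)
            models = simulate_annotation(cfg, truth)
            counts, _, _ = simulate_steady_counts(models, truth, cfg)
            return counts.groupby("gene_id")["exonic_count"].var().sum()

        assert var_sum(over) > 2 * var_sum(base)


class TestGeneSets:
    def test_empty_class_emits_no_planted_term(self):
        cfg = SimConfig(
            seed=7, n_genes=60,
            fractions={"stabilized": 0.2},  # other classes empty
        )
        truth = simulate_truth(cfg)
        from mrnafate.synthetic import simulate_gene_sets

        sets = simulate_gene_sets(truth, cfg)
        planted = [s.term_id for s in sets if s.term_id.startswith("SET_")]
        assert planted == ["SET_STABILIZED"]
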