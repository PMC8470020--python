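"""Synthetic-data generators: determinism, truth-table consistency, models."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from magpot.synthetic import (
    SyntheticMagSpec,
    generate_annotation_table,
    generate_asv_counts,
    generate_protein_set,
    generate_qpcr_run,
    generate_tracer_samples,
    load_reference_marker_table,
    write_fasta,
)


def brute_force_motifs(seq):
    return [p for p in range(len(seq) - 4)
            if seq[p] == "C" and seq[p + 3] == "C" and seq[p + 4] == "H"]


class TestProteinSets:
    def test_seeded_determinism_byte_identical_fasta(self, tmp_path):
        spec = SyntheticMagSpec("KA1", n_background_proteins=15,
                                planted_mhcs=((4, True), (2, False)), seed=42)
        for name in ("a.faa", "b.faa"):
            records, _ = generate_protein_set(spec)
            write_fasta(records, tmp_path / name)
        assert (tmp_path / "a.faa").read_bytes() == (tmp_path / "b.faa").read_bytes()

    def test_planted_motif_counts_exact_by_oracle(self):
        spec = SyntheticMagSpec("KA1", n_background_proteins=0,
                                planted_mhcs=((15, True),), seed=1)
        records, truth = generate_protein_set(spec)
        assert len(records) == 1
        assert truth["motif_count"].tolist() == [15]
        assert len(brute_force_motifs(records[0][1])) == 15

    @pytest.mark.parametrize("seed", range(8))
    def test_background_is_motif_free(self, seed):
        spec = SyntheticMagSpec("KA1", n_background_proteins=50, seed=seed)
        records, truth = generate_protein_set(spec)
        assert not truth["is_mhc"].any()
        assert all(brute_force_motifs(seq) == [] for _, seq in records)

    @pytest.mark.parametrize("seed", range(5))
    def test_truth_table_counts_match_sequences(self, seed):
        spec = SyntheticMagSpec(
            "KA1", n_background_proteins=10,
            planted_mhcs=((2, False), (7, True), (11, True)), seed=seed)
        records, truth = generate_protein_set(spec)
        by_id = dict(records)
        for row in truth.itertuples(index=False):
            assert len(brute_force_motifs(by_id[row.protein_id])) == row.motif_count

    def test_range_too_short_rejected(self):
        spec = SyntheticMagSpec("KA1", background_length_range=(30, 60),
                                planted_mhcs=((20, False),))
        with pytest.raises(ValueError, match="too short"):
            generate_protein_set(spec)

    def test_zero_motif_plant_rejected(self):
        spec = SyntheticMagSpec("KA1", planted_mhcs=((0, False),))
        with pytest.raises(ValueError):
            generate_protein_set(spec)


class TestAnnotationTables:
    def test_rounding_rule_three_of_four(self, catalog):
        from magpot.pathways import PathwayDefinition

        toy = [PathwayDefinition("toy", frozenset("abcd"))]
        spec = SyntheticMagSpec("KA1", pathway_fractions={"toy": 0.75}, seed=0)
        table = generate_annotation_table(spec, toy, catalog)
        assert len(set(table["annotation_id"])) == 3

    def test_full_fraction_gives_complete_pathway(self, definitions, catalog):
        spec = SyntheticMagSpec("KA1", pathway_fractions={"WL": 1.0}, seed=0)
        table = generate_annotation_table(spec, definitions, catalog)
        wl = next(d for d in definitions if d.name == "WL")
        assert set(table["annotation_id"]) == set(wl.essential_genes)

    def test_unknown_pathway_rejected(self, definitions, catalog):
        spec = SyntheticMagSpec("KA1", pathway_fractions={"nope": 1.0})
        with pytest.raises(ValueError, match="unknown pathway"):
            generate_annotation_table(spec, definitions, catalog)

    def test_unknown_marker_rejected(self, definitions, catalog):
        spec = SyntheticMagSpec("KA1", marker_genes=("not_a_marker",))
        with pytest.raises(ValueError, match="unknown marker"):
            generate_annotation_table(spec, definitions, catalog)

    def test_deterministic_given_seed(self, definitions, catalog):
        spec = SyntheticMagSpec("KA1", pathway_fractions={"CBB": 0.5},
                                marker_genes=("sqr", "bzd"), seed=9)
        t1 = generate_annotation_table(spec, definitions, catalog)
        t2 = generate_annotation_table(spec, definitions, catalog)
        pd.testing.assert_frame_equal(t1, t2)


class TestASVTables:
    def test_depth_conserved_exactly(self):
        for seed in range(10):
            t = generate_asv_counts(200, depth=5000, sigma=2.0, seed=seed)
            assert t["count"].sum() == 5000

    def test_uniform_deep_sampling_observes_everything(self):
        t = generate_asv_counts(50, depth=50_000, sigma=0.0, seed=0)
        assert (t["count"] > 0).sum() == 50

    def test_seeded_run_repeats(self):
        t1 = generate_asv_counts(100, depth=3000, seed=5)
        t2 = generate_asv_counts(100, depth=3000, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_asv_counts(100, depth=50)
        with pytest.raises(ValueError):
            generate_asv_counts(10, depth=100, abundance_model="logseries",
                                logseries_p=1.5)
        with pytest.raises(ValueError):
            generate_asv_counts(10, depth=100, abundance_model="zipf")

    def test_skewed_abundances_hide_taxa_and_chao1_corrects(self):
        """With a long-tailed abundance model and modest depth the observed
        richness falls short of the truth and Chao1 moves back toward it."""
        from magpot.diversity import chao1

        richness = 400
        shortfall = 0
        improved = 0
        n_rep = 100
        for seed in range(n_rep):
            t = generate_asv_counts(richness, depth=2000, sigma=2.5, seed=seed)
            counts = t.loc[t["count"] > 0, "count"]
            s_obs = len(counts)
            if s_obs < richness:
                shortfall += 1
                if chao1(counts) > s_obs:
                    improved += 1
        assert shortfall == n_rep
        assert improved >= 95


class TestQPCRRuns:
    def test_noiseless_slope_for_perfect_efficiency(self):
        run = generate_qpcr_run({"s": 1e5}, efficiency_pct=100, cq_noise_sd=0)
        from magpot.quantify import fit_standard_curve
        curve = fit_standard_curve(run.standards)
        assert curve.slope == pytest.approx(-3.3219, abs=5e-5)

    def test_noiseless_round_trip_exact(self):
        from magpot.quantify import fit_standard_curve, quantify_samples

        truth = {"total": 3.03e8, "anme3": 8.85e7}
        run = generate_qpcr_run(truth, efficiency_pct=89.5, cq_noise_sd=0)
        curve = fit_standard_curve(run.standards)
        out = quantify_samples(run.samples, curve)
        for label, copies in truth.items():
            assert out.loc[label, "copies_mean"] == pytest.approx(copies, rel=1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            generate_qpcr_run({"s": 1e5}, efficiency_pct=0)
        with pytest.raises(ValueError):
            generate_qpcr_run({"s": -1.0})
        with pytest.raises(ValueError):
            generate_qpcr_run({"s": 1e5}, standard_copies=(1e5, 2e5, 4e5))

    def test_noisy_recovery_within_tolerance(self):
        """log10 copies recovered within +/-0.2 in >=95/100 seeded runs at
        Cq noise sd 0.1 with triplicates."""
        from magpot.quantify import fit_standard_curve, quantify_samples

        hits = 0
        for seed in range(100):
            run = generate_qpcr_run({"s": 2.4e6}, efficiency_pct=90,
                                    cq_noise_sd=0.1, seed=seed)
            curve = fit_standard_curve(run.standards)
            out = quantify_samples(run.samples, curve)
            err = abs(math.log10(out.loc["s", "copies_mean"]) - math.log10(2.4e6))
            hits += err <= 0.2
        assert hits >= 95


class TestTracerSamples:
    def test_zero_rate_gives_blank_level_product(self):
        t = generate_tracer_samples(true_rate=0.0, control_rate=0.0,
                                    noise_cv=0.0, seed=0)
        assert (t["a_product"] == 0).all()

    def test_fraction_arithmetic(self):
        t = generate_tracer_samples(true_rate=0.2, ch4_pool=100,
                                    incubation_days=5, noise_cv=0.0,
                                    control_rate=0.0, seed=0)
        live = t[~t["is_control"]]
        assert (live["a_product"] / live["a_total"]).tolist() == pytest.approx([0.01] * 3)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError, match="pool too small"):
            generate_tracer_samples(true_rate=10.0, ch4_pool=1.0,
                                    incubation_days=5.0)

    def test_noisy_triplicates_recover_rate_on_average(self):
        from magpot.quantify import aom_rate

        estimates = []
        for seed in range(50):
            t = generate_tracer_samples(seed=seed)
            res = aom_rate(t[~t["is_control"]], t[t["is_control"]],
                           ch4_pool=1400.0, days=5.0)
            estimates.append(res.rate)
        estimates = np.asarray(estimates)
        assert abs(estimates.mean() - 0.47) <= 2 * estimates.std(ddof=1)


def test_reference_marker_table_loads_and_is_consistent():
    table = load_reference_marker_table()
    assert len(table) == 33
    assert table["bin_id"].is_unique
    unid = table[table["expected_labels"].map(lambda l: l == ("Unidentified",))]
    assert set(unid["bin_id"]) == {"KA21", "KA24", "KA27", "KA32", "KA33"}
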