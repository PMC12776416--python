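"""Screen simulator: kinetics, calibration, selection, read emission."""

import math

import numpy as np
import pytest

from pepdisplay.design import LibraryDesign
from pepdisplay.reads import process_sample
from pepdisplay.counting import count_peptides
from pepdisplay.simulate import (
    SimulationConfig,
    SpecificityModel,
    calibrate_exposure,
    emit_fastq,
    expected_enrichment,
    phosphorylation_probability,
    sample_library,
    simulate_screen,
    simulate_selection,
)


class TestPhosphorylationProbability:
    def test_neutral_unit_exposure(self):
        model = SpecificityModel.neutral(3, baseline_rate=1.0, exposure_time=1.0)
        p = phosphorylation_probability("AYA", model)
        assert p == pytest.approx(1.0 - math.exp(-1.0))

    def test_vanishing_exposure(self):
        model = SpecificityModel.neutral(3, baseline_rate=1.0, exposure_time=1e-300)
        assert phosphorylation_probability("AYA", model) == pytest.approx(0.0)

    def test_fourfold_rate_weight(self):
        """A +log(4) weight turns baseline extent 0.1 into 1 - 0.9^4."""
        base_rate = -math.log(0.9)
        model = SpecificityModel.from_preferences(
            3, {(1, "Y"): math.log(4.0)},
            baseline_rate=base_rate, exposure_time=1.0,
        )
        assert phosphorylation_probability("AAA", model) == pytest.approx(0.1)
        assert phosphorylation_probability("AYA", model) == pytest.approx(1.0 - 0.9 ** 4)

    def test_length_mismatch_rejected(self):
        model = SpecificityModel.neutral(3)
        with pytest.raises(ValueError):
            phosphorylation_probability("AAAA", model)


class TestCalibrateExposure:
    def test_neutral_closed_form(self):
        model = SpecificityModel.neutral(2, baseline_rate=2.0)
        pop = {"AY": 10, "CY": 20}
        t = calibrate_exposure(model, pop, 1.0 - math.exp(-1.0))
        assert t == pytest.approx(0.5, rel=1e-6)

    def test_target_midpoint_hit(self, small_screen):
        model = small_screen["model"]
        pop = small_screen["result"]["population"]
        t = calibrate_exposure(model, pop, 0.375)
        peptides = list(pop)
        mean = sum(
            pop[p] * phosphorylation_probability(
                p, SpecificityModel(model.weights, model.baseline_rate, t)
            )
            for p in peptides
        ) / sum(pop.values())
        assert 0.37 <= mean <= 0.38

    def test_monotone_in_target(self):
        model = SpecificityModel.neutral(2)
        pop = {"AY": 5}
        assert calibrate_exposure(model, pop, 0.25) < calibrate_exposure(model, pop, 0.50)

    def test_invalid_target_rejected(self):
        model = SpecificityModel.neutral(2)
        with pytest.raises(ValueError):
            calibrate_exposure(model, {"AY": 1}, 1.5)


class TestSampleLibrary:
    def test_defined_equal_weights(self):
        d = LibraryDesign(kind="defined", peptide_length=2, members=("AY", "CY", "DY"))
        config = SimulationConfig(design=d, n_cells=30_000, seed=3)
        pop = sample_library(config)
        assert sum(pop.values()) == 30_000
        for count in pop.values():
            assert abs(count - 10_000) < 500  # multinomial fluctuation

    def test_degenerate_alphabet(self, x5_design):
        config = SimulationConfig(design=x5_design, n_cells=2000, seed=4)
        pop = sample_library(config)
        allowed = set("ACDEFGHIKLMNPQRSTVWY*")
        for pep in pop:
            assert len(pep) == 11 and set(pep) <= allowed
            assert pep[5] == "Y"

    def test_scanning_support_is_reference_plus_single_mutants(self, scanning_design):
        config = SimulationConfig(design=scanning_design, n_cells=200_000, seed=5)
        pop = sample_library(config)
        ref = scanning_design.reference_peptide
        for pep in pop:
            diffs = sum(a != b for a, b in zip(pep, ref))
            assert diffs <= 1

    def test_dispersion_skews_abundance(self):
        d = LibraryDesign(kind="defined", peptide_length=2, members=tuple(f"{a}Y" for a in "ACDEFGHIKL"))
        flat = sample_library(SimulationConfig(design=d, n_cells=50_000, seed=6))
        skewed = sample_library(
            SimulationConfig(design=d, n_cells=50_000, abundance_dispersion=1.5, seed=6)
        )
        assert np.std(list(skewed.values())) > np.std(list(flat.values()))


class TestSimulateSelection:
    def test_full_capture_keeps_everything(self):
        d = LibraryDesign(kind="defined", peptide_length=2, members=("AY", "CY"))
        config = SimulationConfig(design=d, n_cells=100, capture_efficiency=1.0,
                                  background_capture=0.0, seed=7)
        model = SpecificityModel.neutral(2, baseline_rate=1e9)  # p ~ 1 for all
        pop = {"AY": 60, "CY": 40}
        sorted_pop, unsorted_pop = simulate_selection(pop, model, config)
        assert sorted_pop == pop and unsorted_pop == pop

    def test_zero_rate_zero_background_empties_sorted(self):
        d = LibraryDesign(kind="defined", peptide_length=2, members=("AY",))
        config = SimulationConfig(design=d, n_cells=100, background_capture=0.0, seed=8)
        model = SpecificityModel.neutral(2, baseline_rate=1e-12, exposure_time=1e-12)
        sorted_pop, _ = simulate_selection({"AY": 1000}, model, config)
        assert sorted_pop == {}

    def test_binomial_expectation_ratio(self):
        """Two peptides with extents 0.8 vs 0.2 at equal abundance:
        the sorted ratio approaches 4:1."""
        d = LibraryDesign(kind="defined", peptide_length=2, members=("AY", "CY"))
        config = SimulationConfig(design=d, n_cells=200_000, capture_efficiency=1.0,
                                  background_capture=0.0, seed=9)
        model = SpecificityModel.from_preferences(
            2,
            {(0, "A"): math.log(-math.log(0.2)), (0, "C"): math.log(-math.log(0.8))},
            baseline_rate=1.0,
        )
        pop = {"AY": 100_000, "CY": 100_000}
        assert phosphorylation_probability("AY", model) == pytest.approx(0.8)
        assert phosphorylation_probability("CY", model) == pytest.approx(0.2)
        sorted_pop, _ = simulate_selection(pop, model, config)
        ratio = sorted_pop["AY"] / sorted_pop["CY"]
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_empirical_matches_expected_enrichment(self):
        d = LibraryDesign(kind="defined", peptide_length=2, members=("AY", "CY"))
        config = SimulationConfig(design=d, n_cells=200_000, seed=10)
        model = SpecificityModel.from_preferences(2, {(0, "A"): 1.0}, baseline_rate=0.3)
        pop = {"AY": 100_000, "CY": 100_000}
        expected = expected_enrichment(pop, model, config)
        sorted_pop, _ = simulate_selection(pop, model, config)
        total = sum(sorted_pop.values())
        for pep in pop:
            empirical = (sorted_pop[pep] / total) / (pop[pep] / sum(pop.values()))
            assert empirical == pytest.approx(expected[pep], rel=0.05)


class TestEmitFastq:
    def test_deterministic_output(self, tmp_path, x5_design):
        model = SpecificityModel.neutral(11, positions=x5_design.position_labels())
        config = SimulationConfig(design=x5_design, n_cells=500, reads_per_sample=500, seed=12)
        a = simulate_screen(config, model, tmp_path / "a")
        b = simulate_screen(config, model, tmp_path / "b")
        for key in ("r1", "r2", "truth"):
            assert (a["sorted_files"][key].read_bytes()
                    == b["sorted_files"][key].read_bytes())

    def test_zero_reads_rejected(self, x5_design):
        with pytest.raises(ValueError):
            SimulationConfig(design=x5_design, n_cells=10, reads_per_sample=0)

    def test_error_rate_survival_matches_binomial_expectation(self, tmp_path, x5_design):
        """At 1% per-base substitution error, the fraction of reads
        passing both flank anchors at 1-mismatch tolerance matches the
        binomial computation over the anchor lengths (36 and 37 nt):
        P(<=1 error per anchor) for each, ~0.90 jointly."""
        from pepdisplay.design import FIVE_ANCHOR, THREE_ANCHOR

        p_err = 0.01
        n_reads = 1000

        def p_anchor_ok(length):
            return (1 - p_err) ** length + length * p_err * (1 - p_err) ** (length - 1)

        expected = p_anchor_ok(len(FIVE_ANCHOR)) * p_anchor_ok(len(THREE_ANCHOR))
        sigma = (expected * (1 - expected) / n_reads) ** 0.5
        config = SimulationConfig(design=x5_design, n_cells=n_reads, reads_per_sample=n_reads,
                                  sequencing_error_rate=p_err, seed=13)
        pop = sample_library(config)
        files = emit_fastq(pop, x5_design, config, tmp_path / "err")
        _, stats = process_sample(files["r1"], files["r2"], x5_design)
        passed = 1 - stats.counts["flank_fail"] / n_reads
        # anchor errors can be masked in the read overlap, so a little
        # above expectation is fine; far below is not
        assert passed >= expected - 4 * sigma

    def test_zero_error_round_trip_matches_truth(self, small_screen, x5_design):
        import pandas as pd

        truth = pd.read_csv(small_screen["result"]["unsorted_files"]["truth"], sep="\t")
        ct = count_peptides(small_screen["records_unsorted"])
        assert ct.entries == dict(zip(truth.peptide, truth.reads))
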