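"""Synthetic-data generator: meiosis, population structure, layouts,
phenotypes and thermal scenes."""

import numpy as np
import pandas as pd
import pytest

from thermoqtl import simulate as sim
from thermoqtl.errors import (
    DimensionError,
    DomainError,
    InvalidParameterError,
    LayoutError,
    LookupError_,
)
from thermoqtl.genmap import GeneticMap, kosambi
from thermoqtl.thermal import CameraCalibration, raw_to_temperature


class TestSimulateGeneticMap:
    def test_minimal_map(self):
        m = sim.simulate_genetic_map(1, 100.0, 2, seed=1)
        pos = m.positions(1)
        assert len(pos) == 2 and pos[0] == 0.0 and pos[1] <= 100.0

    def test_marker_count_arithmetic(self):
        m = sim.simulate_genetic_map(12, 80.0, 13, seed=7)
        assert m.n_markers == 156

    def test_deterministic_under_seed(self):
        a = sim.simulate_genetic_map(5, 50.0, 8, seed=42)
        b = sim.simulate_genetic_map(5, 50.0, 8, seed=42)
        assert a == b

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            sim.simulate_genetic_map(0, 100.0, 5, seed=1)
        with pytest.raises(InvalidParameterError):
            sim.simulate_genetic_map(1, -1.0, 5, seed=1)


class TestSimulateGamete:
    def test_zero_distance_coinherited(self, rng):
        gmap = GeneticMap(
            pd.DataFrame({"marker": ["a", "b"], "chrom": [1, 1], "cM": [0.0, 1e-12]})
        )
        h1, h2 = np.array([1.0, 1.0]), np.array([0.0, 0.0])
        for _ in range(200):
            g = sim.simulate_gamete(gmap, (h1, h2), rng)
            assert g[0] == g[1]

    def test_recombination_fraction_matches_kosambi(self, rng):
        d = 21.18  # Kosambi inverse of r = 0.200
        gmap = GeneticMap(
            pd.DataFrame({"marker": ["a", "b"], "chrom": [1, 1], "cM": [0.0, d]})
        )
        h1, h2 = np.ones(2), np.zeros(2)
        n = 10_000
        g = sim._gametes(gmap, np.tile(h1, (n, 1)), np.tile(h2, (n, 1)), rng)
        r_hat = np.mean(g[:, 0] != g[:, 1])
        # 4 sigma Monte-Carlo band around 0.200
        assert abs(r_hat - 0.2) < 4 * np.sqrt(0.2 * 0.8 / n)

    def test_identical_parents_invariant(self, small_map, rng):
        h = rng.integers(0, 2, small_map.n_markers).astype(float)
        g = sim.simulate_gamete(small_map, (h, h), rng)
        assert np.array_equal(g, h)

    def test_dimension_mismatch(self, small_map, rng):
        with pytest.raises(DimensionError):
            sim.simulate_gamete(small_map, (np.ones(3), np.ones(3)), rng)


class TestIbcPopulation:
    def test_bc2_donor_frequency(self, study_map):
        pop = sim.simulate_ibc_population(study_map, 2000, 2, 0, seed=5)
        # expected donor frequency (1/2)^(1+2) = 12.5 %
        assert pop.donor_allele_frequency() == pytest.approx(0.125, abs=0.01)

    def test_bc2s3_frequency_and_heterozygosity(self, study_map):
        pop = sim.simulate_ibc_population(study_map, 2000, 2, 3, seed=6)
        assert pop.donor_allele_frequency() == pytest.approx(0.125, abs=0.01)
        # heterozygosity halves per self generation: 0.25 * (1/2)^3
        assert pop.heterozygote_fraction() == pytest.approx(0.03125, abs=0.01)

    def test_selfing_halves_heterozygosity_stepwise(self, study_map):
        hets = [
            sim.simulate_ibc_population(study_map, 1500, 2, k, seed=7).heterozygote_fraction()
            for k in (0, 1, 2)
        ]
        for k, h in enumerate(hets):
            assert h == pytest.approx(0.25 * 0.5**k, abs=0.012)

    def test_deterministic_and_typed(self, small_map):
        a = sim.simulate_ibc_population(small_map, 50, 2, 3, seed=3)
        b = sim.simulate_ibc_population(small_map, 50, 2, 3, seed=3)
        pd.testing.assert_frame_equal(a.dosage, b.dosage)
        assert set(np.unique(a.values())) <= {0.0, 0.5, 1.0}
        assert a.generation_label == "BC2S3"

    def test_rejects_bad_parameters(self, small_map):
        with pytest.raises(InvalidParameterError):
            sim.simulate_ibc_population(small_map, 0, 2, 3, seed=1)
        with pytest.raises(InvalidParameterError):
            sim.simulate_ibc_population(small_map, 5, 0, 3, seed=1)


class TestAugmentedLayout:
    def test_study_dimensions(self):
        lay = sim.make_augmented_layout(160, n_rows=16, n_columns=15, seed=0)
        assert len(lay) == 160 + 2 * 36
        plots = lay.plots
        # every row and column holds at least one check
        checks = plots[plots["is_check"]]
        assert set(checks["row"]) == set(range(1, 17))
        assert set(checks["column"]) == set(range(1, 16))
        assert checks["check_name"].value_counts().tolist() == [36, 36]
        # entries unreplicated
        assert plots.loc[~plots["is_check"], "entry_id"].is_unique

    def test_single_plot_layout(self):
        lay = sim.make_augmented_layout(
            1, check_names=[], n_check_reps=0, n_rows=1, n_columns=1, seed=0
        )
        assert len(lay) == 1

    def test_deterministic(self):
        a = sim.make_augmented_layout(30, n_rows=10, n_columns=11, seed=9)
        b = sim.make_augmented_layout(30, n_rows=10, n_columns=11, seed=9)
        pd.testing.assert_frame_equal(a.plots, b.plots)

    def test_capacity_violation(self):
        with pytest.raises(LayoutError):
            sim.make_augmented_layout(100, n_rows=5, n_columns=5, seed=0)


class TestSimulatePhenotypes:
    def _layout(self, pop, seed=0):
        return sim.make_augmented_layout(
            pop.n_lines, n_check_reps=6, n_rows=8, n_columns=9,
            seed=seed, entry_ids=pop.line_ids,
        )

    def test_zero_variance_no_qtl_is_constant(self, small_map):
        pop = sim.simulate_ibc_population(small_map, 50, 2, 3, seed=1)
        vs = sim.VarianceSpec(0.0, 0.0, 0.0, 0.0, trait_means={"canopy_temp": 25.0})
        ph = sim.simulate_phenotypes(
            pop, small_map, [], self._layout(pop), vs, seed=2, traits=["canopy_temp"]
        )
        assert np.allclose(ph["canopy_temp"], 25.0)

    def test_qtl_effect_separates_checks_on_liability(self, small_map):
        # single QTL of +0.4 on the turgor liability; noise-free generator,
        # donor check carries dosage 1 at every marker, recurrent dosage 0
        pop = sim.simulate_ibc_population(small_map, 50, 2, 3, seed=1)
        vs = sim.VarianceSpec(0.0, 0.0, 0.0, 0.0)
        qtl = [sim.QtlEffect(1, 10.0, "liab", 0.4)]
        ph = sim.simulate_phenotypes(
            pop, small_map, qtl, self._layout(pop), vs, seed=2, traits=["liab"]
        )
        donor = ph.loc[ph["check_name"] == sim.DONOR_CHECK, "liab"].mean()
        recur = ph.loc[ph["check_name"] == sim.RECURRENT_CHECK, "liab"].mean()
        assert donor - recur == pytest.approx(0.4, abs=1e-12)

    def test_turgor_codomain(self, small_map):
        pop = sim.simulate_ibc_population(small_map, 50, 2, 3, seed=1)
        vs = sim.VarianceSpec(1.0, 0.3, 0.3, 1.0)
        ph = sim.simulate_phenotypes(
            pop, small_map, [], self._layout(pop), vs, seed=3, traits=["turgor"]
        )
        assert set(ph["turgor"]) <= {1.0, 2.0, 3.0, 4.0, 5.0}

    def test_variance_recovery_in_balanced_sim(self, small_map):
        # plain CRD-style truth check on the generator itself: sample
        # variance of genotype means approaches genotype_var
        pop = sim.simulate_ibc_population(small_map, 400, 2, 3, seed=4)
        vs = sim.VarianceSpec(2.0, 0.0, 0.0, 0.0)
        lay = sim.make_augmented_layout(
            400, check_names=[], n_check_reps=0, n_rows=20, n_columns=20,
            seed=0, entry_ids=pop.line_ids,
        )
        ph = sim.simulate_phenotypes(pop, small_map, [], lay, vs, seed=5, traits=["y"])
        assert ph["y"].var(ddof=1) == pytest.approx(2.0, rel=0.25)

    def test_unknown_entry_raises(self, small_map):
        pop = sim.simulate_ibc_population(small_map, 10, 2, 3, seed=1)
        lay = sim.make_augmented_layout(
            11, check_names=[], n_check_reps=0, n_rows=4, n_columns=4, seed=0
        )
        with pytest.raises(LookupError_):
            sim.simulate_phenotypes(
                pop, small_map, [], lay, sim.VarianceSpec(), seed=0, traits=["y"]
            )


class TestThermalScene:
    def test_noise_free_scene_has_two_levels(self, calib):
        truth = sim.ThermalSceneTruth(22.0, 30.0, sim.ellipse_mask((40, 50)), 0.0)
        img = sim.simulate_thermal_scene(truth, calib, seed=0)
        assert len(np.unique(img.counts)) == 2

    def test_round_trip_recovers_temperatures(self, calib):
        truth = sim.ThermalSceneTruth(22.0, 30.0, sim.ellipse_mask((40, 50)), 0.5)
        img = sim.simulate_thermal_scene(truth, calib, seed=1)
        T = raw_to_temperature(img, calib)
        # quantization step of this calibration near ambient is ~3 mK/count
        assert 15.0 < T.min() and T.max() < 35.0
        canopy = T[truth.true_mask]
        assert canopy.mean() == pytest.approx(22.0, abs=0.1)

    def test_empty_mask_rejected(self):
        with pytest.raises(DomainError):
            sim.ThermalSceneTruth(22.0, 30.0, np.zeros((5, 5), dtype=bool))


class TestStudyBundle:
    def test_simulate_study_shapes_and_determinism(self):
        a = sim.simulate_study(3)
        b = sim.simulate_study(3)
        assert a["population"].n_lines == 160
        assert a["map"].n_markers == 156
        assert set(a["phenotypes"]["environment"]) == {"summer", "fall"}
        assert list(a["truth"].columns) == ["turgor", "canopy_temp"]
        pd.testing.assert_frame_equal(a["phenotypes"], b["phenotypes"])
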