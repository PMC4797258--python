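"""Dose model, stochastic fragment model and the end-to-end Monte Carlo.

The Monte-Carlo checks compare empirical frequencies against the closed-form
linkage curve, which is the independent oracle for the sampler: the two are
implemented from different formulas (inverse-CDF sampling vs the survival
function) and must agree within Monte-Carlo error.
"""

import math
from pathlib import Path

import numpy as np
import pytest

from p1deconv.genome import GenomeMap, MarkerInsertion, MarkerLibrary, load_marker_table, load_variants, load_gene_features
from p1deconv.linkage import wu_frequency
from p1deconv.simulate import (
    DoseModel,
    FragmentModel,
    ScreenSimConfig,
    dose_for_target,
    generate_fixtures,
    load_sim_config,
    mutation_count_probabilities,
    run_deconvolution_sim,
    sample_replacement_extent,
    simulate_detection,
    simulate_mutant_genomes,
    simulate_transduction,
    synthetic_annotation,
)


class TestDoseModel:
    @pytest.mark.parametrize(
        "lam,expected",
        [
            (0.0, (1.0, 0.0, 0.0)),
            (6.0, (0.00248, 0.01487, 0.98265)),
            (math.log(2), (0.5, 0.5 * math.log(2), 1 - 0.5 - 0.5 * math.log(2))),
        ],
    )
    def test_count_probabilities(self, lam, expected):
        p = mutation_count_probabilities(DoseModel(lam))
        assert p == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0, 2.0, 6.0, 12.0])
    def test_probabilities_sum_to_one(self, lam):
        assert sum(mutation_count_probabilities(DoseModel(lam))) == pytest.approx(1.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            DoseModel(-1.0)

    @pytest.mark.parametrize(
        "fraction,lam", [(0.95, math.log(20)), (0.5, math.log(2))]
    )
    def test_dose_for_target(self, fraction, lam):
        assert dose_for_target(fraction) == pytest.approx(lam)

    def test_dose_round_trip(self):
        lam = 6.0
        p0, _, _ = mutation_count_probabilities(DoseModel(lam))
        assert dose_for_target(1 - p0) == pytest.approx(lam)

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            dose_for_target(1.0)


class TestMutantGenomes:
    def test_mean_count_recovers_dose(self, toy_genome):
        rng = np.random.default_rng(0)
        genomes, _ = simulate_mutant_genomes(toy_genome, 10_000, 6.0, 0.1, rng)
        counts = [len(g.positions) for g in genomes]
        se = math.sqrt(6.0 / len(counts))
        assert np.mean(counts) == pytest.approx(6.0, abs=3 * se)

    def test_zero_causative_fraction_blocks_screen(self, toy_genome):
        rng = np.random.default_rng(0)
        genomes, retention = simulate_mutant_genomes(toy_genome, 500, 6.0, 0.0, rng)
        assert retention == 0.0
        assert not any(g.screened for g in genomes)

    def test_all_causative_retention_matches_poisson_zero_class(self, toy_genome):
        rng = np.random.default_rng(1)
        _, retention = simulate_mutant_genomes(toy_genome, 20_000, 6.0, 1.0, rng)
        expected = 1 - math.exp(-6.0)
        assert retention == pytest.approx(expected, abs=3 * math.sqrt(expected * (1 - expected) / 20_000))


class TestDetection:
    def test_extremes(self):
        rng = np.random.default_rng(0)
        positions = list(range(100))
        assert simulate_detection(positions, 1.0, rng) == positions
        assert simulate_detection(positions, 0.0, rng) == []

    def test_retained_fraction_binomial(self):
        rng = np.random.default_rng(0)
        positions = list(range(10_000))
        kept = simulate_detection(positions, 0.9, rng)
        se = math.sqrt(0.9 * 0.1 / 10_000)
        assert len(kept) / 10_000 == pytest.approx(0.9, abs=3 * se)


class TestFragmentModel:
    def test_extent_boundaries(self):
        model = FragmentModel(100_000)

        class FakeRng:
            def __init__(self, u):
                self.u = u

            def random(self, shape):
                return np.full(shape, self.u)

        assert sample_replacement_extent(model, FakeRng(1.0)).tolist() == [0.0, 0.0]
        assert sample_replacement_extent(model, FakeRng(0.0)).tolist() == [100_000.0, 100_000.0]

    def test_extent_survival_matches_linkage_curve(self):
        """Empirical P(X >= d) equals the closed-form curve at 19 distances."""
        model = FragmentModel(100_000)
        rng = np.random.default_rng(123)
        extents = sample_replacement_extent(model, rng, size=100_000)[:, 0]
        for d in range(5_000, 100_000, 5_000):
            expected = wu_frequency(d)
            emp = float((extents >= d).mean())
            se = math.sqrt(expected * (1 - expected) / len(extents))
            assert emp == pytest.approx(expected, abs=3 * se + 1e-12)


class TestTransduction:
    def _single_marker(self, genome):
        return MarkerInsertion("m", "s", 100_000, 100_000)

    def test_mutation_at_reference_point_always_replaced(self, toy_genome):
        rng = np.random.default_rng(0)
        outcomes = simulate_transduction(
            [100_000], [True], self._single_marker(toy_genome),
            FragmentModel(), 200, toy_genome, rng,
        )
        assert all(o.replaced[0] and o.reverted for o in outcomes)

    def test_replacement_fraction_matches_curve_at_20kb(self, toy_genome):
        rng = np.random.default_rng(7)
        outcomes = simulate_transduction(
            [120_000], [True], self._single_marker(toy_genome),
            FragmentModel(), 100_000, toy_genome, rng,
        )
        frac = np.mean([o.replaced[0] for o in outcomes])
        se = math.sqrt(0.512 * 0.488 / len(outcomes))
        assert frac == pytest.approx(wu_frequency(20_000), abs=3 * se)

    def test_same_side_pair_separation_matches_curve(self, toy_genome):
        rng = np.random.default_rng(11)
        outcomes = simulate_transduction(
            [120_000, 130_000], [True, False], self._single_marker(toy_genome),
            FragmentModel(), 100_000, toy_genome, rng,
        )
        sep = np.mean([o.replaced[0] and not o.replaced[1] for o in outcomes])
        se = math.sqrt(0.169 * (1 - 0.169) / len(outcomes))
        assert sep == pytest.approx(0.169, abs=3 * se)

    def test_same_side_replacement_is_nested(self, toy_genome):
        """A far locus is never replaced without every nearer same-side locus."""
        rng = np.random.default_rng(13)
        positions = [110_000, 130_000, 160_000]  # same side, increasing distance
        outcomes = simulate_transduction(
            positions, [False] * 3, self._single_marker(toy_genome),
            FragmentModel(), 20_000, toy_genome, rng,
        )
        for o in outcomes:
            assert o.replaced == tuple(sorted(o.replaced, reverse=True))

    def test_wraparound_locus_reachable(self):
        g = GenomeMap("t", 200_000)
        marker = MarkerInsertion("m", "s", 10, 11)
        rng = np.random.default_rng(17)
        # locus at 190,010: 10 kb counter-clockwise of the marker across the origin
        outcomes = simulate_transduction([190_010], [True], marker,
                                         FragmentModel(), 50_000, g, rng)
        frac = np.mean([o.replaced[0] for o in outcomes])
        expected = wu_frequency(10_000.5)
        se = math.sqrt(expected * (1 - expected) / len(outcomes))
        assert frac == pytest.approx(expected, abs=3 * se)


class TestEndToEnd:
    def test_tallies_conserved_and_deterministic(self, toy_genome, uniform_library):
        cfg = ScreenSimConfig(genome=toy_genome, n_reps=300, seed=42,
                              causative_fraction=0.1)
        s1 = run_deconvolution_sim(cfg, uniform_library)
        s2 = run_deconvolution_sim(cfg, uniform_library)
        assert s1 == s2
        assert s1.n_success + sum(s1.failure_modes.values()) == cfg.n_reps

    def test_zero_sensitivity_all_undetected(self, toy_genome, uniform_library):
        cfg = ScreenSimConfig(genome=toy_genome, n_reps=100, seed=1,
                              causative_fraction=0.2, detection_sensitivity=0.0)
        s = run_deconvolution_sim(cfg, uniform_library)
        assert s.success_rate == 0.0
        assert s.failure_modes["causative_undetected_by_WGS"] == 100

    def test_single_pick_success_near_frequency(self, toy_genome, uniform_library):
        """One pick, one causative mutation at a fixed-frequency distance:
        success rate approaches the co-transduction frequency itself."""
        cfg = ScreenSimConfig(genome=toy_genome, n_reps=3_000, seed=5,
                              causative_fraction=1.0, fixed_mutation_count=1,
                              n_picks=1, revertant_threshold=1, plate_noise_sd=0.0)
        s = run_deconvolution_sim(cfg, uniform_library)
        # distance uniform in [0, 25 kb] -> mean success = E[wu(d)] = integral
        expected = np.mean([wu_frequency(d) for d in np.linspace(0, 25_000, 2_001)])
        se = math.sqrt(expected * (1 - expected) / cfg.n_reps)
        assert s.success_rate == pytest.approx(expected, abs=4 * se)

    def test_high_linkage_screen_nearly_always_succeeds(self, toy_genome, uniform_library):
        cfg = ScreenSimConfig(genome=toy_genome, n_reps=1_500, seed=9,
                              causative_fraction=1.0, fixed_mutation_count=1,
                              plate_noise_sd=0.0)
        s = run_deconvolution_sim(cfg, uniform_library)
        assert s.success_rate >= 0.999
        assert s.wilson_ci[0] > 0.99

    def test_config_validation(self, toy_genome, uniform_library):
        with pytest.raises(ValueError, match="seed"):
            ScreenSimConfig(genome=toy_genome, n_reps=10)
        with pytest.raises(ValueError):
            ScreenSimConfig(genome=toy_genome, n_reps=0, seed=1)
        cfg = ScreenSimConfig(genome=toy_genome, n_reps=10, seed=1,
                              causative_fraction=0.0)
        with pytest.raises(ValueError, match="causative"):
            run_deconvolution_sim(cfg, uniform_library)
        cfg2 = ScreenSimConfig(genome=toy_genome, n_reps=10, seed=1)
        with pytest.raises(ValueError, match="empty"):
            run_deconvolution_sim(cfg2, MarkerLibrary(toy_genome, []))


class TestFixtures:
    def test_same_seed_byte_identical(self, tmp_path):
        a = generate_fixtures(tmp_path / "a", seed=99)
        b = generate_fixtures(tmp_path / "b", seed=99)
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_different_seed_differs(self, tmp_path):
        a = generate_fixtures(tmp_path / "a", seed=1)
        b = generate_fixtures(tmp_path / "b", seed=2)
        assert a["vcf"].read_bytes() != b["vcf"].read_bytes()

    def test_fixture_set_is_self_consistent(self, tmp_path):
        paths = generate_fixtures(tmp_path / "fx", seed=3, genome_length=500_000,
                                  target_spacing_bp=50_000)
        g = GenomeMap("synthetic", 500_000)
        lib = load_marker_table(paths["markers"], g)
        assert len(lib) == 10  # 500 kb / 50 kb
        genes = load_gene_features(paths["genes"])
        assert genes, "annotation must contain genes"
        variants = load_variants(paths["vcf"], g, contig="synthetic")
        assert variants
        from p1deconv.planner import load_plate_tsv

        wells = load_plate_tsv(paths["plate"])
        groups = {w.group for w in wells}
        assert {"WT_REF", "MUT_REF"} <= groups

    def test_variant_count_override(self, tmp_path):
        paths = generate_fixtures(tmp_path / "fx", seed=5, n_variants=4)
        g = GenomeMap("synthetic", 500_000)
        assert len(load_variants(paths["vcf"], g, contig="synthetic")) == 4


class TestSimConfigFile:
    def test_flat_key_value_round_trip(self, tmp_path):
        p = tmp_path / "sim.cfg"
        p.write_text(
            "genome_length: 500000\nn_reps: 50\nlam: 6.0\n"
            "causative_fraction: 0.1\nseed: 7\n"
        )
        cfg = load_sim_config(p)
        assert cfg.genome.length_bp == 500_000
        assert cfg.n_reps == 50
        assert cfg.seed == 7

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "sim.cfg"
        p.write_text("seed: 1\nbogus_key: 2\n")
        with pytest.raises(ValueError, match="bogus_key"):
            load_sim_config(p)

    def test_override_wins(self, tmp_path):
        p = tmp_path / "sim.cfg"
        p.write_text("seed: 1\nn_reps: 10\n")
        cfg = load_sim_config(p, seed=99)
        assert cfg.seed == 99
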