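import numpy as np
import pytest
from scipy import integrate, stats

from crossgain.gmap import GeneticMap
from crossgain.crosspred import (
    CrossSpec,
    enumerate_cross_oracle,
    expected_ld_ril,
    predict_correlated_response,
    predict_cross_covariance,
    predict_cross_mean,
    predict_cross_variance,
    predict_crosses,
    predict_superior_progeny,
    recombination_fraction,
    selection_intensity,
    simulate_cross_oracle,
)


def _map_one_chrom(positions):
    pos = np.asarray(positions, float)
    ids = np.array([f"m{i}" for i in range(pos.size)], object)
    return GeneticMap(ids, np.ones(pos.size, int), pos)


def _random_cross(gmap, rng, n_traits=1):
    m = gmap.n_markers
    z1 = rng.choice([-1.0, 1.0], m)
    z2 = rng.choice([-1.0, 1.0], m)
    cross = CrossSpec.from_parents("p1", z1, "p2", z2)
    effects = [rng.normal(size=m) for _ in range(n_traits)]
    return cross, effects


class TestRecombination:
    def test_same_marker_zero(self, small_map):
        assert recombination_fraction(small_map, 0, 0) == 0.0

    def test_cross_chromosome_half(self, small_map):
        assert recombination_fraction(small_map, 0, 6) == 0.5

    def test_ten_cm(self):
        m = _map_one_chrom([0.0, 10.0])
        assert recombination_fraction(m, 0, 1) == pytest.approx(
            0.5 * (1 - np.exp(-0.2)), abs=1e-12)


class TestExpectedLd:
    def test_closed_form_values(self):
        assert expected_ld_ril(0.0) == 1.0
        assert expected_ld_ril(0.5) == 0.0
        assert expected_ld_ril(0.25) == pytest.approx(1.0 / 3.0, abs=1e-14)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_ld_ril(0.6)
        with pytest.raises(ValueError):
            expected_ld_ril(-0.01)

    def test_finite_generations_deferred_to_mc(self):
        with pytest.raises(ValueError, match="simulate_cross_oracle"):
            expected_ld_ril(0.2, generations=4)

    def test_matches_two_locus_selfing_recursion(self):
        # independent numeric oracle: iterate the actual two-locus selfing
        # chain to fixation and read off the coupling probability
        from crossgain.crosspred import _exact_ril_distribution
        for c in (0.05, 0.25, 0.4):
            q = _exact_ril_distribution(
                np.array([0, 0], np.uint8), np.array([1, 1], np.uint8),
                np.array([0.5, c]))
            # haplotypes 00,10,01,11 (bit k = locus k): D = corr of origins
            p_same = q[0] + q[3]
            D_numeric = 2 * p_same - 1
            assert D_numeric == pytest.approx(expected_ld_ril(c), abs=1e-12)


class TestSelectionIntensity:
    def test_limits_and_closed_forms(self):
        assert selection_intensity(0.999999) == pytest.approx(0.0, abs=1e-3)
        assert selection_intensity(0.5) == pytest.approx(
            2 * stats.norm.pdf(0.0), abs=1e-12)

    def test_p10_matches_truncated_normal_quadrature(self):
        p = 0.10
        z = stats.norm.ppf(1 - p)
        mean_tail, _ = integrate.quad(
            lambda x: x * stats.norm.pdf(x) / p, z, 40)
        k = selection_intensity(p)
        assert k == pytest.approx(mean_tail, abs=1e-4)
        assert k == pytest.approx(1.7550, abs=1e-4)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.3, 1.2])
    def test_invalid_p(self, p):
        with pytest.raises(ValueError):
            selection_intensity(p)


class TestPredictMean:
    def test_identical_parents(self):
        m = _map_one_chrom([0, 10, 20])
        z = np.array([1.0, -1.0, 1.0])
        u = np.array([0.5, 1.0, -2.0])
        cross = CrossSpec.from_parents("a", z, "a", z)
        assert predict_cross_mean(cross, u) == pytest.approx(float(z @ u))

    def test_single_segregating_locus_gives_intercept(self):
        m = _map_one_chrom([0.0])
        cross = CrossSpec.from_parents("a", np.array([1.0]), "b",
                                       np.array([-1.0]))
        from crossgain.rrblup import MarkerEffects
        eff = MarkerEffects("t", 3.5, np.array([2.0]), 1, 1, 1)
        assert predict_cross_mean(cross, eff) == pytest.approx(3.5)

    def test_mean_within_mc_error(self):
        gmap = GeneticMap.uniform(3, 8, 90.0)
        rng = np.random.default_rng(0)
        cross, (u,) = _random_cross(gmap, rng)
        mu = predict_cross_mean(cross, u)
        mean, var, _ = simulate_cross_oracle(cross, [u], gmap, 10000, None,
                                             np.random.default_rng(1))
        se = np.sqrt(var[0] / 10000)
        assert abs(mean[0] - mu) < 3 * se


class TestPredictVariance:
    def test_one_segregating_locus(self):
        m = _map_one_chrom([0.0])
        cross = CrossSpec.from_parents("a", np.array([1.0]), "b",
                                       np.array([-1.0]))
        assert predict_cross_variance(cross, np.array([2.0]), m) == \
            pytest.approx(4.0, abs=1e-12)

    def test_unlinked_loci_add(self):
        gmap = GeneticMap(np.array(["x", "y"], object), np.array([1, 2]),
                          np.array([0.0, 0.0]))
        cross = CrossSpec.from_parents("a", np.array([1.0, 1.0]), "b",
                                       np.array([-1.0, -1.0]))
        u = np.array([1.5, -2.5])
        assert predict_cross_variance(cross, u, gmap) == pytest.approx(
            1.5 ** 2 + 2.5 ** 2, abs=1e-12)

    def test_complete_linkage_coupling_vs_repulsion(self):
        gmap = _map_one_chrom([5.0, 5.0])
        a, b = 1.2, 0.8
        coupling = CrossSpec.from_parents("p", np.array([1.0, 1.0]), "q",
                                          np.array([-1.0, -1.0]))
        repulsion = CrossSpec.from_parents("p", np.array([1.0, -1.0]), "q",
                                           np.array([-1.0, 1.0]))
        u = np.array([a, b])
        assert predict_cross_variance(coupling, u, gmap) == pytest.approx(
            (a + b) ** 2, abs=1e-12)
        assert predict_cross_variance(repulsion, u, gmap) == pytest.approx(
            (a - b) ** 2, abs=1e-12)

    def test_empty_segregating_set_zero(self):
        m = _map_one_chrom([0, 10])
        z = np.array([1.0, -1.0])
        cross = CrossSpec.from_parents("a", z, "a", z)
        assert predict_cross_variance(cross, np.array([1.0, 1.0]), m) == 0.0

    def test_variance_within_mc_error_200_markers(self):
        gmap = GeneticMap.uniform(10, 20, 100.0)
        rng = np.random.default_rng(2)
        cross, (u,) = _random_cross(gmap, rng)
        v = predict_cross_variance(cross, u, gmap)
        _, var, _ = simulate_cross_oracle(cross, [u], gmap, 10000, None,
                                          np.random.default_rng(3))
        se = v * np.sqrt(2.0 / 9999)
        assert abs(var[0] - v) < 3 * se

    def test_intercept_and_monomorphic_effects_invariance(self):
        gmap = GeneticMap.uniform(2, 6, 60.0)
        rng = np.random.default_rng(4)
        cross, (u,) = _random_cross(gmap, rng)
        v1 = predict_cross_variance(cross, u, gmap)
        u2 = u.copy()
        u2[~cross.seg] += rng.normal(size=(~cross.seg).sum()) * 10
        assert predict_cross_variance(cross, u2, gmap) == pytest.approx(
            v1, abs=1e-9)


class TestPredictCovariance:
    def test_proportional_effects_give_unit_correlation(self):
        gmap = GeneticMap.uniform(2, 8, 80.0)
        rng = np.random.default_rng(5)
        cross, (u,) = _random_cross(gmap, rng)
        _, rg = predict_cross_covariance(cross, u, 2.0 * u, gmap)
        assert rg == pytest.approx(1.0, abs=1e-10)
        _, rg_neg = predict_cross_covariance(cross, u, -u, gmap)
        assert rg_neg == pytest.approx(-1.0, abs=1e-10)

    def test_correlation_flagged_nan_for_zero_variance(self):
        gmap = _map_one_chrom([0.0, 10.0])
        cross = CrossSpec.from_parents("a", np.array([1.0, 1.0]), "b",
                                       np.array([-1.0, 1.0]))
        u1 = np.array([1.0, 0.0])
        u2 = np.array([0.0, 5.0])  # only loads the monomorphic locus
        cov, rg = predict_cross_covariance(cross, u1, u2, gmap)
        assert np.isnan(rg)

    def test_covariance_within_mc_error(self):
        gmap = GeneticMap.uniform(5, 10, 100.0)
        rng = np.random.default_rng(6)
        cross, (u1, u2) = _random_cross(gmap, rng, n_traits=2)
        u2 = 0.6 * u1 + 0.8 * u2  # induce correlation
        cov, rg = predict_cross_covariance(cross, u1, u2, gmap)
        _, _, corr = simulate_cross_oracle(cross, [u1, u2], gmap, 10000,
                                           None, np.random.default_rng(7))
        se = (1 - rg ** 2) / np.sqrt(10000)
        assert abs(corr[0, 1] - rg) < 4 * se

    def test_symmetry_under_parent_swap(self):
        gmap = GeneticMap.uniform(3, 7, 70.0)
        rng = np.random.default_rng(8)
        cross, (u1, u2) = _random_cross(gmap, rng, n_traits=2)
        swapped = CrossSpec.from_parents("p2", cross.z2, "p1", cross.z1)
        assert predict_cross_mean(cross, u1) == pytest.approx(
            predict_cross_mean(swapped, u1), abs=1e-12)
        assert predict_cross_variance(cross, u1, gmap) == pytest.approx(
            predict_cross_variance(swapped, u1, gmap), abs=1e-10)
        c1, r1 = predict_cross_covariance(cross, u1, u2, gmap)
        c2, r2 = predict_cross_covariance(swapped, u1, u2, gmap)
        assert c1 == pytest.approx(c2, abs=1e-10)

    def test_predicted_covariance_matrix_psd(self):
        gmap = GeneticMap.uniform(4, 10, 90.0)
        rng = np.random.default_rng(9)
        m = gmap.n_markers
        z1 = rng.choice([-1.0, 1.0], m)
        z2 = rng.choice([-1.0, 1.0], m)
        effects = {f"t{k}": rng.normal(size=m) for k in range(4)}
        pred = predict_crosses([("a", z1, "b", z2)], effects, gmap)[0]
        w = np.linalg.eigvalsh(pred.cov_g)
        assert w.min() >= -1e-8 * max(w.max(), 1.0)


class TestSuperiorProgeny:
    def test_zero_variance(self):
        assert predict_superior_progeny(3.0, 0.0, 0.1) == 3.0

    def test_known_value_high(self):
        assert predict_superior_progeny(0.0, 1.0, 0.10, "high") == \
            pytest.approx(1.7550, abs=1e-4)

    def test_low_direction_flips_sign(self):
        hi = predict_superior_progeny(5.0, 2.0, 0.2, "high")
        lo = predict_superior_progeny(5.0, 2.0, 0.2, "low")
        assert hi - 5.0 == pytest.approx(5.0 - lo, abs=1e-12)

    def test_unknown_direction(self):
        with pytest.raises(ValueError, match="direction"):
            predict_superior_progeny(0.0, 1.0, 0.1, "sideways")


class TestCorrelatedResponse:
    def test_zero_correlation(self):
        assert predict_correlated_response(4.0, 2.0, 0.0, 0.1) == 4.0

    def test_unit_correlation_equals_superior_progeny(self):
        assert predict_correlated_response(4.0, 2.0, 1.0, 0.1) == \
            pytest.approx(predict_superior_progeny(4.0, 4.0, 0.1, "high"))

    def test_spec_example(self):
        out = predict_correlated_response(10.0, 2.0, -0.5, 0.1)
        assert out == pytest.approx(10.0 - 1.7550, abs=1e-3)


class TestOracles:
    def test_enumeration_matches_analytic_exactly(self):
        rng = np.random.default_rng(10)
        gmap = GeneticMap.uniform(3, 4, 60.0)
        for _ in range(10):
            cross, (u1, u2) = _random_cross(gmap, rng, n_traits=2)
            mean, cov = enumerate_cross_oracle(cross, [u1, u2], gmap)
            assert mean[0] == pytest.approx(predict_cross_mean(cross, u1),
                                            abs=1e-10)
            assert cov[0, 0] == pytest.approx(
                predict_cross_variance(cross, u1, gmap), abs=1e-10)
            c, _ = predict_cross_covariance(cross, u1, u2, gmap)
            assert cov[0, 1] == pytest.approx(c, abs=1e-10)

    def test_enumeration_limit_enforced(self):
        gmap = GeneticMap.uniform(1, 9, 80.0)
        cross = CrossSpec.from_parents("a", np.ones(9), "b", -np.ones(9))
        with pytest.raises(ValueError, match="enumeration limit"):
            enumerate_cross_oracle(cross, [np.ones(9)], gmap,
                                   max_loci_per_chrom=6)

    def test_mc_oracle_zero_effects(self):
        gmap = GeneticMap.uniform(2, 5, 50.0)
        cross = CrossSpec.from_parents("a", np.ones(10), "b", -np.ones(10))
        mean, var, _ = simulate_cross_oracle(
            cross, [np.zeros(10)], gmap, 100, None, np.random.default_rng(0))
        assert np.allclose(mean, 0.0) and np.allclose(var, 0.0)

    def test_mc_oracle_seeded_reproducible(self):
        gmap = GeneticMap.uniform(2, 5, 50.0)
        rng = np.random.default_rng(11)
        cross, (u,) = _random_cross(gmap, rng)
        r1 = simulate_cross_oracle(cross, [u], gmap, 500, 4,
                                   np.random.default_rng(42))
        r2 = simulate_cross_oracle(cross, [u], gmap, 500, 4,
                                   np.random.default_rng(42))
        assert np.array_equal(r1[0], r2[0]) and np.array_equal(r1[1], r2[1])

    def test_mc_oracle_needs_two_progeny(self):
        gmap = _map_one_chrom([0.0])
        cross = CrossSpec.from_parents("a", np.array([1.0]), "b",
                                       np.array([-1.0]))
        with pytest.raises(ValueError, match="n_progeny"):
            simulate_cross_oracle(cross, [np.ones(1)], gmap, 1, None,
                                  np.random.default_rng(0))


class TestCrossSpec:
    def test_strict_mode_rejects_het_parent(self):
        with pytest.raises(ValueError, match="heterozygous"):
            CrossSpec.from_parents("a", np.array([0.0, 1.0]), "b",
                                   np.array([1.0, 1.0]))

    def test_lenient_mode_drops_loci(self):
        spec = CrossSpec.from_parents("a", np.array([0.0, 1.0, np.nan]),
                                      "b", np.array([1.0, -1.0, 1.0]),
                                      strict=False)
        assert spec.n_dropped == 2
        assert spec.n_segregating == 1
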