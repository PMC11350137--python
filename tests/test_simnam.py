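import numpy as np
import pandas as pd
import pytest

from crossgain.gmap import GeneticMap
from crossgain.simnam import (
    HaplotypePair,
    SimConfig,
    TraitArchitecture,
    assign_qtl_effects,
    genetic_values,
    make_gamete,
    simulate_family,
    simulate_nam,
    true_family_params,
)


def _two_marker_map(dist_cm):
    return GeneticMap(np.array(["m1", "m2"], object), np.array([1, 1]),
                      np.array([0.0, dist_cm]))


class TestMakeGamete:
    def test_zero_length_map_returns_parental(self):
        gmap = GeneticMap(np.array(["m1"], object), np.array([1]), np.array([0.0]))
        parent = HaplotypePair(np.array([0]), np.array([1]))
        rng = np.random.default_rng(0)
        picks = [int(make_gamete(parent, gmap, rng)[0]) for _ in range(2000)]
        frac = np.mean(picks)
        assert 0.45 < frac < 0.55  # fair coin, 3 binomial SE ~ 0.033

    def test_zero_distance_never_recombines(self):
        gmap = _two_marker_map(0.0)
        parent = HaplotypePair(np.array([0, 0]), np.array([1, 1]))
        rng = np.random.default_rng(1)
        for _ in range(500):
            g = make_gamete(parent, gmap, rng)
            assert g[0] == g[1]

    def test_50cm_recombinant_fraction_matches_haldane(self):
        # binomial oracle: expected c = 0.5 (1 - e^-1) ~ 0.3161
        n = 100_000
        gmap = _two_marker_map(50.0)
        parent = HaplotypePair(np.array([0, 0]), np.array([1, 1]))
        rng = np.random.default_rng(2)
        from crossgain.simnam import _batch_gametes
        H1 = np.zeros((n, 2), np.uint8)
        H2 = np.ones((n, 2), np.uint8)
        g = _batch_gametes(H1, H2, gmap.interval_recomb(), rng)
        rec = np.mean(g[:, 0] != g[:, 1])
        expected = 0.5 * (1 - np.exp(-1.0))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec - expected) < 3 * se

    def test_length_mismatch_raises(self):
        gmap = _two_marker_map(10.0)
        parent = HaplotypePair(np.array([0]), np.array([1]))
        with pytest.raises(ValueError):
            make_gamete(parent, gmap, np.random.default_rng(0))


class TestSimulateFamily:
    def test_identical_parents_give_identical_rils(self):
        gmap = GeneticMap.uniform(2, 5, 50.0)
        p = HaplotypePair.inbred(np.random.default_rng(0).integers(0, 2, 10))
        fam = simulate_family(p, p, 20, 4, gmap, np.random.default_rng(3))
        assert np.all(fam.dosages == p.dosage()[None, :])
        assert fam.dosages.std(axis=0).max() == 0.0

    @pytest.mark.parametrize("gens", [1, 3, 5])
    def test_heterozygosity_halves_per_selfing_round(self, gens):
        gmap = GeneticMap.uniform(1, 8, 70.0)
        p1 = HaplotypePair.inbred(np.zeros(8, int))
        p2 = HaplotypePair.inbred(np.ones(8, int))
        fam = simulate_family(p1, p2, 3000, gens, gmap,
                              np.random.default_rng(4))
        het = np.mean(fam.dosages == 0)
        expected = 0.5 ** gens
        se = np.sqrt(expected * (1 - expected) / (3000 * 8))
        assert abs(het - expected) < 4 * se

    def test_two_locus_f_inf_correlation_haldane_waddington(self):
        # Monte-Carlo vs D = (1-2c)/(1+2c); c=0.25 -> distance from inverse
        c = 0.25
        d_cm = -50.0 * np.log(1 - 2 * c)
        gmap = _two_marker_map(d_cm)
        p1 = HaplotypePair.inbred(np.array([0, 0]))
        p2 = HaplotypePair.inbred(np.array([1, 1]))
        n = 40_000
        fam = simulate_family(p1, p2, n, None, gmap, np.random.default_rng(5))
        r = np.corrcoef(fam.dosages[:, 0], fam.dosages[:, 1])[0, 1]
        # SE of a correlation estimate ~ (1 - rho^2)/sqrt(n)
        se = (1 - (1 / 3) ** 2) / np.sqrt(n)
        assert abs(r - 1.0 / 3.0) < 3 * se

    def test_heterozygous_parent_rejected_in_strict_mode(self):
        gmap = _two_marker_map(10.0)
        het = HaplotypePair(np.array([0, 1]), np.array([1, 1]))
        hom = HaplotypePair.inbred(np.array([0, 0]))
        with pytest.raises(ValueError, match="heterozygous"):
            simulate_family(het, hom, 5, 2, gmap, np.random.default_rng(0))


class TestAssignQtlEffects:
    def test_diagonal_covariance_gives_uncorrelated_effects(self):
        gmap = GeneticMap.uniform(5, 100, 100.0)
        arch = assign_qtl_effects(gmap, 300, np.eye(2),
                                  np.random.default_rng(6))
        r = np.corrcoef(arch.effect_matrix.T)[0, 1]
        assert abs(r) < 3 / np.sqrt(300)

    def test_unit_correlation_gives_proportional_effects(self):
        gmap = GeneticMap.uniform(2, 30, 100.0)
        cov = np.array([[1.0, 2.0], [2.0, 4.0]])  # correlation exactly 1
        arch = assign_qtl_effects(gmap, 20, cov, np.random.default_rng(7))
        ratio = arch.effect_matrix[:, 1] / arch.effect_matrix[:, 0]
        assert np.allclose(ratio, 2.0, atol=1e-8)

    def test_target_correlation_recovered(self):
        gmap = GeneticMap.uniform(5, 100, 100.0)
        cov = np.array([[1.0, 0.7], [0.7, 1.0]])
        arch = assign_qtl_effects(gmap, 200, cov, np.random.default_rng(8))
        r = np.corrcoef(arch.effect_matrix.T)[0, 1]
        assert abs(r - 0.7) < 3 / np.sqrt(200)

    def test_non_psd_covariance_rejected(self):
        gmap = GeneticMap.uniform(1, 10, 50.0)
        with pytest.raises(ValueError, match="semi-definite"):
            assign_qtl_effects(gmap, 5, np.array([[1.0, 2.0], [2.0, 1.0]]),
                               np.random.default_rng(0))

    def test_too_many_qtl_rejected(self):
        gmap = GeneticMap.uniform(1, 10, 50.0)
        with pytest.raises(ValueError, match="exceeds"):
            assign_qtl_effects(gmap, 11, np.eye(1), np.random.default_rng(0))

    def test_reproducible_from_seed(self):
        gmap = GeneticMap.uniform(2, 20, 80.0)
        a1 = assign_qtl_effects(gmap, 10, np.eye(2), np.random.default_rng(9))
        a2 = assign_qtl_effects(gmap, 10, np.eye(2), np.random.default_rng(9))
        assert np.array_equal(a1.qtl_indices, a2.qtl_indices)
        assert np.array_equal(a1.effect_matrix, a2.effect_matrix)


class TestSimulatePhenotypes:
    def _setup(self, h2, env_var=0.0, seed=10):
        cfg = SimConfig(n_founders=2, n_families=2, ril_per_family=30,
                        n_chromosomes=2, markers_per_chromosome=8,
                        chromosome_length_cM=60, n_qtl=10,
                        heritability=(h2,), env_variance=env_var,
                        n_environments=2, rng_seed=seed)
        ds = simulate_nam(cfg)
        return cfg, ds

    def test_h2_one_no_env_gives_pure_genetic_values(self):
        cfg, ds = self._setup(1.0, env_var=0.0)
        g = genetic_values(ds.genotypes, ds.arch, cfg.intercepts)
        ph = ds.phenotypes
        for (lid, trait), grp in ph.groupby(["line_id", "trait"]):
            i = list(ds.genotypes.line_ids).index(lid)
            t = cfg.trait_names.index(trait)
            assert np.allclose(grp["value"], g[i, t], atol=1e-10)

    def test_same_seed_identical_tables(self):
        _, ds1 = self._setup(0.6, 1.0, seed=11)
        _, ds2 = self._setup(0.6, 1.0, seed=11)
        pd.testing.assert_frame_equal(ds1.phenotypes, ds2.phenotypes)

    def test_residual_variance_calibration(self):
        # realized residual var should match sigma_g^2 (1-h2)/h2
        cfg, ds = self._setup(0.5, env_var=0.0, seed=12)
        g = genetic_values(ds.genotypes, ds.arch, cfg.intercepts)
        var_g = g.var(ddof=1)
        ph = ds.phenotypes
        line_idx = {l: i for i, l in enumerate(ds.genotypes.line_ids)}
        resid = ph["value"].to_numpy() - np.array(
            [g[line_idx[l], 0] for l in ph["line_id"]])
        # residual includes env effect (0 variance here); compare moments
        expected = var_g * (1 - 0.5) / 0.5
        assert resid.var(ddof=1) == pytest.approx(expected, rel=0.2)

    def test_zero_heritability_rejected(self):
        with pytest.raises(ValueError, match="heritability"):
            SimConfig(heritability=(0.0,))


class TestTrueFamilyParams:
    def test_monomorphic_family(self):
        gmap = GeneticMap.uniform(1, 4, 30.0)
        from crossgain.genotypes import GenotypeMatrix
        dos = np.ones((5, 4))
        geno = GenotypeMatrix(np.array([f"l{i}" for i in range(5)], object),
                              gmap.marker_id, dos)
        arch = TraitArchitecture(np.array([0, 2]), np.array([[1.0], [2.0]]),
                                 np.eye(1))
        truth = true_family_params(geno, ["f"] * 5, arch)
        assert truth.variance[0, 0] == 0.0
        assert truth.musp[0, 0] == truth.mean[0, 0]

    def test_duplicated_trait_has_unit_correlation(self):
        gmap = GeneticMap.uniform(1, 6, 50.0)
        from crossgain.genotypes import GenotypeMatrix
        rng = np.random.default_rng(13)
        dos = rng.choice([-1.0, 1.0], size=(20, 6))
        geno = GenotypeMatrix(np.array([f"l{i}" for i in range(20)], object),
                              gmap.marker_id, dos)
        eff = rng.normal(size=(3, 1))
        arch = TraitArchitecture(np.array([0, 2, 4]),
                                 np.hstack([eff, eff]), np.eye(2))
        truth = true_family_params(geno, ["f"] * 20, arch)
        assert truth.rg[0, 0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_two_locus_exhaustive_enumeration(self):
        # 4 genotypes, printed effects: values enumerated by hand
        gmap = GeneticMap.uniform(1, 2, 10.0)
        from crossgain.genotypes import GenotypeMatrix
        dos = np.array([[-1.0, -1.0], [-1.0, 1.0], [1.0, -1.0], [1.0, 1.0]])
        geno = GenotypeMatrix(np.array(list("abcd"), object),
                              gmap.marker_id, dos)
        arch = TraitArchitecture(np.array([0, 1]), np.array([[2.0], [3.0]]),
                                 np.eye(1))
        truth = true_family_params(geno, ["f"] * 4, arch, p=0.25)
        vals = np.array([-5.0, 1.0, -1.0, 5.0])
        assert truth.mean[0, 0] == pytest.approx(vals.mean())
        assert truth.variance[0, 0] == pytest.approx(vals.var(ddof=1))
        assert truth.musp[0, 0] == pytest.approx(5.0)  # top 25% = best single

    def test_family_of_one_rejected(self):
        gmap = GeneticMap.uniform(1, 2, 10.0)
        from crossgain.genotypes import GenotypeMatrix
        geno = GenotypeMatrix(np.array(["a", "b"], object), gmap.marker_id,
                              np.array([[1.0, 1.0], [-1.0, 1.0]]))
        arch = TraitArchitecture(np.array([0]), np.array([[1.0]]), np.eye(1))
        with pytest.raises(ValueError, match="fewer than 2"):
            true_family_params(geno, ["f1", "f2"], arch)


class TestSimulateNam:
    def test_reproducible_bundle(self):
        cfg = SimConfig(n_founders=3, n_families=3, ril_per_family=10,
                        n_chromosomes=2, markers_per_chromosome=6,
                        n_qtl=8, heritability=(0.7,), rng_seed=21)
        d1, d2 = simulate_nam(cfg), simulate_nam(cfg)
        assert np.array_equal(d1.genotypes.dosages, d2.genotypes.dosages)
        pd.testing.assert_frame_equal(d1.phenotypes, d2.phenotypes)
        assert np.array_equal(d1.truth.variance, d2.truth.variance)

    def test_segregating_locus_mean_near_zero(self, tiny_nam):
        ds = tiny_nam
        fam = ds.families == ds.truth.families[0]
        dos = ds.genotypes.dosages[fam]
        seg = dos.std(axis=0) > 0
        n = fam.sum()
        # no selection: segregating-locus dosage mean ~ 0, SE = 1/sqrt(n)
        means = dos[:, seg].mean(axis=0)
        z = means / (1.0 / np.sqrt(n))
        assert np.mean(np.abs(z) < 3) > 0.97

    def test_genetic_variance_matches_analytic_predictor(self):
        # large family at F-infinity vs crosspred formula with true effects
        from crossgain.crosspred import CrossSpec, predict_cross_variance
        cfg = SimConfig(n_founders=1, n_families=1, ril_per_family=5000,
                        n_chromosomes=3, markers_per_chromosome=10,
                        chromosome_length_cM=90, n_qtl=15,
                        heritability=(0.9,), rng_seed=22)
        ds = simulate_nam(cfg)
        eff = ds.arch.effects_full(ds.gmap.n_markers)[:, 0]
        p1 = ds.parents.row("HUB")
        p2 = ds.parents.row("P01")
        cross = CrossSpec.from_parents("HUB", p1, "P01", p2)
        analytic = predict_cross_variance(cross, eff, ds.gmap)
        empirical = ds.truth.variance[0, 0]
        se = analytic * np.sqrt(2.0 / (5000 - 1))  # variance-of-variance scale
        assert abs(empirical - analytic) < 3 * se
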