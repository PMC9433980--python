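import numpy as np
import pytest
from scipy.stats import multivariate_normal

from plastinet.ar1 import AR1Covariance, ar1_quadform, profile_ar1_mle
from plastinet.cofunmap import (
    GroupModel,
    effect_curve,
    fit_null,
    loglik,
    permutation_threshold,
    scan,
)
from plastinet.curves import LogisticParams, logistic_eval
from plastinet.datamodel import GenotypeTable, PlasticitySet, TimeGrid, compute_plasticity
from plastinet.synthdata import QtlSpec, SimConfig, simulate_population


class TestAR1:
    def test_quadform_matches_dense_inverse(self):
        rng = np.random.default_rng(0)
        for rho in (-0.7, 0.0, 0.3, 0.9):
            cov = AR1Covariance(1.0, rho)
            T = 6
            R = cov.matrix(T)
            E = rng.normal(size=(4, T))
            direct = np.einsum("bi,ij,bj->b", E, np.linalg.inv(R), E)
            np.testing.assert_allclose(ar1_quadform(E, rho), direct, rtol=1e-10)

    def test_logdet_matches_dense(self):
        cov = AR1Covariance(2.5, 0.6)
        sign, logdet = np.linalg.slogdet(cov.matrix(7))
        assert sign > 0
        assert cov.logdet(7) == pytest.approx(logdet)

    def test_mle_recovers_parameters(self):
        from plastinet.synthdata import _ar1_noise

        rng = np.random.default_rng(3)
        E = _ar1_noise(rng, (4000, 6), 2.0, 0.5)
        est = profile_ar1_mle(E)
        assert est.sigma2 == pytest.approx(2.0, rel=0.05)
        assert est.rho == pytest.approx(0.5, abs=0.03)


class TestLoglik:
    def _small_instance(self, rho):
        rng = np.random.default_rng(7)
        grid = TimeGrid([1.0, 2.0, 3.0, 4.0])
        z = PlasticitySet(ids=[f"g{i}" for i in range(5)], grid=grid,
                          z=rng.normal(2.0, 1.0, size=(5, 4)))
        model = GroupModel(
            groups={0: (0.6, LogisticParams(3.0, 2.0, 0.5)),
                    1: (0.4, LogisticParams(5.0, 1.0, 0.3))},
            covariance=AR1Covariance(1.3, rho),
        )
        assignment = np.array([0, 1, 0, 1, 0])
        return model, z, assignment, grid

    @pytest.mark.parametrize("rho", [0.0, 0.45, -0.3])
    def test_matches_dense_multivariate_normal_oracle(self, rho):
        model, z, assignment, grid = self._small_instance(rho)
        got = loglik(model, z, assignment)
        Sigma = model.covariance.matrix(len(grid))
        want = 0.0
        for i, code in enumerate(assignment):
            mu = logistic_eval(model.groups[int(code)][1], grid.times)
            want += multivariate_normal.logpdf(z.z[i], mean=mu, cov=Sigma)
        assert got == pytest.approx(want, abs=1e-10)

    def test_rho_zero_equals_independent_normals(self):
        from scipy.stats import norm

        model, z, assignment, grid = self._small_instance(0.0)
        got = loglik(model, z, assignment)
        sd = np.sqrt(model.covariance.sigma2)
        want = 0.0
        for i, code in enumerate(assignment):
            mu = logistic_eval(model.groups[int(code)][1], grid.times)
            want += norm.logpdf(z.z[i], loc=mu, scale=sd).sum()
        assert got == pytest.approx(want, abs=1e-10)


class TestFitNull:
    @pytest.mark.parametrize("n", [50, 100, 400])
    def test_parameter_recovery_improves_with_n(self, n):
        cfg = SimConfig(n=n, m=5, seed=n)
        traj, _, _ = simulate_population(cfg)
        z = compute_plasticity(traj)
        null = fit_null(z)
        params = next(iter(null.groups.values()))[1]
        # true plasticity mean curve: (a_c - a_s) shape = 9 * logistic shape
        assert params.a == pytest.approx(9.0, rel=0.35 if n == 50 else 0.2)
        assert null.covariance.sigma2 == pytest.approx(2.0, rel=0.35)
        assert null.covariance.rho == pytest.approx(0.5, abs=0.15)

    def test_null_loglik_never_exceeds_full(self, plasticity_null, null_population):
        _, geno, _ = null_population
        null = fit_null(plasticity_null)
        result = scan(plasticity_null, geno, null=null)
        assert np.all(result.lr[~result.skipped] >= 0)

    def test_degenerate_constant_data_flagged(self):
        grid = TimeGrid([1.0, 2.0, 3.0, 4.0])
        z = PlasticitySet(ids=[f"g{i}" for i in range(10)], grid=grid,
                          z=np.tile([1.0, 2.0, 3.0, 3.5], (10, 1)))
        assert fit_null(z).flagged


class TestScan:
    def test_duplicated_snp_gives_identical_lr(self, plasticity_null, null_population):
        _, geno, _ = null_population
        dup = GenotypeTable(
            snp_ids=["a", "b"],
            individual_ids=geno.individual_ids,
            codes=np.vstack([geno.codes[0], geno.codes[0]]),
            marker_class=["gwas_biallelic"] * 2,
        )
        result = scan(plasticity_null, dup)
        assert result.lr[0] == pytest.approx(result.lr[1], rel=1e-12)

    def test_group_relabelling_leaves_lr_unchanged(self, plasticity_null,
                                                   null_population):
        _, geno, _ = null_population
        flipped = GenotypeTable(
            snp_ids=list(geno.snp_ids),
            individual_ids=geno.individual_ids,
            codes=(2 - geno.codes).astype(np.int16),
            marker_class=list(geno.marker_class),
        )
        a = scan(plasticity_null, geno)
        b = scan(plasticity_null, flipped)
        keep = ~(a.skipped | b.skipped)
        np.testing.assert_allclose(a.lr[keep], b.lr[keep], rtol=1e-6, atol=1e-6)

    def test_undersized_groups_are_skipped(self, plasticity_null, null_population):
        _, geno, _ = null_population
        rare = np.zeros(plasticity_null.n, dtype=np.int16)
        rare[:2] = 1  # only two carriers: below the group-size floor
        g = GenotypeTable(snp_ids=["rare"], individual_ids=geno.individual_ids,
                          codes=rare[None, :], marker_class=["gwas_biallelic"])
        result = scan(plasticity_null, g, min_group=5)
        assert result.skipped[0]

    def test_planted_qtl_scores_far_above_background(self, qtl_population):
        traj, geno, _ = qtl_population
        z = compute_plasticity(traj)
        result = scan(z, geno)
        assert result.lr[7] > 3 * np.delete(result.lr, 7).max()

    def test_separation_monotonicity_of_median_lr(self):
        medians = []
        for shift in (0.0, 1.0, 2.0):
            lrs = []
            for rep in range(3):
                cfg = SimConfig(n=100, m=10, seed=100 + rep,
                                qtls=[QtlSpec(snp_index=0, stress_shift=shift)])
                traj, geno, _ = simulate_population(cfg)
                z = compute_plasticity(traj)
                lrs.append(scan(z, geno).lr[0])
            medians.append(np.median(lrs))
        assert medians[0] <= medians[1] <= medians[2]


class TestPermutationThreshold:
    def test_deterministic_under_seed(self, plasticity_null, null_population):
        _, geno, _ = null_population
        a = permutation_threshold(plasticity_null, geno, 100, 0.05,
                                  "gwas_biallelic", seed=9)
        b = permutation_threshold(plasticity_null, geno, 100, 0.05,
                                  "gwas_biallelic", seed=9)
        assert a == b

    def test_alpha_one_returns_minimum_of_maxima(self, plasticity_null,
                                                 null_population):
        _, geno, _ = null_population
        thr = permutation_threshold(plasticity_null, geno, 100, 1.0,
                                    "gwas_biallelic", seed=9)
        thr05 = permutation_threshold(plasticity_null, geno, 100, 0.05,
                                      "gwas_biallelic", seed=9)
        assert thr <= thr05

    def test_too_few_permutations_rejected(self, plasticity_null, null_population):
        _, geno, _ = null_population
        with pytest.raises(ValueError):
            permutation_threshold(plasticity_null, geno, 50, 0.05,
                                  "gwas_biallelic", seed=0)


class TestEffectCurve:
    def test_two_balanced_groups_give_half_gap(self):
        grid = TimeGrid(np.arange(20.0, 121.0, 20.0))
        mu, d = LogisticParams(10, 5, 0.05), 1.5
        model = GroupModel(
            groups={0: (0.5, LogisticParams(10 + 0, 5, 0.05)),
                    1: (0.5, LogisticParams(10, 5, 0.05))},
            covariance=AR1Covariance(1.0, 0.0),
        )
        # groups mu +/- d(t): use two asymptote-shifted curves
        model.groups[0] = (0.5, LogisticParams(10 + 2 * d, 5, 0.05))
        ec = effect_curve(model, grid)
        gap = logistic_eval(LogisticParams(2 * d, 5, 0.05), grid.times)
        np.testing.assert_allclose(ec.values, np.abs(gap) / 2, atol=1e-10)

    def test_identical_groups_give_zero_curve(self):
        grid = TimeGrid(np.arange(20.0, 121.0, 20.0))
        p = LogisticParams(10, 5, 0.05)
        model = GroupModel(groups={0: (0.4, p), 1: (0.6, p)},
                           covariance=AR1Covariance(1.0, 0.0))
        ec = effect_curve(model, grid)
        np.testing.assert_allclose(ec.values, 0, atol=1e-12)

    def test_three_groups_match_weighted_variance_oracle(self):
        grid = TimeGrid(np.arange(20.0, 121.0, 20.0))
        ps = [0.25, 0.5, 0.25]
        params = [LogisticParams(8, 4, 0.06), LogisticParams(11, 6, 0.05),
                  LogisticParams(14, 3, 0.07)]
        model = GroupModel(
            groups={j: (ps[j], params[j]) for j in range(3)},
            covariance=AR1Covariance(1.0, 0.0),
        )
        ec = effect_curve(model, grid)
        # brute-force weighted standard deviation at every grid time
        for k, t in enumerate(grid.times):
            mus = [logistic_eval(p, t) for p in params]
            mbar = sum(w * m for w, m in zip(ps, mus))
            want = np.sqrt(sum(w * (m - mbar) ** 2 for w, m in zip(ps, mus)))
            assert ec.values[k] == pytest.approx(want, abs=1e-10)

    def test_single_group_returns_flagged_zero_curve(self):
        grid = TimeGrid(np.arange(20.0, 121.0, 20.0))
        model = GroupModel(groups={0: (1.0, LogisticParams(10, 5, 0.05))},
                           covariance=AR1Covariance(1.0, 0.0))
        ec = effect_curve(model, grid)
        assert ec.flagged and np.all(ec.values == 0)

    def test_scale_equivariance(self, qtl_population):
        traj, geno, _ = qtl_population
        z = compute_plasticity(traj)
        c = 2.5
        z_scaled = PlasticitySet(ids=z.ids, grid=z.grid, z=c * z.z)
        ec1 = effect_curve(scan(z, geno).group_models[7], z.grid)
        ec2 = effect_curve(scan(z_scaled, geno).group_models[7], z.grid)
        np.testing.assert_allclose(ec2.values, c * ec1.values, rtol=5e-2)
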