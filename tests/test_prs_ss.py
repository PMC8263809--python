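import numpy as np
import pytest

import prstools as pt
from prstools import megaprs
from prstools.megaprs import bayesr_triplets


class TestPseudoSumstats:
    def test_sum_identity_holds_exactly(self, toy_sim):
        ss, G = toy_sim["ss"], toy_sim["G"]
        ps = pt.make_pseudo_sumstats(ss, G, frac=0.9, seed=1)
        lhs = ps.train.n * ps.train.r + ps.test.n * ps.test.r
        np.testing.assert_allclose(lhs, ss.n * ss.r, atol=1e-10)
        assert ps.n_a == round(0.9 * ss.n[0])
        assert ps.n_a + ps.n_b == ss.n[0]

    def test_zero_noise_limit_reproduces_full_statistics(self, toy_sim,
                                                         monkeypatch):
        """With the Gaussian draw forced to zero, both pseudo sets equal
        the full statistics (as correlations)."""
        ss, G = toy_sim["ss"], toy_sim["G"]

        class ZeroRng:
            def standard_normal(self, size):
                return np.zeros(size)

        monkeypatch.setattr(megaprs.np.random, "default_rng",
                            lambda seed: ZeroRng())
        ps = pt.make_pseudo_sumstats(ss, G, frac=0.9, seed=0)
        np.testing.assert_allclose(ps.train.r, ss.r, atol=1e-12)
        np.testing.assert_allclose(ps.test.r, ss.r, atol=1e-12)

    def test_training_noise_covariance_matches_reference_ld(self):
        """Monte Carlo: Cov(X_A^T Y_A / n_A) = (n_B / (n_A n)) C with C the
        reference-panel correlation matrix."""
        rng = np.random.default_rng(5)
        n_ref, m, n = 400, 5, 50_000
        base = rng.standard_normal((n_ref, 1))
        X = 0.6 * base + 0.8 * rng.standard_normal((n_ref, m))
        G = pt.GenotypeMatrix(X)
        Xs = G.standardized()
        C = Xs.T @ Xs / n_ref
        r = np.full(m, 0.01)
        ss = pt.SummaryStats.from_r(
            [f"rs{j}" for j in range(m)], ["A"] * m, ["G"] * m,
            np.full(m, n), r,
        )
        draws = np.empty((10_000, m))
        for it in range(10_000):
            ps = pt.make_pseudo_sumstats(ss, G, frac=0.9, seed=1000 + it)
            draws[it] = ps.train.r
        emp = np.cov(draws.T)
        n_a = round(0.9 * n)
        n_b = n - n_a
        target = (n_b / (n_a * n)) * C
        np.testing.assert_allclose(emp, target, rtol=0.05, atol=5e-9)

    def test_varying_sample_sizes_rejected(self, toy_sim):
        ss = toy_sim["ss"]
        bad = pt.SummaryStats.from_r(
            ss.snp_id, ss.allele1, ss.allele2,
            np.arange(100, 100 + ss.m), ss.r,
        )
        with pytest.raises(ValueError, match="single sample size"):
            pt.make_pseudo_sumstats(bad, toy_sim["G"], seed=0)


class TestSolveWindows:
    def test_single_snp_ridge_closed_form(self):
        """r = 0.1, n = 100, prior variance 0.01:
        beta = n r / (n + 1/0.01) = 0.05."""
        ss = pt.SummaryStats.from_r(["rs1"], ["A"], ["G"], [100], [0.1])
        panel = pt.SnpPanel(["rs1"], [1], [100], [0.0], ["A"], ["G"], [0.3])
        from prstools.ld import _from_upper_pairs
        e = np.empty(0)
        store = _from_upper_pairs(1, 100, 3.0, 0.01, e.astype(np.int32),
                                  e.astype(np.int32), e)
        beta, diag = pt.solve_windows(ss, store, panel,
                                      pt.PriorSpec.ridge(), np.array([0.01]))
        assert beta[0] == pytest.approx(0.05, rel=1e-10)
        assert diag["window_resets"] == 0

    def test_zero_statistics_give_zero_effects(self, toy_sim):
        panel, store = toy_sim["panel"], toy_sim["store"]
        ss = pt.SummaryStats.from_r(
            panel.snp_id, panel.allele1, panel.allele2,
            np.full(panel.m, 1000), np.zeros(panel.m),
        )
        beta, _ = pt.solve_windows(ss, store, panel, pt.PriorSpec.ridge(),
                                   np.full(panel.m, 1e-3))
        np.testing.assert_array_equal(beta, 0.0)

    def test_dense_ld_ridge_matches_direct_linear_solve(self):
        """With dense exact LD stored, the window fixed point solves
        (n C + diag(1/prior var)) beta = n r."""
        cfg = pt.SimConfig(n=500, m=30, rho=0.6, length_cm=0.2, seed=21)
        panel, G = pt.simulate_genotypes(cfg)
        eff = pt.simulate_effects(panel, np.ones(30), pt.PriorSpec.ridge(),
                                  0.3, seed=22)
        y = pt.simulate_phenotype(G, eff, seed=23)
        ss = pt.gwas_linear(G, y, panel)
        store = pt.compute_ld_pairs(G, panel, window_cm=3.0,
                                    p_threshold=1 - 1e-12)
        e_j = np.full(30, 0.01)
        beta, _ = pt.solve_windows(ss, store, panel, pt.PriorSpec.ridge(),
                                   e_j, tol=1e-12, max_iter=500)
        n = G.n
        direct = np.linalg.solve(
            n * store.dense() + np.diag(1.0 / e_j), n * ss.r
        )
        np.testing.assert_allclose(beta, direct, atol=1e-6)

    def test_matches_individual_level_fixed_point(self):
        """Summary-statistic and individual-level conditional updates agree
        on a small dense-LD problem with matched priors and noise."""
        cfg = pt.SimConfig(n=800, m=40, rho=0.5, length_cm=0.3, seed=31)
        panel, G = pt.simulate_genotypes(cfg)
        eff = pt.simulate_effects(panel, np.ones(40),
                                  pt.PriorSpec.bayesr(0.1, 0.05, 0.01),
                                  0.3, seed=32)
        y = pt.simulate_phenotype(G, eff, seed=33)
        ss = pt.gwas_linear(G, y, panel)
        store = pt.compute_ld_pairs(G, panel, window_cm=3.0,
                                    p_threshold=1 - 1e-12)
        e_j = np.full(40, 0.3 / 40)
        for spec in (pt.PriorSpec.ridge(), pt.PriorSpec.bolt(0.1, 0.3),
                     pt.PriorSpec.bayesr(0.1, 0.05, 0.01)):
            beta_ss, _ = pt.solve_windows(ss, store, panel, spec, e_j,
                                          tol=1e-10, max_iter=300)
            fit = pt.vb_fit_individual(G, y, e_j, spec, sigma2_e=1.0,
                                       tol=1e-10, max_iter=300)
            np.testing.assert_allclose(beta_ss, fit.beta, atol=1e-4)


class TestGrids:
    def test_bolt_grid_has_eighteen_pairs(self):
        assert len(pt.default_grid("bolt")) == 18

    def test_bayesr_grid_has_thirty_five_configurations(self):
        grid = pt.default_grid("bayesr")
        assert len(grid) == 35
        assert grid[0].pis == (0.0, 0.0, 0.0, 1.0)
        for spec in grid[1:]:
            _, p2, p3, p4 = spec.pis
            assert p4 <= p3 <= p2
            assert p2 + p3 + p4 > 0

    def test_unrestricted_triplets_number_125(self):
        assert len(bayesr_triplets(ordered=False)) == 125

    def test_scale_grids_have_eleven_settings(self):
        assert len(pt.default_grid("ridge")) == 11
        assert len(pt.default_grid("lasso")) == 11

    def test_unknown_tool_rejected(self):
        with pytest.raises(ValueError):
            pt.default_grid("mcmc")


class TestScoring:
    def test_scaling_beta_leaves_r_unchanged(self, toy_sim):
        ss, store = toy_sim["ss"], toy_sim["store"]
        rng = np.random.default_rng(7)
        beta = rng.standard_normal(ss.m) * 0.01
        r1 = pt.score_pseudo_R(beta, ss, store).r
        r2 = pt.score_pseudo_R(2 * beta, ss, store).r
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_model_scores_minus_infinity(self, toy_sim):
        score = pt.score_pseudo_R(np.zeros(toy_sim["ss"].m), toy_sim["ss"],
                                  toy_sim["store"])
        assert score.r == -np.inf

    def test_true_effects_score_near_sqrt_h2(self, toy_sim):
        """Scoring the generative effects against the GWAS statistics
        estimates corr(Y, X beta) ~ sqrt(h2)."""
        score = pt.score_pseudo_R(toy_sim["effects"].beta, toy_sim["ss"],
                                  toy_sim["store"])
        assert score.r == pytest.approx(np.sqrt(0.5), abs=0.12)

    def test_permuted_effects_score_near_zero(self, toy_sim):
        rng = np.random.default_rng(8)
        rs = [
            pt.score_pseudo_R(rng.permutation(toy_sim["effects"].beta),
                              toy_sim["ss"], toy_sim["store"]).r
            for _ in range(30)
        ]
        assert abs(np.mean(rs)) < 0.15

    def test_excluded_regions_are_zeroed(self, toy_sim):
        panel, ss, store = toy_sim["panel"], toy_sim["ss"], toy_sim["store"]
        beta = np.zeros(ss.m)
        beta[:10] = 0.1
        region = [(1, int(panel.bp_position[0]), int(panel.bp_position[9]))]
        score = pt.score_pseudo_R(beta, ss, store, panel=panel,
                                  exclude_regions=region)
        assert score.r == -np.inf  # everything nonzero was excluded


class TestRunMegaprs:
    @pytest.fixture(scope="class")
    def small_inputs(self):
        cfg = pt.SimConfig(n=2400, m=300, h2=0.5, rho=0.6, seed=41)
        panel, G = pt.simulate_genotypes(cfg)
        eff = pt.simulate_effects(panel, np.ones(300), pt.PriorSpec.ridge(),
                                  0.5, seed=42)
        G_train = pt.GenotypeMatrix(G.dosages[:1600], snp_ids=panel.snp_id)
        G_a = pt.GenotypeMatrix(G.dosages[1600:2000], snp_ids=panel.snp_id)
        G_c = pt.GenotypeMatrix(G.dosages[2000:], snp_ids=panel.snp_id)
        y = pt.simulate_phenotype(G_train, eff, seed=43)
        ss = pt.gwas_linear(G_train, y, panel)
        return panel, ss, G_a, G_c

    def test_same_seed_gives_identical_model(self, small_inputs):
        panel, ss, G_a, G_c = small_inputs
        m1 = pt.run_megaprs(ss, G_a, G_c, panel, "ridge", seed=5)
        m2 = pt.run_megaprs(ss, G_a, G_c, panel, "ridge", seed=5)
        np.testing.assert_array_equal(m1.beta, m2.beta)
        assert m1.prior == m2.prior

    def test_single_candidate_equals_direct_solve(self, small_inputs):
        panel, ss, G_a, G_c = small_inputs
        spec = pt.PriorSpec.ridge(0.5)
        cfg = pt.MegaConfig(grid=[spec])
        model = pt.run_megaprs(ss, G_a, G_c, panel, "ridge", config=cfg,
                               seed=5)
        store = pt.compute_ld_pairs(G_a, panel)
        her = pt.fit_taus(ss, store, pt.build_annotations(panel, "gcta"))
        beta, _ = pt.solve_windows(ss, store, panel, spec, her.e_j)
        np.testing.assert_allclose(model.beta, beta, atol=1e-12)
        assert model.prior == spec

    def test_empty_grid_rejected(self, small_inputs):
        panel, ss, G_a, G_c = small_inputs
        with pytest.raises(ValueError, match="empty"):
            pt.run_megaprs(ss, G_a, G_c, panel, "ridge",
                           config=pt.MegaConfig(grid=[]), seed=5)
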