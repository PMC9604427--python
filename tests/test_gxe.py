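"""Component score tests, mixture-of-chi-square null, combination rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

from misti import gxe
from misti import simulate as sim
from misti.exceptions import (
    DegenerateInteractionError,
    ParameterError,
    SeparationError,
)


class TestNullFit:
    def test_balanced_null_intercept_near_zero(self):
        rng = np.random.default_rng(1)
        n = 2000
        X = np.ones((n, 1))
        E = rng.standard_normal(n)
        T = rng.standard_normal(n)
        y = np.repeat([0.0, 1.0], n // 2)
        fit = gxe.fit_null_logistic(X, E, T, y)
        assert abs(fit.beta[0]) <= 0.1
        assert np.all((fit.mu > 0) & (fit.mu < 1))

    def test_matches_statsmodels(self):
        """Independent cross-check of the IRLS solver."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 1500
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        E = rng.standard_normal(n)
        T = rng.standard_normal(n)
        eta = 0.3 - 0.5 * X[:, 1] + 0.4 * E - 0.2 * T
        y = rng.binomial(1, expit(eta)).astype(float)
        fit = gxe.fit_null_logistic(X, E, T, y)
        ref = sm.Logit(y, np.column_stack([X, E, T])).fit(disp=0)
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.mu, ref.predict(), atol=1e-6)

    def test_known_coefficients_recovered_within_3se(self):
        rng = np.random.default_rng(3)
        n = 10000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        E = rng.standard_normal(n)
        T = rng.standard_normal(n)
        beta_true = np.array([-0.3, 0.5, 0.25, -0.4])
        eta = np.column_stack([X, E, T]) @ beta_true
        y = rng.binomial(1, expit(eta)).astype(float)
        fit = gxe.fit_null_logistic(X, E, T, y)
        D = np.column_stack([X, E, T])
        info = (D * (fit.w)[:, None]).T @ D
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        assert np.all(np.abs(fit.beta - beta_true) <= 3 * se)

    def test_perfect_separation_raises(self):
        X = np.ones((8, 1))
        E = np.array([-4.0, -3.0, -2.0, -1.0, 1.0, 2.0, 3.0, 4.0])
        T = np.zeros(8) + np.arange(8) * 0.01
        y = (E > 0).astype(float)
        with pytest.raises((SeparationError, ParameterError)):
            gxe.fit_null_logistic(X, E, T, y)


class TestFixedScore:
    def test_degenerate_interaction_detected(self):
        rng = np.random.default_rng(4)
        n = 200
        X = np.ones((n, 1))
        E = rng.standard_normal(n)
        T = rng.standard_normal(n)
        y = rng.binomial(1, 0.5, n).astype(float)
        fit = gxe.fit_null_logistic(X, E, T, y)
        with pytest.raises(DegenerateInteractionError):
            gxe.fixed_score_test(fit, T=np.zeros(n), E=E)

    def test_single_snp_gene_equals_direct_1df_score_test(self):
        """With one SNP and weight w, the burden test reduces to the
        score test of the single SNP x E term (w cancels)."""
        rng = np.random.default_rng(5)
        n = 800
        g = rng.binomial(2, 0.3, n).astype(float)
        E = rng.standard_normal(n)
        X = np.ones((n, 1))
        y = rng.binomial(1, expit(-0.2 + 0.1 * g + 0.1 * E)).astype(float)
        w = 0.37
        fit_w = gxe.fit_null_logistic(X, E, w * g, y)
        p_w = gxe.fixed_score_test(fit_w).p_value
        fit_1 = gxe.fit_null_logistic(X, E, g, y)
        p_1 = gxe.fixed_score_test(fit_1).p_value
        assert p_w == pytest.approx(p_1, rel=1e-6)


class TestMixtureTail:
    def test_chi2_1_closed_form(self):
        q = stats.chi2.isf(0.05, 1)
        assert gxe.mixture_tail_prob(q, [1.0]) == pytest.approx(0.05, abs=1e-4)

    def test_chi2_2_closed_form(self):
        q = stats.chi2.isf(0.05, 2)
        assert gxe.mixture_tail_prob(q, [1.0, 1.0]) == pytest.approx(0.05, abs=1e-4)
        # chi2_2 tail is exp(-q/2)
        for q in (1.0, 4.0, 9.0):
            assert gxe.mixture_tail_prob(q, [1.0, 1.0]) == pytest.approx(np.exp(-q / 2), abs=1e-6)

    def test_scaling_invariance(self):
        q = stats.chi2.isf(0.05, 1)
        assert gxe.mixture_tail_prob(2 * q, [2.0]) == pytest.approx(0.05, abs=1e-4)

    def test_monte_carlo_agreement_mixed_weights(self):
        lam = np.array([3.0, 2.0, 1.0, 0.5])
        rng = np.random.default_rng(1)
        draws = rng.chisquare(1, size=(200_000, 4)) @ lam
        for q in (5.0, 13.0, 25.0):
            mc = (draws >= q).mean()
            se = np.sqrt(mc * (1 - mc) / draws.size)
            assert gxe.mixture_tail_prob(q, lam) == pytest.approx(mc, abs=3 * se)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ParameterError):
            gxe.mixture_tail_prob(1.0, [-1.0, 2.0])

    @given(st.floats(0.1, 50.0), st.lists(st.floats(0.05, 5.0), min_size=1, max_size=6))
    @settings(max_examples=25, deadline=None)
    def test_tail_is_valid_probability_and_decreasing(self, q, lams):
        p1 = gxe.mixture_tail_prob(q, lams)
        p2 = gxe.mixture_tail_prob(q * 1.5, lams)
        assert 0 < p1 <= 1
        # tolerance spans the inversion accuracy and the fallback switch
        assert p2 <= p1 + 1e-6


class TestFisherCombination:
    def test_closed_form_on_grid(self):
        vals = np.linspace(0.01, 1.0, 10)
        for p1 in vals:
            for p2 in vals:
                x = -2 * (np.log(p1) + np.log(p2))
                expected = np.exp(-x / 2) * (1 + x / 2)
                assert gxe.combine_fisher(p1, p2) == pytest.approx(expected, abs=1e-12)

    def test_worked_examples(self):
        assert gxe.combine_fisher(1.0, 1.0) == pytest.approx(1.0)
        assert gxe.combine_fisher(np.exp(-1), np.exp(-1)) == pytest.approx(3 * np.exp(-2), rel=1e-12)
        x = -2 * np.log(0.05)
        assert gxe.combine_fisher(0.05, 1.0) == pytest.approx(
            np.exp(-x / 2) * (1 + x / 2), rel=1e-12)
        assert gxe.combine_fisher(0.05, 1.0) == pytest.approx(0.1996, abs=5e-4)

    def test_matches_chi2_4_survival(self):
        for p1, p2 in [(0.3, 0.7), (0.01, 0.2), (0.9, 0.05)]:
            x = -2 * (np.log(p1) + np.log(p2))
            assert gxe.combine_fisher(p1, p2) == pytest.approx(stats.chi2.sf(x, 4), rel=1e-10)


class TestAdaptiveCombination:
    def test_both_one_gives_one(self):
        assert gxe.combine_adaptive(1.0, 1.0) == 1.0

    def test_single_weight_grid_reduces_to_component(self):
        assert gxe.combine_adaptive(0.03, 0.7, grid=(1.0,)) == pytest.approx(0.03, rel=1e-9)
        assert gxe.combine_adaptive(0.03, 0.7, grid=(0.0,)) == pytest.approx(0.7, rel=1e-9)

    def test_frozen_monte_carlo_oracle(self):
        """Expected value from 1e7 iid Exp(1) pairs (seed 1): 0.022991
        with MC SE 4.7e-5."""
        assert gxe.combine_adaptive(0.01, 0.5) == pytest.approx(0.022991, abs=1.5e-4)

    def test_agreement_with_seeded_monte_carlo(self):
        rng = np.random.default_rng(42)
        B = 300_000
        U = rng.exponential(size=B)
        V = rng.exponential(size=B)
        grid = np.asarray(gxe.DEFAULT_GRID)

        def tail_vec(l, s):
            if l > 1 - 1e-12 or l < 1e-12:
                return np.exp(-s)
            if abs(2 * l - 1) < 1e-8:
                return np.exp(-2 * s) * (1 + 2 * s)
            return (l * np.exp(-s / l) - (1 - l) * np.exp(-s / (1 - l))) / (2 * l - 1)

        tmin = np.ones(B)
        for l in grid:
            tmin = np.minimum(tmin, tail_vec(float(l), l * U + (1 - l) * V))
        for pf, pr in [(0.05, 0.05), (0.2, 0.9), (0.001, 0.4)]:
            u, v = -np.log(pf), -np.log(pr)
            tobs = min(tail_vec(float(l), l * u + (1 - l) * v) for l in grid)
            mc = (tmin <= tobs).mean()
            se = max(np.sqrt(mc * (1 - mc) / B), 1e-6)
            assert gxe.combine_adaptive(pf, pr) == pytest.approx(mc, abs=4 * se)

    def test_symmetric_in_components(self):
        # the default grid is symmetric, so swapping components is neutral
        assert gxe.combine_adaptive(0.02, 0.3) == pytest.approx(
            gxe.combine_adaptive(0.3, 0.02), rel=1e-8)

    def test_bad_grid_rejected(self):
        with pytest.raises(ParameterError):
            gxe.combine_adaptive(0.5, 0.5, grid=(0.5, 1.2))


class TestInvariances:
    """p-values invariant to exposure rescaling and study relabeling."""

    @pytest.fixture(scope="class")
    def dataset(self):
        spec = sim.LDSpec(n_blocks=2, block_size=5, seed=91)
        pop = sim.simulate_ld_genotypes(20000, spec, sample_seed=92)
        w = np.zeros(10)
        w[[2, 7]] = [0.5, -0.4]
        truth = sim.CohortTruth(beta_E=0.1, beta_T=0.1, beta_TE=0.1, seed=93)
        genos, pheno = sim.simulate_cohort(pop, w, sim.ExposureSim(name="exposure"),
                                           truth, 500, 500)
        y = pheno["case_status"].to_numpy(float)
        E = pheno["exposure"].to_numpy(float)
        study = (pheno["study"] == "study1").to_numpy(float)
        X = np.column_stack([np.ones(1000), study,
                             pheno["age"].to_numpy(float)])
        return genos, w, X, E, y

    def _pvals(self, genos, w, X, E, y):
        res = gxe.MistiGxE(y, X, E, genos, w).fit()
        return res.p_fixed, res.p_random, res.p_fisher, res.p_amisti

    def test_affine_exposure_rescaling(self, dataset):
        genos, w, X, E, y = dataset
        base = self._pvals(genos, w, X, E, y)
        scaled = self._pvals(genos, w, X, E * 5.0, y)
        np.testing.assert_allclose(base, scaled, rtol=1e-5)

    def test_study_relabeling(self, dataset):
        genos, w, X, E, y = dataset
        base = self._pvals(genos, w, X, E, y)
        X2 = X.copy()
        X2[:, 1] = 1.0 - X2[:, 1]  # swap study labels
        relabeled = self._pvals(genos, w, X2, E, y)
        np.testing.assert_allclose(base, relabeled, rtol=1e-5)


class TestPowerStructure:
    def test_fixed_component_drives_pure_burden_interactions(self):
        """With tau=0 and a strong burden interaction, the fixed
        component is more sensitive than the residual component."""
        from misti import calibration as cal

        cfg = cal.NullStudyConfig(beta_TE=0.6, n=1000)
        pf, pr = [], []
        for r in range(60):
            y, X, E, G, w = cal.simulate_gene_replicate(cfg, 40_000 + 7 * r)
            res = gxe.MistiGxE(y, X, E, G, w).fit()
            pf.append(res.p_fixed)
            pr.append(res.p_random)
        assert np.median(pf) < np.median(pr)

    def test_power_monotone_in_sample_size(self):
        from misti import calibration as cal

        powers = []
        for k, n in enumerate((500, 1000, 2000)):
            cfg = cal.NullStudyConfig(beta_TE=0.6, n=n)
            hits = 0
            for r in range(60):
                y, X, E, G, w = cal.simulate_gene_replicate(cfg, 50_000 + 900 * k + 7 * r)
                hits += gxe.MistiGxE(y, X, E, G, w).fit().p_amisti < 0.05
            powers.append(hits / 60)
        assert powers[0] <= powers[1] <= powers[2]


class TestGeneLevel:
    def test_summary_and_record(self):
        spec = sim.LDSpec(n_blocks=1, block_size=5, seed=95)
        pop = sim.simulate_ld_genotypes(10000, spec, sample_seed=96)
        w = np.full(5, 0.2)
        truth = sim.CohortTruth(seed=97)
        genos, pheno = sim.simulate_cohort(pop, w, sim.ExposureSim(name="exposure"),
                                           truth, 300, 300)
        res = gxe.MistiGxE(
            pheno["case_status"].to_numpy(float), np.ones((600, 1)),
            pheno["exposure"].to_numpy(float), genos, w,
            gene_id="geneA", exposure_name="exposure",
        ).fit()
        rec = res.to_record()
        assert rec.n_snps == 5
        for p in (rec.p_fixed, rec.p_random, rec.p_fisher, rec.p_amisti):
            assert 0 < p <= 1
        text = res.summary()
        assert "geneA" in text and "aMiSTi" in text
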