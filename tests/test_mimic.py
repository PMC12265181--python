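"""MIMIC/CFA estimation: implied covariance, ML fit, indices, MIs."""

import numpy as np
import pytest

from brainsym.mimic import (
    IdentificationError,
    MimicSpec,
    SampleMoments,
    default_mimic_spec,
    degrees_of_freedom,
    fit_baseline,
    fit_indices,
    fit_ml,
    model_implied_covariance,
    modification_indices,
    spec_for_indicators,
    standardized_solution,
    two_step_fit,
)
from brainsym.synthetic import CohortParams, population_moments, simulate_cohort

from _oracles import RamSem, oracle_fit_indices

TOY_CFA = MimicSpec(indicators=("y1", "y2", "y3", "y4"), identification="first_loading",
                    structural=False)


def _cohort_moments(params: CohortParams) -> SampleMoments:
    table, _ = simulate_cohort(params)
    return SampleMoments.from_dataframe(
        table, list(params.indicators) + list(params.predictors)
    )


class TestSpec:
    def test_duplicate_residual_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MimicSpec(indicators=("a", "b", "c"),
                      residual_cov_pairs=(("a", "b"), ("b", "a")))

    def test_pair_outside_indicators_rejected(self):
        with pytest.raises(ValueError):
            MimicSpec(indicators=("a", "b"), residual_cov_pairs=(("a", "z"),))

    def test_default_spec_matches_study_structure(self):
        spec = default_mimic_spec()
        assert len(spec.indicators) == 11
        assert spec.predictors == ("ses", "age", "sex")
        assert len(spec.residual_cov_pairs) == 4


class TestImpliedCovariance:
    def test_zero_loadings_give_pure_residual_covariance(self):
        spec = MimicSpec(indicators=("y1", "y2"), identification="latent_variance",
                         structural=False)
        theta = np.array([0.0, 0.0, 2.0, 3.0])  # lambda1, lambda2, theta11, theta22
        np.testing.assert_allclose(
            model_implied_covariance(spec, theta), np.diag([2.0, 3.0])
        )

    def test_two_indicator_hand_algebra(self):
        # lambda = (1, 0.5), psi = 4, Theta = I  ->  [[5, 2], [2, 2]]
        spec = MimicSpec(indicators=("y1", "y2"), structural=False)
        theta = np.array([0.5, 4.0, 1.0, 1.0])
        np.testing.assert_allclose(
            model_implied_covariance(spec, theta), [[5.0, 2.0], [2.0, 2.0]]
        )

    def test_matches_monte_carlo_covariance(self, rng):
        """Sigma(theta) agrees with brute-force generate-and-covary."""
        spec = MimicSpec(indicators=("y1", "y2", "y3"), predictors=("x1", "x2"))
        phi = np.array([[1.0, 0.3], [0.3, 2.0]])
        lam = np.array([1.0, 0.8, 0.6])
        gamma = np.array([0.5, -0.4])
        psi, th = 0.7, np.array([0.5, 0.6, 0.7])
        theta = np.concatenate([lam[1:], [psi], gamma, th])
        n = 200_000
        x = rng.multivariate_normal(np.zeros(2), phi, size=n)
        eta = x @ gamma + rng.normal(0, np.sqrt(psi), n)
        y = eta[:, None] * lam + rng.normal(0, np.sqrt(th), (n, 3))
        emp = np.cov(np.column_stack([y, x]).T)
        np.testing.assert_allclose(
            model_implied_covariance(spec, theta, phi), emp, atol=0.03
        )

    def test_wrong_theta_length_rejected(self):
        with pytest.raises(ValueError, match="entries"):
            model_implied_covariance(TOY_CFA, np.zeros(3))


class TestDegreesOfFreedom:
    def test_full_study_model_df(self):
        assert degrees_of_freedom(default_mimic_spec()) == 70

    def test_cfa_only_df(self):
        assert degrees_of_freedom(default_mimic_spec().cfa()) == 40

    def test_just_identified_three_indicator_model(self):
        spec = MimicSpec(indicators=("y1", "y2", "y3"), structural=False)
        # 6 moments, 6 free parameters (2 loadings, psi, 3 residuals)
        assert degrees_of_freedom(spec) == 0

    def test_overparameterized_spec_rejected(self):
        spec = MimicSpec(indicators=("y1", "y2"), structural=False,
                         residual_cov_pairs=(("y1", "y2"),))
        with pytest.raises(IdentificationError):
            degrees_of_freedom(spec)


class TestFitMl:
    def test_population_moments_zero_discrepancy(self):
        params = CohortParams()
        fit = fit_ml(default_mimic_spec(), population_moments(params, n=2000))
        assert fit.converged and not fit.heywood
        assert fit.fmin <= 1e-10
        assert fit.chisq <= 1e-6
        true = params.raw_parameters()
        for name, value in true.items():
            assert fit.estimates[name] == pytest.approx(value, abs=1e-6), name

    def test_estimates_match_generic_optimizer_on_cfa(self):
        params = CohortParams(n_subjects=400, seed=11, indicators=("y1", "y2", "y3", "y4"),
                              loadings=(0.8, 0.7, 0.6, 0.75), residual_pairs=())
        mom = _cohort_moments(params).subset(["y1", "y2", "y3", "y4"])
        fit = fit_ml(TOY_CFA, mom)
        oracle = RamSem(TOY_CFA.indicators)
        est_o, fmin_o = oracle.fit(mom.cov, start=fit.theta * 1.15 + 0.05)
        assert fit.fmin == pytest.approx(fmin_o, abs=1e-8)
        for name, value in est_o.items():
            assert fit.estimates[name] == pytest.approx(value, abs=1e-4), name

    def test_estimates_match_generic_optimizer_on_mimic(self):
        spec = MimicSpec(indicators=("y1", "y2", "y3", "y4", "y5"),
                         predictors=("ses", "age"),
                         residual_cov_pairs=(("y1", "y2"),))
        params = CohortParams(n_subjects=600, seed=3,
                              indicators=("y1", "y2", "y3", "y4", "y5"),
                              loadings=(0.8, 0.7, 0.75, 0.6, 0.65),
                              residual_pairs=(("y1", "y2"),))
        mom = _cohort_moments(params).subset(list(spec.observed))
        fit = fit_ml(spec, mom)
        oracle = RamSem(spec.indicators, spec.predictors, spec.residual_cov_pairs)
        est_o, fmin_o = oracle.fit(mom.cov, start=fit.theta * 1.1 + 0.02)
        assert fit.fmin == pytest.approx(fmin_o, abs=1e-8)
        for name, value in est_o.items():
            assert fit.estimates[name] == pytest.approx(value, abs=1e-4), name

    def test_non_pd_sample_covariance_rejected(self):
        bad = np.ones((4, 4))  # singular
        with pytest.raises(ValueError):
            fit_ml(TOY_CFA, SampleMoments(cov=bad + np.eye(4) * 0, names=list(TOY_CFA.indicators), n=50))


class TestFitIndices:
    def test_perfect_fit_limit(self):
        fit = fit_ml(default_mimic_spec(), population_moments(CohortParams(), n=500))
        ix = fit_indices(fit)
        assert ix.cfi == pytest.approx(1.0)
        assert ix.rmsea == pytest.approx(0.0, abs=1e-6)
        assert ix.srmr == pytest.approx(0.0, abs=1e-6)

    def test_published_rmsea_arithmetic(self):
        # T = 119.7, df = 70, n = 132 -> RMSEA = sqrt(49.7 / (70 * 131))
        rmsea = np.sqrt(max(119.7 - 70, 0.0) / (70 * 131))
        assert round(float(rmsea), 2) == 0.07

    def test_indices_match_independent_reference(self):
        params = CohortParams(n_subjects=300, seed=21)
        mom = _cohort_moments(params)
        spec = default_mimic_spec()
        fit = fit_ml(spec, mom)
        ix = fit_indices(fit)
        ref = oracle_fit_indices(fit.fmin, fit.df, mom.subset(list(spec.observed)).cov,
                                 fit.sigma, mom.n, spec.n_indicators, spec.n_predictors)
        for key in ("cfi", "tli", "rmsea", "srmr", "p_rmsea_le_05"):
            assert getattr(ix, key) == pytest.approx(ref[key], abs=0.005), key
        assert ix.rmsea_ci90 == pytest.approx(ref["rmsea_ci90"], abs=0.005)

    def test_rmsea_ci_brackets_point_estimate(self):
        params = CohortParams(n_subjects=150, seed=5)
        fit = fit_ml(default_mimic_spec(), _cohort_moments(params))
        ix = fit_indices(fit)
        lo, hi = ix.rmsea_ci90
        assert lo <= ix.rmsea <= hi


class TestModificationIndices:
    def test_free_parameters_not_listed(self):
        fit = fit_ml(default_mimic_spec(), population_moments(CohortParams(), n=500))
        listed = {e.parameter for e in modification_indices(fit)}
        for a, b in fit.spec.residual_cov_pairs:
            assert f"theta[{a},{b}]" not in listed
            assert f"theta[{b},{a}]" not in listed

    def test_omitted_residual_covariance_detected(self):
        """Data generated with an extra residual covariance: the fitted
        model omitting it should put the largest MI on that pair."""
        hits = 0
        n_rep = 30
        gen_ind = ("y1", "y2", "y3", "y4", "y5", "y6")
        fit_spec = MimicSpec(indicators=gen_ind, structural=False)
        for rep in range(n_rep):
            params = CohortParams(
                n_subjects=500, seed=1000 + rep, indicators=gen_ind,
                loadings=(0.8, 0.75, 0.7, 0.65, 0.7, 0.75),
                residual_pairs=(("y3", "y4"),), residual_corr=0.4,
            )
            mom = _cohort_moments(params).subset(list(gen_ind))
            fit = fit_ml(fit_spec, mom)
            top = modification_indices(fit)[0]
            hits += {top.lhs, top.rhs} == {"y3", "y4"}
        assert hits >= 0.9 * n_rep

    def test_mi_approximates_chi_square_drop(self):
        params = CohortParams(n_subjects=800, seed=77, residual_corr=0.35)
        mom = _cohort_moments(params)
        spec = default_mimic_spec()
        reduced = MimicSpec(indicators=spec.indicators, predictors=spec.predictors,
                            residual_cov_pairs=spec.residual_cov_pairs[:-1])
        fit = fit_ml(reduced, mom)
        top = modification_indices(fit)[0]
        freed = MimicSpec(
            indicators=spec.indicators, predictors=spec.predictors,
            residual_cov_pairs=reduced.residual_cov_pairs + ((top.lhs, top.rhs),),
        )
        refit = fit_ml(freed, mom)
        drop = fit.chisq - refit.chisq
        assert abs(top.mi - drop) <= 0.15 * top.mi


class TestStandardizedSolution:
    def test_single_factor_toy_loading_is_correlation(self):
        # population moments of a 3-indicator model: standardized loading
        # equals the indicator-factor correlation lambda*sd_eta/sd_y
        spec = MimicSpec(indicators=("y1", "y2", "y3"), structural=False)
        theta0 = np.array([0.5, 0.25, 4.0, 1.0, 1.0, 1.0])
        sigma = model_implied_covariance(spec, theta0)
        fit = fit_ml(spec, SampleMoments(cov=sigma, names=["y1", "y2", "y3"], n=500),
                     start=theta0)
        std = standardized_solution(fit)
        assert std["loadings"]["y1"] == pytest.approx(2.0 / np.sqrt(5.0), abs=1e-6)

    def test_invariant_to_identification_choice(self):
        params = CohortParams(n_subjects=400, seed=13)
        mom = _cohort_moments(params)
        spec = default_mimic_spec()
        fit_a = fit_ml(spec, mom)
        fit_b = fit_ml(
            MimicSpec(indicators=spec.indicators, predictors=spec.predictors,
                      residual_cov_pairs=spec.residual_cov_pairs,
                      identification="latent_variance"),
            mom,
        )
        std_a, std_b = standardized_solution(fit_a), standardized_solution(fit_b)
        for name in spec.indicators:
            assert std_a["loadings"][name] == pytest.approx(std_b["loadings"][name], abs=1e-6)
        for name in spec.predictors:
            assert std_a["paths"][name] == pytest.approx(std_b["paths"][name], abs=1e-6)

    def test_population_fit_reproduces_generating_standardized_values(self):
        params = CohortParams()
        fit = fit_ml(default_mimic_spec(), population_moments(params, n=2000))
        std = standardized_solution(fit)
        for name, lam in zip(params.indicators, params.loadings):
            assert std["loadings"][name] == pytest.approx(lam, abs=1e-4)
        for name, beta in zip(("ses", "age", "sex"), params.paths):
            assert std["paths"][name] == pytest.approx(beta, abs=1e-4)


class TestTwoStep:
    def test_population_data_passes_both_steps(self):
        result = two_step_fit(default_mimic_spec(), population_moments(CohortParams(), n=800))
        assert result.measurement_model_acceptable
        assert all(result.structural_pass.values())
        assert result.cfa_fit.df == 40 and result.structural_fit.df == 70

    def test_well_specified_samples_pass_measurement_thresholds(self):
        passes = 0
        n_rep = 20
        for rep in range(n_rep):
            mom = _cohort_moments(CohortParams(n_subjects=2000, seed=5000 + rep))
            result = two_step_fit(default_mimic_spec(), mom)
            passes += result.measurement_model_acceptable
        assert passes >= round(0.95 * n_rep)

    def test_gross_misspecification_flagged_by_rmsea(self):
        """Two nearly independent factors forced into one: step-1 RMSEA
        must blow past the 0.08 cutoff in nearly every replicate."""
        n_rep = 10
        flagged = 0
        rng = np.random.default_rng(31)
        ind = tuple(f"y{i}" for i in range(1, 12))
        spec = MimicSpec(indicators=ind, structural=False)
        for _ in range(n_rep):
            f1 = rng.normal(size=2000)
            f2 = rng.normal(size=2000)
            y = np.empty((2000, 11))
            for j in range(11):
                factor = f1 if j < 6 else f2
                y[:, j] = 0.8 * factor + rng.normal(0, 0.6, 2000)
            mom = SampleMoments(cov=np.cov(y.T), names=list(ind), n=2000)
            with pytest.warns(UserWarning, match="thresholds"):
                result = two_step_fit(spec, mom)
            flagged += result.cfa_indices.rmsea > 0.08
        assert flagged >= round(0.9 * n_rep)
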