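"""Prior penalty, MAP/EBE estimation, Laplace marginal likelihood, LRT."""

import numpy as np
import pytest
from _oracles import quadrature_subject_ofv

from palbopk import (
    CohortConfig,
    ConcentrationObservation,
    DoseEvent,
    PopulationParameters,
    PriorSpecification,
    SubjectRecord,
    estimate_individual,
    fit_population,
    individual_objective,
    lrt_covariate,
    marginal_ofv,
    prior_penalty,
)
from palbopk.estimation import (
    ConfigurationError,
    FitConfig,
    _laplace_subject_ofv,
    _SubjectModel,
)
from palbopk.synthetic import generate_cohort, generate_rich_pk


def one_eta_subject(pop_one_eta, seed, n_obs=2):
    cohort = generate_cohort(CohortConfig(n_patients=4, pop=pop_one_eta,
                                          seed=seed, p_missing_sample=0.0))
    subj = cohort.subjects[0]
    assert len(subj.usable_observations) >= 1
    return subj


class TestPriorPenalty:
    def scalar_prior(self, rse=0.02, no_weight=()):
        return PriorSpecification.from_rse({"cl_pop": 62.6},
                                           {"cl_pop": rse},
                                           no_weight=no_weight)

    def test_zero_at_prior_mean(self):
        assert prior_penalty([62.6], self.scalar_prior()) == 0.0

    def test_one_sd_deviation_gives_one(self):
        # sd = 2% of 62.6 = 1.252; theta one sd above the mean
        assert prior_penalty([63.852], self.scalar_prior()) == pytest.approx(
            1.0, rel=1e-12)

    def test_no_weight_parameter_ignored(self):
        prior = PriorSpecification.from_rse(
            {"cl_pop": 62.6, "f_rel": 1.0}, {"cl_pop": 0.02},
            no_weight=("f_rel",))
        a = prior_penalty([62.6, 1.0], prior)
        b = prior_penalty([62.6, 37.0], prior)
        assert a == b == 0.0

    def test_singular_covariance_rejected(self):
        with pytest.raises(ConfigurationError):
            PriorSpecification(names=("cl_pop", "v1_pop"),
                               theta_prior=[62.6, 2370.0],
                               theta_prior_cov=np.zeros((2, 2)))

    def test_positive_away_from_mean(self):
        assert prior_penalty([70.0], self.scalar_prior()) > 0.0


class TestIndividualObjective:
    def test_no_observations_at_zero_eta(self, pop):
        subj = SubjectRecord("s1", 70.0, doses=(DoseEvent(0.0, 125.0),))
        assert individual_objective(subj, pop, np.zeros(2)) == 0.0

    def test_no_observations_is_quadratic_form(self, pop):
        subj = SubjectRecord("s1", 70.0, doses=(DoseEvent(0.0, 125.0),))
        eta = np.array([0.3, -0.2])
        expected = eta @ np.linalg.inv(pop.omega) @ eta
        assert individual_objective(subj, pop, eta) == pytest.approx(expected)

    def test_coercive_in_eta(self, pop_one_eta):
        subj = one_eta_subject(pop_one_eta, seed=3)
        vals = [individual_objective(subj, pop_one_eta, np.array([e]))
                for e in (0.0, 3.0, 6.0, 9.0)]
        assert vals[-1] > vals[0]
        assert individual_objective(subj, pop_one_eta, np.array([-9.0])) > vals[0]

    def test_matches_hand_assembled_scalar_expression(self, pop_one_eta):
        """One observation, one eta on CL: objective =
        (y-f)^2/(sigma f)^2 + log((sigma f)^2) + eta^2/omega."""
        from palbopk import concentration_profile, individual_from_eta

        doses = (DoseEvent(0.0, 125.0), DoseEvent(24.0, 125.0))
        obs = ConcentrationObservation(time=30.0, value=55.0, cycle=1)
        subj = SubjectRecord("s1", 80.0, doses=doses, observations=(obs,))
        eta = np.array([0.25])
        ind = individual_from_eta(pop_one_eta, 80.0, eta)
        f = concentration_profile(ind, doses, np.array([30.0]))[0]
        var = (pop_one_eta.sigma_prop * f) ** 2
        expected = (55.0 - f) ** 2 / var + np.log(var) \
            + eta[0] ** 2 / pop_one_eta.omega[0, 0]
        assert individual_objective(subj, pop_one_eta, eta) == pytest.approx(
            expected, rel=1e-10)


class TestEstimateIndividual:
    def test_no_observations_returns_prior_mode(self, pop):
        subj = SubjectRecord("s1", 70.0, doses=(DoseEvent(0.0, 125.0),))
        ind = estimate_individual(subj, pop)
        np.testing.assert_array_equal(ind.eta, 0.0)

    def test_tight_omega_shrinks_to_population(self, pop_one_eta):
        from dataclasses import replace

        subj = one_eta_subject(pop_one_eta, seed=5)
        tight = replace(pop_one_eta, omega=np.array([[1e-6 * 0.09]]))
        ind = estimate_individual(subj, tight)
        assert np.linalg.norm(ind.eta) < 1e-3

    def test_matches_grid_search(self, pop_one_eta):
        for seed in (11, 12, 13):
            subj = one_eta_subject(pop_one_eta, seed=seed)
            ind = estimate_individual(subj, pop_one_eta)
            grid = np.linspace(-2.0, 2.0, 40001)
            model = _SubjectModel(subj, pop_one_eta)
            vals = [model.objective(np.array([e])) for e in grid]
            assert ind.eta[0] == pytest.approx(grid[int(np.argmin(vals))],
                                               abs=1e-4)

    def test_ebe_pipeline_deterministic(self, pop, small_sparse_cohort):
        subj = next(s for s in small_sparse_cohort.subjects
                    if s.usable_observations)
        a = estimate_individual(subj, pop)
        b = estimate_individual(subj, pop)
        np.testing.assert_array_equal(a.eta, b.eta)


class TestMarginalOfv:
    def test_laplace_matches_quadrature_one_eta(self, pop_one_eta):
        """Spec invariant: Laplace within 0.1 of the quadrature oracle on
        randomized one-eta subjects (sparse and rich designs)."""
        diffs = []
        for seed in (1, 2, 3):
            sparse = generate_cohort(CohortConfig(
                n_patients=5, pop=pop_one_eta, seed=seed))
            rich = generate_rich_pk(CohortConfig(
                n_patients=5, pop=pop_one_eta, seed=seed), 8)
            for s in sparse.subjects + rich.subjects:
                model = _SubjectModel(s, pop_one_eta)
                if model.n_obs == 0:
                    continue
                ofv, eta = _laplace_subject_ofv(model,
                                                np.zeros(1))
                diffs.append(ofv - quadrature_subject_ofv(model, eta))
        assert np.max(np.abs(diffs)) < 0.1

    def test_additivity_over_subjects(self, pop_one_eta):
        cohort = generate_cohort(CohortConfig(n_patients=6, pop=pop_one_eta,
                                              seed=9))
        base = marginal_ofv(cohort.subjects, pop_one_eta)
        from dataclasses import replace

        doubled = cohort.subjects + [
            replace(s, subject_id=s.subject_id + "b") for s in cohort.subjects]
        assert marginal_ofv(doubled, pop_one_eta) == pytest.approx(2 * base,
                                                                   rel=1e-9)

    def test_prior_penalty_added(self, pop_one_eta):
        cohort = generate_cohort(CohortConfig(n_patients=6, pop=pop_one_eta,
                                              seed=9))
        prior = PriorSpecification.from_rse({"cl_pop": 50.0},
                                            {"cl_pop": 0.1})
        without = marginal_ofv(cohort.subjects, pop_one_eta)
        with_prior = marginal_ofv(cohort.subjects, pop_one_eta, prior)
        expected = prior_penalty([pop_one_eta.cl_pop], prior)
        assert with_prior - without == pytest.approx(expected, rel=1e-9)

    def test_requires_usable_observations(self, pop):
        subj = SubjectRecord("s1", 70.0, doses=(DoseEvent(0.0, 125.0),))
        with pytest.raises(ConfigurationError):
            marginal_ofv([subj], pop)


class TestFitPopulation:
    def test_tight_prior_pins_estimates(self, pop_one_eta):
        cohort = generate_cohort(CohortConfig(n_patients=20, pop=pop_one_eta,
                                              seed=21))
        prior = PriorSpecification.from_rse(
            {"cl_pop": 62.6, "v1_pop": 2370.0, "v2_pop": 682.0},
            {"cl_pop": 0.25, "v1_pop": 0.25, "v2_pop": 0.25})
        tight = prior.scaled(1e-8)
        res = fit_population(
            cohort.subjects, pop_one_eta, tight,
            FitConfig(estimate_theta=("cl_pop", "v1_pop", "v2_pop"),
                      estimate_omega=False, estimate_sigma_prop=False,
                      compute_covariance=False))
        assert res.estimates.cl_pop == pytest.approx(62.6, rel=1e-3)
        assert res.estimates.v1_pop == pytest.approx(2370.0, rel=1e-3)
        assert res.estimates.v2_pop == pytest.approx(682.0, rel=1e-3)

    def test_descent_from_init(self, pop_one_eta):
        from dataclasses import replace

        cohort = generate_cohort(CohortConfig(n_patients=25, pop=pop_one_eta,
                                              seed=22))
        init = replace(pop_one_eta, cl_pop=90.0)
        cfg = FitConfig(estimate_theta=("cl_pop",), estimate_omega=False,
                        estimate_sigma_prop=False, compute_covariance=False)
        res = fit_population(cohort.subjects, init, None, cfg)
        assert res.ofv <= marginal_ofv(cohort.subjects, init) + 1e-6

    def test_empty_dataset_rejected(self, pop):
        with pytest.raises(ConfigurationError):
            fit_population([], pop)

    def test_prior_rescues_sparse_fit_precision(self, pop):
        """The motivation for the frequentist prior: with 1-2 samples per
        patient the unpenalized fit cannot pin down the peripheral
        parameters (huge RSEs), while the prior-penalized fit keeps all
        fixed-effect RSEs below 31%."""
        from palbopk.dataio import default_prior_specification

        cohort = generate_cohort(CohortConfig(n_patients=120, pop=pop,
                                              seed=11))
        prior = default_prior_specification(pop, rse=0.25)
        cfg = FitConfig(n_starts=1)
        with_prior = fit_population(cohort.subjects, pop, prior, cfg)
        without = fit_population(cohort.subjects, pop, None, cfg)
        theta = ("cl_pop", "v1_pop", "v2_pop", "q_pop")
        assert max(with_prior.rse[k] for k in theta) < 31.0
        assert max(without.rse[k] for k in theta) > 31.0


class TestLrt:
    @pytest.mark.parametrize("delta,expected", [
        (3.84, True), (3.83, False), (0.0, False), (10.0, True)])
    def test_significance_boundary(self, delta, expected):
        out = lrt_covariate(100.0 + delta, 100.0)
        assert out["significant"] is expected
        assert out["delta"] == pytest.approx(delta)

    def test_negative_delta_warns(self):
        with pytest.warns(RuntimeWarning):
            lrt_covariate(100.0, 101.0)
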