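"""Interim Bayesian model: design matrix, priors, superiority table."""

import json

import numpy as np
import pytest

from linkedbar.bayes_interim import (
    COEF_NAMES,
    N_COEF,
    ModelCoefficients,
    PriorSpec,
    build_design_matrix,
    fit_posterior,
    prior_superiority,
    superiority_for_profile,
)
from linkedbar.scenario_sim import BiomarkerProfile, profile_index


class TestDesignMatrix:
    def test_sixteen_columns_in_fixed_order(self, s2_fixture):
        arms, pidx, _ = s2_fixture
        X, names = build_design_matrix(arms, pidx)
        assert X.shape == (len(arms), 16)
        assert names == COEF_NAMES

    def test_control_all_negative_row(self):
        X, _ = build_design_matrix(np.array([0]), np.array([0]))
        expected = np.zeros(16)
        expected[0] = 1.0
        np.testing.assert_array_equal(X[0], expected)

    def test_t1_patient_positive_for_b1_and_b3(self):
        idx = profile_index(1, 0, 1)
        X, names = build_design_matrix(np.array([1]), np.array([idx]))
        on = {names[j] for j in np.flatnonzero(X[0])}
        assert on == {"mu", "theta1", "beta1", "beta3", "gamma11", "gamma13"}

    def test_unassigned_arm_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix(np.array([-1]), np.array([0]))


class TestPriorSpec:
    def test_linked_design_pairs(self):
        p = PriorSpec()
        assert p.linked_pairs == frozenset({(1, 1), (2, 2), (3, 3)})
        prec = p.precision_vector()
        assert prec[COEF_NAMES.index("gamma11")] == 1.0
        assert prec[COEF_NAMES.index("gamma12")] == 0.0

    def test_flat_variant_has_no_informative_pairs(self):
        assert PriorSpec.flat().linked_pairs == frozenset()

    def test_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(box_low=1.0, box_high=-1.0)
        with pytest.raises(ValueError):
            PriorSpec(linked_var=0.0)


class TestPriorOnlySuperiority:
    def test_flat_symmetric_priors_give_one_half_everywhere(self):
        n_draws = 20000
        summ = prior_superiority(PriorSpec.flat(), n_draws=n_draws,
                                 rng=np.random.default_rng(21))
        tol = 2 * np.sqrt(0.25 / n_draws)
        assert np.all(np.abs(summ.superiority - 0.5) < 3 * tol)

    def test_linked_prior_favours_linked_arm_on_its_profile(self):
        summ = prior_superiority(PriorSpec(), n_draws=20000,
                                 rng=np.random.default_rng(22))
        b1_only = profile_index(1, 0, 0)
        assert summ.superiority[b1_only, 0] > 0.52  # T1 favoured
        assert abs(summ.superiority[b1_only, 1] - 0.5) < 0.02  # T2 neutral


class TestFitPosterior:
    def test_agrees_with_long_mcmc_reference(self, s2_fixture):
        """Superiority of T1 for the B1-only profile vs a converged ensemble
        MCMC run on the same 200-patient fixture (within 0.02)."""
        emcee = pytest.importorskip("emcee")
        arms, pidx, outcomes = s2_fixture
        priors = PriorSpec()
        X, _ = build_design_matrix(arms, pidx)
        m, prec = priors.mean_vector(), priors.precision_vector()

        def logpost(B):
            B = np.atleast_2d(B)
            lp = np.full(B.shape[0], -np.inf)
            ok = np.all(np.abs(B) <= 10, axis=1)
            if ok.any():
                eta = B[ok] @ X.T
                lp[ok] = (eta @ outcomes
                          - np.logaddexp(0.0, eta).sum(axis=1)
                          - 0.5 * ((B[ok] - m) ** 2 @ prec))
            return lp

        from linkedbar._logistic import fit_map

        # reference run sized so that two independent seeds agree to ~0.004
        # on every superiority entry (integrated autocorrelation time is
        # ~185, so 15 000 steps is ~80 tau)
        mode_fit = fit_map(X, outcomes, m, prec, -10, 10)
        L = np.linalg.cholesky(mode_fit.cov)
        r0 = np.random.default_rng(1)
        nwalkers = 128
        p0 = np.clip(mode_fit.mode
                     + 1.1 * (r0.standard_normal((nwalkers, N_COEF)) @ L.T),
                     -9.9, 9.9)
        sampler = emcee.EnsembleSampler(nwalkers, N_COEF, logpost,
                                        vectorize=True)
        sampler.run_mcmc(p0, 15000, progress=False)
        chain = sampler.get_chain(discard=5000, thin=10, flat=True)
        b1_only = profile_index(1, 0, 0)
        ref = float(((chain[:, 1] + chain[:, 7]) > 0).mean())

        summ = fit_posterior(arms, pidx, outcomes, priors, n_draws=8000,
                             rng=np.random.default_rng(3))
        assert summ.superiority[b1_only, 0] == pytest.approx(ref, abs=0.02)

    def test_two_seeds_agree_elementwise(self, s2_fixture):
        arms, pidx, outcomes = s2_fixture
        a = fit_posterior(arms, pidx, outcomes, PriorSpec(), n_draws=8000,
                          rng=np.random.default_rng(100))
        b = fit_posterior(arms, pidx, outcomes, PriorSpec(), n_draws=8000,
                          rng=np.random.default_rng(200))
        assert np.max(np.abs(a.superiority - b.superiority)) < 0.03

    def test_strong_effect_dominates_prior_at_n_300(self, library):
        """With 300 observed outcomes under the scenario-2 truth, the
        posterior should be nearly certain T1 beats control in B1-positive
        patients (seed-averaged)."""
        from linkedbar.scenario_sim import sample_profile_indices

        s2 = library["S2"]
        table = s2.response_table()
        b1_only = profile_index(1, 0, 0)
        vals = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            pidx = sample_profile_indices(s2.prevalence, 300, rng)
            arms = rng.integers(0, 4, 300)
            y = (rng.random(300) < table[arms, pidx]).astype(float)
            summ = fit_posterior(arms, pidx, y, PriorSpec(), n_draws=4000,
                                 rng=rng)
            vals.append(summ.superiority[b1_only, 0])
        assert np.mean(vals) > 0.95

    def test_contract_violations(self, s2_fixture):
        arms, pidx, outcomes = s2_fixture
        with pytest.raises(ValueError):
            fit_posterior(arms[:0], pidx[:0], outcomes[:0], PriorSpec())
        with pytest.raises(ValueError):
            fit_posterior(arms, pidx, outcomes, PriorSpec(), n_draws=10)


class TestSummaryAccess:
    def test_profile_lookup_is_a_pure_accessor(self, s2_fixture):
        arms, pidx, outcomes = s2_fixture
        summ = fit_posterior(arms, pidx, outcomes, PriorSpec(), n_draws=2000,
                             rng=np.random.default_rng(5))
        profile = BiomarkerProfile(0, 0, 0)
        row1 = superiority_for_profile(summ, profile)
        row2 = superiority_for_profile(summ, 0)
        np.testing.assert_array_equal(row1, row2)
        row1[:] = -1  # mutating the copy must not touch the summary
        assert np.all(summ.superiority[0] >= 0)
        assert np.all((summ.superiority >= 0) & (summ.superiority <= 1))

    def test_json_export_keyed_by_bitstring(self, s2_fixture):
        arms, pidx, outcomes = s2_fixture
        summ = fit_posterior(arms, pidx, outcomes, PriorSpec(), n_draws=2000,
                             rng=np.random.default_rng(6))
        doc = json.loads(summ.to_json())
        assert set(doc["superiority"].keys()) == {
            f"{b1}{b2}{b3}" for b1 in (0, 1) for b2 in (0, 1) for b3 in (0, 1)
        }
        assert doc["n_outcomes"] == 200


class TestModelCoefficients:
    def test_vector_round_trip(self):
        v = np.arange(16.0)
        mc = ModelCoefficients.from_vector(v)
        np.testing.assert_array_equal(mc.to_vector(), v)
        assert mc.gamma.shape == (3, 3)
        assert mc.gamma[0, 0] == 7.0  # gamma11 sits right after the betas
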