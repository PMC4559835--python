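"""The trial orchestrator: schedules, delay, determinism, design variants."""

import numpy as np
import pytest
import yaml

from linkedbar.bayes_interim import PriorSpec
from linkedbar.scenario_sim import build_accrual, profile_index
from linkedbar.trial_engine import (
    DesignConfig,
    available_outcomes,
    interim_schedule,
    replay_allocations,
    run_trial,
)


class TestInterimSchedule:
    def test_default_trial_triggers(self):
        # 100 + round(k * 62.5) for k = 0..3
        assert interim_schedule(350, 100, 4) == [100, 163, 225, 288]

    def test_single_interim(self):
        assert interim_schedule(350, 100, 1) == [100]

    def test_first_interim_must_precede_trial_end(self):
        with pytest.raises(ValueError):
            interim_schedule(100, 100, 4)


class TestAvailableOutcomes:
    def test_zero_delay_includes_everyone_recruited(self):
        times = build_accrual(350, 36.0).recruit_times
        mask = available_outcomes(times[:100], times[99], 0.0)
        assert mask.sum() == 100

    def test_six_month_delay_at_first_interim_gives_41(self):
        # recruit_time_i = 36 i / 350; need 36 i / 350 + 6 <= 36 * 100 / 350
        times = build_accrual(350, 36.0).recruit_times
        mask = available_outcomes(times[:100], times[99], 6.0)
        assert mask.sum() == 41
        assert mask[:41].all() and not mask[41:].any()

    def test_before_any_outcome_matures(self):
        times = build_accrual(350, 36.0).recruit_times
        assert available_outcomes(times[:10], times[9], 6.0).sum() == 0


class TestDesignConfig:
    def test_defaults_match_the_trial_blueprint(self):
        cfg = DesignConfig(variant="LB")
        assert (cfg.n_total, cfg.n_first_interim, cfg.n_stages) == (350, 100, 5)
        assert (cfg.delay, cfg.accrual_duration) == (6.0, 36.0)
        assert cfg.wald_threshold == 1.5
        assert cfg.priors.linked_pairs == frozenset({(1, 1), (2, 2), (3, 3)})

    def test_non_linked_designs_get_flat_priors(self):
        for variant in ("NLB", "PT", "ER"):
            assert DesignConfig(variant=variant).priors.linked_pairs == frozenset()

    def test_yaml_round_trip(self):
        cfg = DesignConfig(variant="LB", seed=9,
                           priors=PriorSpec(linked_mean=0.5))
        back = DesignConfig.from_dict(yaml.safe_load(yaml.safe_dump(cfg.to_dict())))
        assert back.variant == "LB"
        assert back.priors.linked_mean == 0.5
        assert back.priors.linked_pairs == cfg.priors.linked_pairs
        assert back.tuning == cfg.tuning
        assert back.seed == 9

    def test_validation(self):
        with pytest.raises(ValueError):
            DesignConfig(variant="LB", n_first_interim=350)
        with pytest.raises(ValueError):
            DesignConfig(variant="LB", n_stages=0)
        with pytest.raises(ValueError):
            DesignConfig(variant="??")


@pytest.fixture(scope="module")
def small_lb():
    """Desk-scale linked-BAR design: 120 patients, 3 stages."""
    return DesignConfig(variant="LB", n_total=120, n_first_interim=40,
                        n_stages=3, accrual_duration=36.0, delay=6.0,
                        n_draws=1000)


class TestRunTrial:
    def test_same_seed_reproduces_everything(self, library, small_lb):
        a = run_trial(small_lb, library["S2"], rng=np.random.default_rng(17))
        b = run_trial(small_lb, library["S2"], rng=np.random.default_rng(17))
        np.testing.assert_array_equal(a.patients.arm, b.patients.arm)
        np.testing.assert_array_equal(a.patients.outcome, b.patients.outcome)
        np.testing.assert_allclose(a.patient_alloc, b.patient_alloc)
        assert a.recommendations.rejected == b.recommendations.rejected

    def test_population_identical_across_variants(self, library):
        """Profiles, recruit times and outcome uniforms come from dedicated
        substreams, so accrual never depends on the design."""
        results = {
            v: run_trial(DesignConfig(variant=v, n_total=80, n_first_interim=30,
                              n_draws=1000),
                         library["S2"], rng=np.random.default_rng(23))
            for v in ("LB", "NLB", "PT", "ER")
        }
        base = results["ER"].patients
        for v in ("LB", "NLB", "PT"):
            pts = results[v].patients
            np.testing.assert_array_equal(pts.profile_idx, base.profile_idx)
            np.testing.assert_allclose(pts.recruit_time, base.recruit_time)

    def test_er_uses_a_single_flat_allocation(self, library):
        res = run_trial(DesignConfig(variant="ER", n_total=60, n_first_interim=20),
                        library["S1"], rng=np.random.default_rng(3))
        assert len(res.allocation_history) == 1
        np.testing.assert_allclose(res.allocation_history[0].probs, 0.25)
        np.testing.assert_allclose(res.patient_alloc, 0.25)

    def test_pt_never_assigns_unlinked_arms(self, library):
        res = run_trial(DesignConfig(variant="PT"),
                        library["S2"], rng=np.random.default_rng(4))
        pts = res.patients
        b1_only = pts.profile_idx == profile_index(1, 0, 0)
        assert set(np.unique(pts.arm[b1_only])) <= {0, 1}

    def test_outcome_delay_is_exact(self, library, small_lb):
        res = run_trial(small_lb, library["S1"], rng=np.random.default_rng(5))
        np.testing.assert_allclose(
            res.patients.outcome_time - res.patients.recruit_time, 6.0
        )

    def test_replaying_history_reproduces_every_allocation(self, library,
                                                           small_lb):
        res = run_trial(small_lb, library["S2"], rng=np.random.default_rng(29))
        assert len(res.posterior_history) >= 1
        np.testing.assert_allclose(replay_allocations(res), res.patient_alloc)

    def test_adaptive_allocation_rows_are_probability_vectors(self, library,
                                                              small_lb):
        res = run_trial(small_lb, library["S8"], rng=np.random.default_rng(31))
        sums = res.patient_alloc.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert np.all(res.patient_alloc >= 0)
        for table in res.allocation_history:
            np.testing.assert_allclose(table.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_harmful_arm_allocation_vanishes_without_delay(self, library):
        """With no outcome delay and many interims, the mean linked-BAR
        allocation to a strictly harmful arm in its profile falls away."""
        cfg = DesignConfig(variant="LB", n_total=350, n_first_interim=50,
                           n_stages=8, delay=0.0, n_draws=1000)
        b1_only = profile_index(1, 0, 0)
        traj = np.zeros((cfg.n_total, 4))
        n_reps = 60
        for rep in range(n_reps):
            res = run_trial(cfg, library["S5"],
                            rng=np.random.default_rng(1000 + rep),
                            track_profile=b1_only)
            traj += res.trajectory
        traj /= n_reps
        # T1 is detrimental for B1-positive patients: its mean allocation
        # starts at 0.5 and must collapse by the final stage
        assert traj[-20:, 1].mean() < 0.15

    def test_trial_json_round_trips_to_valid_document(self, library, small_lb):
        import json

        res = run_trial(small_lb, library["S2"], rng=np.random.default_rng(7))
        doc = json.loads(res.to_json())
        assert doc["scenario"] == "S2"
        assert len(doc["patients"]["arm"]) == 120
        assert set(doc["recommendations"]) == {"rejected", "any"}

    def test_patient_csv_export_columns(self, tmp_path, library, small_lb):
        import pandas as pd

        res = run_trial(small_lb, library["S1"], rng=np.random.default_rng(8))
        out = tmp_path / "patients.csv"
        res.patients.to_csv(out)
        frame = pd.read_csv(out)
        assert list(frame.columns) == [
            "index", "b1", "b2", "b3", "recruit_time", "arm", "outcome",
            "outcome_time",
        ]
        assert len(frame) == 120
        assert frame["recruit_time"].is_monotonic_increasing
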