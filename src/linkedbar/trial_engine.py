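"""Simulation of one complete trial under a chosen design variant.

The engine recruits patients along a uniform accrual schedule, assigns each
to an arm from the live allocation table, triggers interim analyses at fixed
recruitment counts, respects the outcome delay (only matured outcomes inform
an interim fit), and runs the final classical analysis once every outcome is
observed.  Everything is deterministic given (seed, design, scenario).

Recruitment is never paused: accrual times depend only on the accrual
schedule, so they are identical across design variants for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import allocation as alloc_mod
from .allocation import (
    AllocationTable,
    BarTuning,
    bar_weights,
    initial_allocation_table,
    is_adaptive,
)
from .bayes_interim import LINKED_PAIRS, PosteriorSummary, PriorSpec, fit_posterior
from .final_analysis import (
    HypothesisResult,
    RecommendationSet,
    fit_final_model,
    summarise,
    wald_statistics,
)
from .scenario_sim import ARMS, ScenarioSpec, build_accrual, sample_profile_indices

__all__ = [
    "DesignConfig",
    "PatientTable",
    "TrialResult",
    "interim_schedule",
    "available_outcomes",
    "run_trial",
    "replay_allocations",
]

logger = logging.getLogger(__name__)


@dataclass
class DesignConfig:
    """Full specification of one trial design.

    ``n_stages`` counts the final analysis, so the default of 5 means four
    interim analyses.  ``priors`` defaults to the linked informative priors
    for the LB variant and to all-flat priors otherwise.
    """

    variant: str = "LB"
    n_total: int = 350
    n_first_interim: int = 100
    n_stages: int = 5
    delay: float = 6.0
    accrual_duration: float = 36.0
    priors: PriorSpec | None = None
    tuning: BarTuning = field(default_factory=BarTuning)
    wald_threshold: float = 1.5
    n_draws: int = 4000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in alloc_mod.VARIANTS:
            raise ValueError(f"unknown design variant {self.variant!r}")
        if not 1 <= self.n_first_interim < self.n_total:
            raise ValueError("n_first_interim must be in [1, n_total)")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.priors is None:
            self.priors = (
                PriorSpec(linked_pairs=LINKED_PAIRS)
                if self.variant == "LB"
                else PriorSpec.flat()
            )

    @property
    def n_interims(self) -> int:
        return self.n_stages - 1

    def with_variant(self, variant: str) -> "DesignConfig":
        return replace(self, variant=variant, priors=None)

    def to_dict(self) -> dict:
        p = self.priors
        return {
            "variant": self.variant,
            "n_total": self.n_total,
            "n_first_interim": self.n_first_interim,
            "n_stages": self.n_stages,
            "delay": self.delay,
            "accrual_duration": self.accrual_duration,
            "priors": {
                "box_low": p.box_low, "box_high": p.box_high,
                "linked_mean": p.linked_mean, "linked_var": p.linked_var,
                "linked_pairs": sorted(list(pair) for pair in p.linked_pairs),
            },
            "tuning": {
                "power_scale": self.tuning.power_scale,
                "power_shape": self.tuning.power_shape,
                "control_gain": self.tuning.control_gain,
                "min_prob": self.tuning.min_prob,
            },
            "wald_threshold": self.wald_threshold,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        d = dict(d)
        if "priors" in d and d["priors"] is not None:
            p = dict(d["priors"])
            p["linked_pairs"] = frozenset(tuple(x) for x in p.get("linked_pairs", []))
            d["priors"] = PriorSpec(**p)
        if "tuning" in d and d["tuning"] is not None:
            d["tuning"] = BarTuning(**d["tuning"])
        return cls(**d)


class PatientTable:
    """Struct-of-arrays container for the recruited patients."""

    def __init__(self, bits, recruit_time, arm, outcome, outcome_time):
        self.bits = np.asarray(bits, dtype=np.int8)  # (n, 3)
        self.recruit_time = np.asarray(recruit_time, dtype=float)
        self.arm = np.asarray(arm, dtype=np.int8)
        self.outcome = np.asarray(outcome, dtype=np.int8)
        self.outcome_time = np.asarray(outcome_time, dtype=float)
        self.profile_idx = (self.bits @ np.array([4, 2, 1], dtype=np.int8)).astype(np.int8)

    def __len__(self) -> int:
        return len(self.arm)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "index": np.arange(1, len(self) + 1),
                "b1": self.bits[:, 0],
                "b2": self.bits[:, 1],
                "b3": self.bits[:, 2],
                "recruit_time": self.recruit_time,
                "arm": [ARMS[a] for a in self.arm],
                "outcome": self.outcome,
                "outcome_time": self.outcome_time,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class TrialResult:
    """Everything one simulated trial produced."""

    design: DesignConfig
    scenario_name: str
    patients: PatientTable
    allocation_history: list[AllocationTable]
    posterior_history: list[PosteriorSummary]
    patient_alloc: np.ndarray  # (n, 4) row actually used for each patient
    hypothesis_results: list[HypothesisResult]
    recommendations: RecommendationSet
    trajectory: np.ndarray | None = None  # (n, 4) live row for tracked profile
    interim_triggers: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "design": self.design.to_dict(),
                "scenario": self.scenario_name,
                "patients": self.patients.to_dataframe().to_dict(orient="list"),
                "allocation_history": [
                    {"stage": t.stage, "probs": t.probs.tolist()}
                    for t in self.allocation_history
                ],
                "wald": {r.hypothesis: r.wald for r in self.hypothesis_results},
                "recommendations": self.recommendations.to_dict(),
            }
        )


def interim_schedule(n_total: int, n_first: int, n_interims: int) -> list[int]:
    """Recruitment counts that trigger the interim analyses.

    The first interim fires at ``n_first`` recruits; the remaining
    ``n_interims - 1`` are equally spaced over the rest of recruitment
    (rounding half up).
    """
    if n_first >= n_total:
        raise ValueError("n_first must be < n_total")
    if n_interims < 1:
        raise ValueError("n_interims must be >= 1")
    gap = (n_total - n_first) / n_interims
    triggers = [n_first] + [
        n_first + int(np.floor(i * gap + 0.5)) for i in range(1, n_interims)
    ]
    if any(b <= a for a, b in zip(triggers, triggers[1:])):
        raise ValueError("interim schedule must be strictly increasing")
    return triggers


def available_outcomes(
    recruit_times: np.ndarray, now: float, delay: float
) -> np.ndarray:
    """Boolean mask of patients whose outcome has matured by ``now``."""
    return np.asarray(recruit_times) + delay <= now


def _categorical_rows(rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorised categorical draws, one per row (same arithmetic as
    :func:`linkedbar.allocation.assign_arm`)."""
    cum = np.cumsum(rows, axis=1)
    return np.clip((cum <= u[:, None]).sum(axis=1), 0, 3).astype(np.int8)


def run_trial(
    design: DesignConfig,
    scenario: ScenarioSpec,
    rng: np.random.Generator | None = None,
    track_profile: int | None = None,
) -> TrialResult:
    """Simulate one trial end to end.

    Patient-level randomness is split into independent substreams for
    biomarker profiles, outcomes, arm assignments and posterior draws, so
    the recruited population is identical across design variants for a
    fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    rng_profiles, rng_outcomes, rng_assign, rng_post = rng.spawn(4)

    n = design.n_total
    accrual = build_accrual(n, design.accrual_duration)
    profile_idx = sample_profile_indices(scenario.prevalence, n, rng_profiles)
    outcome_u = rng_outcomes.random(n)
    ptable = scenario.response_table()  # (4, 8)

    adaptive = is_adaptive(design.variant)
    triggers = (
        interim_schedule(n, design.n_first_interim, design.n_interims)
        if adaptive and design.n_interims >= 1
        else []
    )
    trigger_set = set(triggers)

    init_table = initial_allocation_table(design.variant)
    allocation_history: list[AllocationTable] = [init_table]
    posterior_history: list[PosteriorSummary] = []
    superiority: np.ndarray | None = None  # (8, 3) once the first refit runs

    arms = np.full(n, -1, dtype=np.int8)
    patient_alloc = np.empty((n, 4))
    trajectory = np.empty((n, 4)) if track_profile is not None else None
    counts = np.zeros((8, 4))

    if not adaptive:
        # static allocation: fully vectorised (identical stream consumption
        # to the sequential path: one uniform per patient)
        patient_alloc[:] = init_table.probs[profile_idx]
        arms[:] = _categorical_rows(patient_alloc, rng_assign.random(n))
        np.add.at(counts, (profile_idx, arms), 1)
        if trajectory is not None:
            trajectory[:] = init_table.probs[track_profile]
    else:
        assign_u = rng_assign.random(n)
        stage = 0
        for t in range(1, n + 1):
            b = int(profile_idx[t - 1])
            frac = (t - 1) / n
            if superiority is None:
                row = init_table.probs[b]
            else:
                row = bar_weights(superiority[b], counts[b], design.tuning,
                                  frac=frac)
            if trajectory is not None:
                if superiority is None:
                    trajectory[t - 1] = init_table.probs[track_profile]
                else:
                    trajectory[t - 1] = bar_weights(
                        superiority[track_profile], counts[track_profile],
                        design.tuning, frac=frac,
                    )
            arm = int(np.clip(np.searchsorted(np.cumsum(row), assign_u[t - 1],
                                              side="right"), 0, 3))
            arms[t - 1] = arm
            patient_alloc[t - 1] = row
            counts[b, arm] += 1

            if t in trigger_set:
                now = accrual.recruit_times[t - 1]
                avail = available_outcomes(
                    accrual.recruit_times[:t], now, design.delay
                )
                stage += 1
                if not avail.any():
                    logger.info(
                        "interim at %d recruits skipped: no matured outcomes", t
                    )
                    continue
                obs = np.flatnonzero(avail)
                outcomes_obs = (
                    outcome_u[obs] < ptable[arms[obs], profile_idx[obs]]
                ).astype(float)
                summary = fit_posterior(
                    arms[obs], profile_idx[obs], outcomes_obs,
                    priors=design.priors, n_draws=design.n_draws, rng=rng_post,
                )
                posterior_history.append(summary)
                superiority = summary.superiority
                logger.info(
                    "interim refit: stage=%d recruits=%d outcomes=%d "
                    "superiority_crc=%08x", stage, t, summary.n_outcomes,
                    zlib.crc32(superiority.tobytes()),
                )
                snapshot = np.stack(
                    [bar_weights(superiority[i], counts[i], design.tuning,
                                 frac=t / n)
                     for i in range(8)]
                )
                allocation_history.append(
                    AllocationTable(probs=snapshot, stage=stage)
                )

    outcomes = (outcome_u < ptable[arms, profile_idx]).astype(np.int8)
    patients = PatientTable(
        bits=np.stack([(profile_idx >> 2) & 1, (profile_idx >> 1) & 1,
                       profile_idx & 1], axis=1),
        recruit_time=accrual.recruit_times,
        arm=arms,
        outcome=outcomes,
        outcome_time=accrual.recruit_times + design.delay,
    )

    fit = fit_final_model(arms, profile_idx, outcomes)
    results = wald_statistics(fit, threshold=design.wald_threshold)
    recs = summarise(results)

    return TrialResult(
        design=design,
        scenario_name=scenario.name,
        patients=patients,
        allocation_history=allocation_history,
        posterior_history=posterior_history,
        patient_alloc=patient_alloc,
        hypothesis_results=results,
        recommendations=recs,
        trajectory=trajectory,
        interim_triggers=triggers,
    )


def replay_allocations(result: TrialResult) -> np.ndarray:
    """Recompute every patient's allocation row from the recorded posterior
    history and the patient table (audit helper: must equal
    ``result.patient_alloc``)."""
    design = result.design
    n = len(result.patients)
    init_table = initial_allocation_table(design.variant)
    profile_idx = result.patients.profile_idx
    arms = result.patients.arm
    rows = np.empty((n, 4))
    if not is_adaptive(design.variant):
        rows[:] = init_table.probs[profile_idx]
        return rows

    refits = {}  # trigger count -> superiority table, in firing order
    fired = iter(result.posterior_history)
    # posterior history entries correspond, in order, to triggers that had
    # matured outcomes; reconstruct which using the delay arithmetic
    for t in result.interim_triggers:
        now = result.patients.recruit_time[t - 1]
        if available_outcomes(result.patients.recruit_time[:t], now,
                              design.delay).any():
            refits[t] = next(fired).superiority

    counts = np.zeros((8, 4))
    superiority = None
    for t in range(1, n + 1):
        b = int(profile_idx[t - 1])
        if superiority is None:
            rows[t - 1] = init_table.probs[b]
        else:
            rows[t - 1] = bar_weights(superiority[b], counts[b], design.tuning,
                                      frac=(t - 1) / n)
        counts[b, arms[t - 1]] += 1
        if t in refits:
            superiority = refits[t]
    return rows
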