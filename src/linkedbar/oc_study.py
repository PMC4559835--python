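"""Monte-Carlo operating characteristics of the four trial designs.

Estimates recommendation probabilities (power under effect scenarios, the
family-wise error rate under the global null) by simulating independent
replicate trials, plus mean allocation-trajectory curves and sensitivity
sweeps over biomarker prevalence, recruitment rate, number of stages and the
linked-interaction prior mean.

Replicate seeds are indexed by replicate id (``SeedSequence(seed,
spawn_key=(rep,))``), so results do not depend on worker scheduling and
split runs pool exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bayes_interim import PriorSpec
from .final_analysis import HYPOTHESES
from .scenario_sim import ScenarioSpec
from .trial_engine import DesignConfig, run_trial

__all__ = [
    "OCRow",
    "SweepResult",
    "run_oc",
    "allocation_trajectory",
    "prevalence_sweep",
    "sensitivity_grid",
]

logger = logging.getLogger(__name__)

REC_KEYS = tuple(list(HYPOTHESES) + ["any"])


@dataclass
class OCRow:
    """One design x scenario row of estimated recommendation probabilities."""

    design: str
    scenario: str
    n_reps: int
    rec_probs: dict[str, float]
    mc_se: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        row = {"design": self.design, "scenario": self.scenario,
               "n_reps": self.n_reps}
        row.update(self.rec_probs)
        row.update({f"se_{k}": v for k, v in self.mc_se.items()})
        return pd.DataFrame([row])


@dataclass
class SweepResult:
    """Power along a one-dimensional parameter grid."""

    axis: str
    grid: np.ndarray
    table: pd.DataFrame  # columns: value, design, hypothesis, power, mc_se


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))


def _rejection_flags(design: DesignConfig, scenario: ScenarioSpec,
                     seed: int, rep: int) -> np.ndarray:
    res = run_trial(design, scenario, rng=_replicate_rng(seed, rep))
    rejected = set(res.recommendations.rejected)
    flags = np.fromiter((h in rejected for h in HYPOTHESES), dtype=bool,
                        count=len(HYPOTHESES))
    return np.append(flags, flags.any())


def run_oc(
    design: DesignConfig,
    scenario: ScenarioSpec,
    n_reps: int,
    seed: int,
    workers: int = 1,
    rep_start: int = 0,
) -> OCRow:
    """Estimate the 12 recommendation probabilities plus "recommend any".

    ``rep_start`` offsets the replicate ids so that split runs
    (``rep_start=0, n_reps=k`` and ``rep_start=k, n_reps=m-k``) pool to
    exactly the same counts as one run of ``m`` replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    reps = range(rep_start, rep_start + n_reps)
    if workers > 1:
        from joblib import Parallel, delayed

        flags = Parallel(n_jobs=workers)(
            delayed(_rejection_flags)(design, scenario, seed, r) for r in reps
        )
    else:
        flags = [_rejection_flags(design, scenario, seed, r) for r in reps]
    mat = np.asarray(flags, dtype=float)  # (n_reps, 13), replicate-id order
    p = mat.mean(axis=0)
    se = np.sqrt(p * (1.0 - p) / n_reps)
    return OCRow(
        design=design.variant,
        scenario=scenario.name,
        n_reps=n_reps,
        rec_probs=dict(zip(REC_KEYS, p)),
        mc_se=dict(zip(REC_KEYS, se)),
    )


def allocation_trajectory(
    design: DesignConfig,
    scenario: ScenarioSpec,
    profile: int,
    n_reps: int,
    seed: int,
) -> pd.DataFrame:
    """Mean live allocation row for one biomarker profile at each
    recruitment index, averaged over replicates.

    Returns a tidy frame with columns ``index, control, T1, T2, T3``.
    """
    total = np.zeros((design.n_total, 4))
    for rep in range(n_reps):
        res = run_trial(design, scenario, rng=_replicate_rng(seed, rep),
                        track_profile=profile)
        total += res.trajectory
    mean = total / n_reps
    from .scenario_sim import ARMS

    out = pd.DataFrame(mean, columns=list(ARMS))
    out.insert(0, "index", np.arange(1, design.n_total + 1))
    return out


def _power_for(design: DesignConfig, scenario: ScenarioSpec, hypothesis: str,
               n_reps: int, seed: int, workers: int = 1) -> tuple[float, float]:
    row = run_oc(design, scenario, n_reps, seed, workers=workers)
    return row.rec_probs[hypothesis], row.mc_se[hypothesis]


def prevalence_sweep(
    designs: list[DesignConfig],
    scenario: ScenarioSpec,
    grid: np.ndarray | None = None,
    n_reps: int = 500,
    seed: int = 0,
    workers: int = 1,
    hypothesis: str = "T1_in_B1",
) -> SweepResult:
    """Power to recommend T1 in B1-positive patients as the prevalence of B1
    varies (B2 and B3 keep their scenario value)."""
    if grid is None:
        grid = np.arange(0.1, 0.5 + 1e-9, 0.025)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 1) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing within (0, 1)")
    rows = []
    for v in grid:
        prev = scenario.prevalence.copy()
        prev[0] = v
        sc = replace(scenario, prevalence=prev)
        for design in designs:
            power, se = _power_for(design, sc, hypothesis, n_reps, seed, workers)
            rows.append({"value": v, "design": design.variant,
                         "hypothesis": hypothesis, "power": power, "mc_se": se})
    return SweepResult(axis="prevalence_B1", grid=grid,
                       table=pd.DataFrame(rows))


def sensitivity_grid(
    axis: str,
    values,
    design: DesignConfig,
    scenario: ScenarioSpec,
    n_reps: int = 500,
    seed: int = 0,
    workers: int = 1,
) -> SweepResult:
    """Power along one design-parameter axis.

    Axes: ``n_stages`` (total stages, 1 = no interims), ``prior_mean``
    (linked-interaction prior mean; reports linked T1-in-B1 and unlinked
    T1-in-B2 power) and ``recruitment_rate`` (patients per month; the
    accrual duration is ``n_total / rate`` with the outcome delay fixed).
    """
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(values) <= 0):
        raise ValueError("values must be strictly increasing")
    rows = []
    for v in values:
        if axis == "n_stages":
            cfg = replace(design, n_stages=int(v))
        elif axis == "prior_mean":
            cfg = replace(design, priors=PriorSpec(
                box_low=design.priors.box_low,
                box_high=design.priors.box_high,
                linked_mean=float(v),
                linked_var=design.priors.linked_var,
                linked_pairs=design.priors.linked_pairs,
            ))
        elif axis == "recruitment_rate":
            cfg = replace(design, accrual_duration=design.n_total / float(v))
        else:
            raise ValueError(f"unknown sensitivity axis {axis!r}")
        hyps = ("T1_in_B1", "T1_in_B2") if axis == "prior_mean" else ("T1_in_B1",)
        oc = run_oc(cfg, scenario, n_reps, seed, workers=workers)
        for h in hyps:
            rows.append({"value": v, "design": cfg.variant, "hypothesis": h,
                         "power": oc.rec_probs[h], "mc_se": oc.mc_se[h]})
    return SweepResult(axis=axis, grid=values, table=pd.DataFrame(rows))
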