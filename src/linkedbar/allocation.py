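"""Randomisation probabilities per biomarker profile.

Four design variants are supported:

* ``LB`` (linked BAR): start with equal allocation over control and the
  experimental arms linked to the patient's positive biomarkers, then adapt
  using the interim superiority probabilities.
* ``NLB`` (non-linked BAR): start with equal allocation over all four arms,
  adapt the same way but with no informative priors in the interim model.
* ``PT`` (parallel stratified trials): the linked initial rule throughout,
  no adaptation.
* ``ER`` (equal randomisation): 1/4 to every arm throughout.

Between interim analyses the superiority probabilities are frozen, but the
control arm's allocation is recomputed after every recruit from the live
per-profile arm counts, steering the expected control count toward the count
of the best-recruited experimental arm (control matching).  Experimental
weights are proportional to the posterior superiority probabilities; the
control weight anchors to the largest experimental weight and is multiplied
by ``exp(eta * (n_star - n_0) / (n_b + 1))`` where ``n_star`` is the count on
the best-recruited experimental arm, ``n_0`` the control count and ``n_b``
the number of patients with this profile so far.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .scenario_sim import PROFILE_BITS, BiomarkerProfile

__all__ = [
    "VARIANTS",
    "BarTuning",
    "AllocationTable",
    "initial_allocation",
    "initial_allocation_table",
    "bar_weights",
    "assign_arm",
]

logger = logging.getLogger(__name__)

VARIANTS = ("LB", "NLB", "PT", "ER")
_ADAPTIVE = frozenset({"LB", "NLB"})


def is_adaptive(variant: str) -> bool:
    return variant in _ADAPTIVE


@dataclass(frozen=True)
class BarTuning:
    """Tuning constants of the adaptive allocation rule.

    The exponent applied to the superiority probabilities increases with
    the fraction of recruitment completed: ``h(t) = a (t/N)^b`` with scale
    ``a = power_scale`` and shape ``b = power_shape``.  Early in the trial
    the allocation is close to balanced; late in the trial it concentrates
    sharply on the better-performing arms.  Setting ``power_scale`` to a
    value and ``power_shape = 0`` recovers a constant exponent.

    control_gain
        Sensitivity ``eta`` of the control-matching correction.
    min_prob
        Optional floor applied to every arm's probability before
        renormalisation (0 = no floor).
    """

    power_scale: float = 3.0
    power_shape: float = 0.5
    control_gain: float = 1.25
    min_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.power_scale < 0:
            raise ValueError("power_scale must be >= 0")
        if self.power_shape < 0:
            raise ValueError("power_shape must be >= 0")
        if self.control_gain < 0:
            raise ValueError("control_gain must be >= 0")
        if not 0.0 <= self.min_prob < 0.25:
            raise ValueError("min_prob must lie in [0, 0.25)")

    def exponent(self, frac: float) -> float:
        """Exponent on the superiority probabilities at recruitment
        fraction ``frac`` (0 = trial start, 1 = full accrual)."""
        if not 0.0 <= frac <= 1.0:
            raise ValueError("frac must lie in [0, 1]")
        return self.power_scale * frac ** self.power_shape if self.power_shape else self.power_scale


@dataclass
class AllocationTable:
    """Per-profile randomisation probabilities over (control, T1, T2, T3)."""

    probs: np.ndarray  # (8, 4)
    stage: int

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (8, 4):
            raise ValueError("probs must be 8x4")
        if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("each profile row must be a probability vector")
        self.probs = probs

    def row(self, profile: BiomarkerProfile | int) -> np.ndarray:
        idx = profile.index if isinstance(profile, BiomarkerProfile) else int(profile)
        return self.probs[idx]

    def to_frame(self):
        import pandas as pd

        from .scenario_sim import ARMS, PROFILES

        rows = [
            {"stage": self.stage, "profile": p.key,
             **{arm: self.probs[p.index, a] for a, arm in enumerate(ARMS)}}
            for p in PROFILES
        ]
        return pd.DataFrame(rows)


def initial_allocation(profile: BiomarkerProfile | int, variant: str) -> np.ndarray:
    """Initial-stage randomisation row for one profile.

    LB and PT put equal mass on control plus the experimental arms linked to
    the patient's positive biomarkers (all-negative patients: 1/4 to every
    arm).  NLB and ER use 1/4 everywhere.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown design variant {variant!r}")
    idx = profile.index if isinstance(profile, BiomarkerProfile) else int(profile)
    if variant in ("NLB", "ER"):
        return np.full(4, 0.25)
    bits = PROFILE_BITS[idx]
    row = np.zeros(4)
    row[0] = 1.0
    row[1:] = bits
    if bits.sum() == 0:
        row[:] = 1.0
    return row / row.sum()


def initial_allocation_table(variant: str) -> AllocationTable:
    probs = np.stack([initial_allocation(b, variant) for b in range(8)])
    return AllocationTable(probs=probs, stage=0)


def bar_weights(
    superiority: np.ndarray,
    counts: np.ndarray,
    tuning: BarTuning = BarTuning(),
    frac: float = 1.0,
) -> np.ndarray:
    """Adaptive randomisation probabilities for one profile.

    Parameters
    ----------
    superiority
        ``(p_1(b), p_2(b), p_3(b))`` from the latest interim fit.
    counts
        Patients with this profile recruited so far on
        (control, T1, T2, T3).
    frac
        Fraction of total recruitment completed; sets the exponent applied
        to the superiority probabilities (see :class:`BarTuning`).

    Returns the normalised 4-vector of randomisation probabilities.
    """
    p = np.asarray(superiority, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if p.shape != (3,) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("superiority must be three probabilities")
    if counts.shape != (4,) or np.any(counts < 0):
        raise ValueError("counts must be four non-negative numbers")

    w = p ** tuning.exponent(frac)
    if np.all(w == 0.0):
        # degenerate posterior: equal over control + any arm with p_k > 0
        row = np.zeros(4)
        row[0] = 1.0
        row[1:][p > 0] = 1.0
        logger.warning("all BAR weights zero; falling back to equal allocation")
        return row / row.sum()

    # n_star = count on the best-recruited experimental arm (ties are
    # immaterial: only the count value enters the formula)
    n_star = counts[1:].max()
    n_b = counts.sum()
    w0 = w.max() * np.exp(tuning.control_gain * (n_star - counts[0]) / (n_b + 1.0))

    full = np.concatenate([[w0], w])
    probs = full / full.sum()
    if tuning.min_prob > 0.0:
        probs = np.maximum(probs, tuning.min_prob)
        probs = probs / probs.sum()
    return probs


def assign_arm(alloc_row: np.ndarray, rng: np.random.Generator) -> int:
    """One categorical draw from a 4-vector of arm probabilities."""
    alloc_row = np.asarray(alloc_row, dtype=float)
    if abs(alloc_row.sum() - 1.0) > 1e-9:
        raise ValueError("allocation row must sum to 1")
    u = rng.random()
    return int(np.searchsorted(np.cumsum(alloc_row), u, side="right").clip(0, 3))
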