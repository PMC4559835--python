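"""Synthetic patients for biomarker-stratified multi-arm trial simulation.

The simulated population carries three binary biomarkers (B1, B2, B3),
independently positive with configurable prevalence, giving eight possible
biomarker profiles.  A binary response (e.g. pathologic complete response)
is generated from a logistic model with an intercept ``mu``, treatment main
effects ``theta_k`` for the three experimental arms T1-T3, biomarker main
effects ``beta_j`` and treatment-by-biomarker interactions ``gamma_kj``, all
on the log-odds scale.  Accrual is uniform: ``n_total`` patients over a
fixed duration, with outcomes observed after a fixed delay.

A library of eight named truth scenarios is provided, covering a global
null, linked and unlinked beneficial interactions, a global main effect,
and detrimental interactions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "ARMS",
    "CONTROL",
    "BiomarkerProfile",
    "PROFILES",
    "profile_index",
    "ScenarioSpec",
    "AccrualSchedule",
    "sample_profile",
    "sample_outcome",
    "response_probability",
    "build_accrual",
    "scenario_library",
    "DOUBLING_EFFECT",
    "DETRIMENTAL_EFFECT",
]

#: Arm labels in canonical order; index 0 is the control arm.
ARMS = ("control", "T1", "T2", "T3")
CONTROL = 0

#: Log-odds shift that doubles the response probability from 0.30 to 0.60.
DOUBLING_EFFECT = float(logit(0.6) - logit(0.3))
#: Log-odds shift that drops the response probability from 0.30 to 0.11.
DETRIMENTAL_EFFECT = float(logit(0.11) - logit(0.3))


@dataclass(frozen=True)
class BiomarkerProfile:
    """Positive/negative status for the three biomarkers."""

    b1: int
    b2: int
    b3: int

    def __post_init__(self) -> None:
        for v in (self.b1, self.b2, self.b3):
            if v not in (0, 1):
                raise ValueError("biomarker indicators must be 0 or 1")

    @property
    def bits(self) -> tuple[int, int, int]:
        return (self.b1, self.b2, self.b3)

    @property
    def index(self) -> int:
        """Unique profile index in 0..7 (b1 is the high bit)."""
        return 4 * self.b1 + 2 * self.b2 + self.b3

    @property
    def key(self) -> str:
        """Bit-string key ``"b1b2b3"`` used in exports."""
        return f"{self.b1}{self.b2}{self.b3}"

    @classmethod
    def from_index(cls, index: int) -> "BiomarkerProfile":
        if not 0 <= index <= 7:
            raise ValueError("profile index must be in 0..7")
        return cls((index >> 2) & 1, (index >> 1) & 1, index & 1)


#: All eight profiles, ordered by index.
PROFILES = tuple(BiomarkerProfile.from_index(i) for i in range(8))

#: (8, 3) array of biomarker indicators, row i = profile with index i.
PROFILE_BITS = np.array([p.bits for p in PROFILES], dtype=np.int8)


def profile_index(b1: int, b2: int, b3: int) -> int:
    return BiomarkerProfile(b1, b2, b3).index


@dataclass
class ScenarioSpec:
    """A simulation truth: biomarker prevalences plus logistic coefficients.

    Parameters
    ----------
    prevalence
        Marginal probability that each biomarker is positive; biomarkers are
        assigned independently.
    mu, theta, beta, gamma
        Intercept, treatment main effects (length 3), biomarker main effects
        (length 3) and treatment-by-biomarker interactions (3x3, entry
        ``[k, j]`` = arm ``k+1`` x biomarker ``j+1``), all log-odds.
    """

    name: str
    prevalence: np.ndarray
    mu: float
    theta: np.ndarray = field(default_factory=lambda: np.zeros(3))
    beta: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gamma: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    description: str = ""

    def __post_init__(self) -> None:
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.prevalence.shape != (3,):
            raise ValueError("prevalence must have length 3")
        if np.any(self.prevalence < 0) or np.any(self.prevalence > 1):
            raise ValueError("prevalences must lie in [0, 1]")
        if self.theta.shape != (3,) or self.beta.shape != (3,):
            raise ValueError("theta and beta must have length 3")
        if self.gamma.shape != (3, 3):
            raise ValueError("gamma must be 3x3")

    def response_probability(self, arm: int, profile: BiomarkerProfile) -> float:
        """True response probability for a patient on ``arm`` with ``profile``."""
        return float(self.response_table()[arm, profile.index])

    def response_table(self) -> np.ndarray:
        """(4, 8) table of response probabilities by (arm, profile index)."""
        eta = np.empty((4, 8))
        base = self.mu + PROFILE_BITS @ self.beta  # (8,)
        eta[CONTROL] = base
        for k in range(3):
            eta[k + 1] = base + self.theta[k] + PROFILE_BITS @ self.gamma[k]
        return expit(eta)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "prevalence": self.prevalence.tolist(),
            "mu": self.mu,
            "theta": self.theta.tolist(),
            "beta": self.beta.tolist(),
            "gamma": self.gamma.reshape(-1).tolist(),  # row-major, arm-by-biomarker
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            name=d["name"],
            prevalence=np.asarray(d["prevalence"], dtype=float),
            mu=float(d["mu"]),
            theta=np.asarray(d.get("theta", np.zeros(3)), dtype=float),
            beta=np.asarray(d.get("beta", np.zeros(3)), dtype=float),
            gamma=np.asarray(d.get("gamma", np.zeros(9)), dtype=float).reshape(3, 3),
            description=d.get("description", ""),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "ScenarioSpec":
        return cls.from_dict(json.loads(s))


@dataclass
class AccrualSchedule:
    """Deterministic uniform accrual: constant inter-arrival gap."""

    n_total: int
    duration: float
    recruit_times: np.ndarray

    @property
    def rate(self) -> float:
        """Average accrual rate in patients per month."""
        return self.n_total / self.duration


def build_accrual(n_total: int, duration: float) -> AccrualSchedule:
    """Uniform accrual of ``n_total`` patients over ``duration`` months.

    Patient ``i`` (1-based) is recruited at ``duration * i / n_total``, so
    the last patient arrives exactly at ``duration``.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    times = duration * np.arange(1, n_total + 1) / n_total
    return AccrualSchedule(n_total=n_total, duration=float(duration), recruit_times=times)


def sample_profile(prevalence: np.ndarray, rng: np.random.Generator) -> BiomarkerProfile:
    """Draw one biomarker profile, each marker independently positive."""
    prevalence = np.asarray(prevalence, dtype=float)
    if prevalence.shape != (3,) or np.any(prevalence < 0) or np.any(prevalence > 1):
        raise ValueError("prevalence must be three probabilities in [0, 1]")
    bits = (rng.random(3) < prevalence).astype(int)
    return BiomarkerProfile(*bits)


def sample_profile_indices(
    prevalence: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised draw of ``n`` profile indices (same stream order as
    ``n`` successive :func:`sample_profile` calls)."""
    prevalence = np.asarray(prevalence, dtype=float)
    bits = (rng.random((n, 3)) < prevalence).astype(np.int8)
    return bits @ np.array([4, 2, 1], dtype=np.int8)


def sample_outcome(p: float, rng: np.random.Generator) -> int:
    """One Bernoulli(``p``) response draw."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("response probability must lie in [0, 1]")
    return int(rng.random() < p)


def response_probability(
    spec: ScenarioSpec, arm: int, profile: BiomarkerProfile
) -> float:
    """Inverse-logit of the scenario's linear predictor for (arm, profile)."""
    if arm not in range(4):
        raise ValueError("arm must be 0 (control) or 1..3")
    return spec.response_probability(arm, profile)


def scenario_library(prevalence: float = 0.3) -> dict[str, ScenarioSpec]:
    """The eight canonical truth scenarios.

    All scenarios share a 30% control response everywhere (``mu`` =
    logit(0.3), ``beta`` = 0).  Beneficial interactions raise the response
    to 60% in the affected subgroup; detrimental interactions lower it to
    11%.  Scenario 4 instead gives T1 a moderate benefit (+0.63 log-odds)
    in every subgroup.
    """
    mu = float(logit(0.3))
    up, down = DOUBLING_EFFECT, DETRIMENTAL_EFFECT
    prev = np.full(3, prevalence)

    def make(name, desc, theta=None, gamma_entries=()):
        gamma = np.zeros((3, 3))
        for (k, j), v in gamma_entries:
            gamma[k - 1, j - 1] = v
        theta_vec = np.zeros(3)
        if theta is not None:
            theta_vec[0] = theta
        return ScenarioSpec(
            name=name, prevalence=prev.copy(), mu=mu, theta=theta_vec,
            gamma=gamma, description=desc,
        )

    return {
        "S1": make("S1", "global null: every arm matches control everywhere"),
        "S2": make("S2", "T1 doubles response 0.30->0.60 in B1-positive patients",
                   gamma_entries=[((1, 1), up)]),
        "S3": make("S3", "T1 doubles response 0.30->0.60 in B2-positive patients",
                   gamma_entries=[((1, 2), up)]),
        "S4": make("S4", "T1 gives a moderate benefit in all biomarker groups",
                   theta=0.63),
        "S5": make("S5", "T1 drops response 0.30->0.11 in B1-positive patients",
                   gamma_entries=[((1, 1), down)]),
        "S6": make("S6", "T1 drops response 0.30->0.11 in B2-positive patients",
                   gamma_entries=[((1, 2), down)]),
        "S7": make("S7", "T1 beneficial in B1-positive, detrimental in B2-positive",
                   gamma_entries=[((1, 1), up), ((1, 2), down)]),
        "S8": make("S8", "T1 detrimental and T2 beneficial in B1-positive patients",
                   gamma_entries=[((1, 1), down), ((2, 1), up)]),
    }
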