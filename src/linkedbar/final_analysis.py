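"""Final classical analysis: logistic regression and 12 one-sided Wald tests.

Once every patient's outcome is observed, the same 16-coefficient logistic
model used at the interims is refitted by maximum likelihood (no priors, so
the conclusions rest on trial data alone).  Twelve null hypotheses are then
tested, each one-sided in the benefit direction:

* treatment k in patients positive for biomarker j (9 tests): contrast
  ``theta_k + gamma_kj``;
* treatment k in patients negative for all biomarkers (3 tests): contrast
  ``theta_k``.

A hypothesis is rejected when its Wald statistic (contrast estimate over its
standard error from the fit covariance) exceeds 1.5, i.e. a one-sided
p-value below about 0.067 — a deliberately lenient phase II threshold.

Adaptive designs routinely starve poor arms, so empty (arm x profile) cells
and separation are expected; the fit falls back to Firth bias-reduced
logistic regression whenever plain ML fails to converge, and columns with no
data at all are dropped (their contrasts report a statistic of 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._logistic import fit_firth, fit_ml
from .bayes_interim import N_COEF, ModelCoefficients, build_design_matrix

__all__ = [
    "HYPOTHESES",
    "FinalFit",
    "HypothesisResult",
    "RecommendationSet",
    "fit_final_model",
    "wald_statistics",
    "summarise",
    "WALD_THRESHOLD",
]

logger = logging.getLogger(__name__)

WALD_THRESHOLD = 1.5

#: The 12 hypothesis ids: treatment k in B_j-positive patients (9), and
#: treatment k in all-biomarker-negative patients (3).
HYPOTHESES = tuple(
    [f"T{k}_in_B{j}" for k in (1, 2, 3) for j in (1, 2, 3)]
    + [f"T{k}_in_neg" for k in (1, 2, 3)]
)


def _contrast_vector(hypothesis: str) -> np.ndarray:
    c = np.zeros(N_COEF)
    k = int(hypothesis[1])
    c[k] = 1.0  # theta_k
    if hypothesis.endswith("neg"):
        return c
    j = int(hypothesis[-1])
    c[7 + 3 * (k - 1) + (j - 1)] = 1.0  # gamma_kj
    return c


_CONTRASTS = {h: _contrast_vector(h) for h in HYPOTHESES}


@dataclass
class FinalFit:
    """Classical logistic fit on the complete trial."""

    coefficients: ModelCoefficients
    covariance: np.ndarray  # (16, 16); NaN rows/cols for dropped columns
    converged: bool
    method: str  # "ml", "firth" or "null" (total failure sentinel)
    estimable: np.ndarray  # bool mask over the 16 coefficients


@dataclass(frozen=True)
class HypothesisResult:
    hypothesis: str
    wald: float
    rejected: bool


@dataclass
class RecommendationSet:
    rejected: tuple[str, ...]
    any: bool

    def to_dict(self) -> dict:
        return {"rejected": list(self.rejected), "any": self.any}


def fit_final_model(arms: np.ndarray, profile_idx: np.ndarray,
                    outcomes: np.ndarray) -> FinalFit:
    """ML logistic fit of the 16-column model, Firth on failure.

    Columns that are identically zero (no patient contributes) are dropped
    before fitting and marked non-estimable.  If even the Firth fit fails,
    an empty-fit sentinel with zero coefficients is returned so that no
    hypothesis is rejected.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    X_full, _ = build_design_matrix(arms, profile_idx)
    active = X_full.any(axis=0)
    X = X_full[:, active]

    coef = np.zeros(N_COEF)
    cov = np.full((N_COEF, N_COEF), np.nan)

    res = fit_ml(X, outcomes)
    if not res.converged:
        res = fit_firth(X, outcomes)
    if not res.converged or not np.all(np.isfinite(res.cov)):
        logger.warning("final model fit failed entirely; returning null fit")
        return FinalFit(
            coefficients=ModelCoefficients.from_vector(coef),
            covariance=cov, converged=False, method="null", estimable=active,
        )

    coef[active] = res.coef
    ix = np.flatnonzero(active)
    cov[np.ix_(ix, ix)] = res.cov
    return FinalFit(
        coefficients=ModelCoefficients.from_vector(coef),
        covariance=cov, converged=True, method=res.method, estimable=active,
    )


def wald_statistics(
    fit: FinalFit, threshold: float = WALD_THRESHOLD
) -> list[HypothesisResult]:
    """One-sided Wald statistics for the 12 hypotheses.

    Rejection requires the contrast to be positive (benefit direction) with
    statistic above ``threshold``; non-estimable contrasts report 0.
    """
    coef = fit.coefficients.to_vector()
    results = []
    for h in HYPOTHESES:
        c = _CONTRASTS[h]
        involved = c > 0
        if fit.method == "null" or not np.all(fit.estimable[involved]):
            results.append(HypothesisResult(h, 0.0, False))
            continue
        est = float(c @ coef)
        var = float(c @ fit.covariance @ c)
        if not np.isfinite(var) or var <= 0.0:
            logger.warning("non-estimable contrast %s; statistic set to 0", h)
            results.append(HypothesisResult(h, 0.0, False))
            continue
        stat = est / np.sqrt(var)
        results.append(HypothesisResult(h, stat, bool(stat > threshold)))
    return results


def summarise(results: list[HypothesisResult]) -> RecommendationSet:
    """Collect rejected hypotheses; ``any`` flags at least one rejection."""
    if len(results) != len(HYPOTHESES):
        raise ValueError(f"expected {len(HYPOTHESES)} hypothesis results")
    rejected = tuple(r.hypothesis for r in results if r.rejected)
    return RecommendationSet(rejected=rejected, any=bool(rejected))
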