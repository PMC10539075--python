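"""Misclassification-induced attenuation of SNP effects, and its correction.

Imputed disease labels are sometimes wrong.  Let gamma0 be the probability
that a true control enters the analysis labeled as a case and gamma1 the
probability that a true case enters labeled as a control.  Non-differential
misclassification of a binary outcome attenuates a small logistic
coefficient by an approximate multiplicative factor

    B = (1 - gamma1 - gamma0) / [(1 + gamma1 - gamma0) (1 - gamma1 + gamma0)],

which is 1 at perfect classification and 1 - 2*gamma in the symmetric case
gamma0 = gamma1 = gamma.  (This closed form is our parse of a typographically
garbled display; it is validated against a Monte-Carlo attenuation oracle in
the test suite.)

Only the *direct* part of the SNP effect is attenuated: the prediction model
is built from the mediating endophenotypes, so the mediated (indirect) part
of the SNP signal survives imputation.  With d* the proportion of direct
effect, the observed coefficient satisfies beta* ~ (B d* + 1 - d*) beta, and
the corrected estimate is

    beta_adj = beta* / (B d* + 1 - d*).

The correction applies to reported effect sizes / odds ratios only -- never
to p-values; hypothesis testing is unaffected by the attenuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MisclassRates",
    "BiasModel",
    "bias_factor",
    "misclass_rates_from_model",
    "cohort_rates_from_counts",
    "estimate_direct_proportion",
    "adjust_coefficient",
    "adjust_odds_ratio",
]


@dataclass(frozen=True)
class MisclassRates:
    """gamma0: P(labeled case | true control); gamma1: P(labeled control | true case)."""

    gamma0: float
    gamma1: float

    def __post_init__(self) -> None:
        if not (0 <= self.gamma0 < 1 and 0 <= self.gamma1 < 1):
            raise ValueError("misclassification rates must lie in [0, 1)")
        if self.gamma0 + self.gamma1 >= 1:
            raise ValueError(
                "gamma0 + gamma1 >= 1: classification is no better than label-flipping, "
                "the attenuation direction is unidentifiable"
            )


@dataclass(frozen=True)
class BiasModel:
    """Everything needed to adjust one coefficient for label misclassification."""

    d_star: float
    b_hat: float
    rho: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.d_star <= 1:
            raise ValueError("d* must lie in [0, 1]")
        if self.b_hat <= 0:
            raise ValueError("bias factor must be positive")


def bias_factor(rates: MisclassRates) -> float:
    """Approximate multiplicative attenuation of a small logistic coefficient."""
    g0, g1 = rates.gamma0, rates.gamma1
    return (1 - g1 - g0) / ((1 + g1 - g0) * (1 - g1 + g0))


def misclass_rates_from_model(
    rho: float, sensitivity: float, specificity: float
) -> MisclassRates:
    """Misclassification rates of the *imputed stratum* from model accuracy.

    gamma1 = 1 - sensitivity, gamma0 = 1 - specificity.  ``rho`` (the assumed
    true case fraction among imputed subjects) does not alter the stratum
    rates; it is carried by the caller into the cohort-level mixing (see
    ``cohort_rates_from_counts``).
    """
    for name, v in (("rho", rho), ("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return MisclassRates(gamma0=1 - specificity, gamma1=1 - sensitivity)


def cohort_rates_from_counts(
    n_cases_labeled: float,
    n_controls_labeled: float,
    n_imputed: float,
    rho: float,
    sensitivity: float,
    specificity: float,
) -> MisclassRates:
    """Cohort-level misclassification rates when only a stratum is imputed.

    Observed cases/controls are labeled perfectly, so the cohort-level rate
    for each true class is the imputed-stratum rate scaled by the fraction of
    that class that was imputed.  ``rho`` is the true case fraction among the
    ``n_imputed`` subjects.
    """
    true_cases_imp = rho * n_imputed
    true_ctrls_imp = (1 - rho) * n_imputed
    frac_cases_imp = true_cases_imp / (n_cases_labeled + true_cases_imp)
    frac_ctrls_imp = true_ctrls_imp / (n_controls_labeled + true_ctrls_imp)
    return MisclassRates(
        gamma0=(1 - specificity) * frac_ctrls_imp,
        gamma1=(1 - sensitivity) * frac_cases_imp,
    )


def estimate_direct_proportion(h2_unadjusted: float, h2_adjusted: float) -> float:
    """Proportion of direct SNP effect from heritabilities with/without mediators.

    ``d* = h2_adjusted / h2_unadjusted`` -- the share of SNP heritability
    that survives adjustment for the mediating endophenotypes.
    """
    if not (0 < h2_adjusted <= h2_unadjusted <= 1):
        raise ValueError(
            "need 0 < h2_adjusted <= h2_unadjusted <= 1; a mediation proportion is "
            f"undefined for ({h2_unadjusted}, {h2_adjusted})"
        )
    return h2_adjusted / h2_unadjusted


def adjust_coefficient(beta_star: float, b_hat: float, d_star: float) -> float:
    """Misclassification-corrected coefficient ``beta* / (B d* + 1 - d*)``."""
    if not 0 <= d_star <= 1:
        raise ValueError("d* must lie in [0, 1]")
    denom = b_hat * d_star + (1 - d_star)
    if denom <= 0:
        raise ValueError(f"non-positive adjustment denominator {denom}")
    return beta_star / denom


def adjust_odds_ratio(or_star: float, b_hat: float, d_star: float) -> float:
    """Adjusted odds ratio ``exp(adjust_coefficient(log OR*, B, d*))``."""
    if or_star <= 0:
        raise ValueError("odds ratio must be positive")
    return math.exp(adjust_coefficient(math.log(or_star), b_hat, d_star))
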