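"""Screening operating points: specificity-floor thresholds, sensitivity,
PPV under low prevalence, and single-marker threshold back-conversion.

A cancer screening test must be extremely specific because disease
prevalence is low (ovarian cancer: 0.145% in the United States), otherwise
false positives swamp true positives and the positive predictive value
collapses.  The operating point used here is the *minimal* score threshold
achieving at least a given specificity floor (default 99%) among the
negative-class scores; a sample is called positive when its score is
strictly above the threshold, so placing the threshold at the k-th smallest
negative score yields specificity exactly k/n (with 182 negatives and a 99%
floor, 181/182 = 99.5%).  An alternative "zero false positive" rule —
threshold above the maximum negative score — is provided for comparison;
it is maximally sensitive to a single healthy outlier, which is the
robustness argument against it.

For a single-marker logistic model the score threshold can be converted
back through the logit and the inverse zlog transform to a concentration a
clinician can read off an assay report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .lr_models import FittedLinearModel
from .zlog import ReferenceRange, inverse_zlog

#: SEER 2022 prevalence of ovarian cancer in the United States.
DEFAULT_PREVALENCE = 0.00145

THRESHOLD_RULES = ("min_floor", "zero_fp")


@dataclass
class ThresholdReport:
    """Operating point at a specificity floor."""

    floor: float
    threshold: float
    spec_k: int
    spec_n: int
    sensitivity: float | None = None
    ppv: float | None = None
    zlog_value: float | None = None
    concentration: float | None = None

    @property
    def specificity(self) -> float:
        return self.spec_k / self.spec_n


def threshold_at_specificity(
    scores, labels, floor: float = 0.99, rule: str = "min_floor"
) -> ThresholdReport:
    """Smallest threshold achieving specificity >= ``floor``.

    With ``rule="min_floor"`` the threshold is the ceil(floor * n)-th order
    statistic of the negative-class scores: calling positive on score > t
    then misses exactly the negatives above t, giving the smallest
    achievable specificity >= floor.  With ``rule="zero_fp"`` the threshold
    is the maximum negative score (specificity n/n), the outlier-sensitive
    alternative.
    """
    if not (0 < floor <= 1):
        raise ValueError(f"specificity floor must be in (0, 1], got {floor}")
    if rule not in THRESHOLD_RULES:
        raise ValueError(f"rule must be one of {THRESHOLD_RULES}, got {rule!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    neg = np.sort(scores[~labels])
    n = len(neg)
    if n == 0 or not labels.any():
        raise ValueError("both classes must be present")
    if rule == "zero_fp":
        t = float(neg[-1])
    else:
        k = math.ceil(floor * n)
        t = float(neg[k - 1])
    spec_k = int((neg <= t).sum())  # ties can only raise specificity
    report = ThresholdReport(floor=floor, threshold=t, spec_k=spec_k, spec_n=n)
    report.sensitivity = sensitivity_at_threshold(scores, labels, t)
    return report


def sensitivity_at_threshold(scores, labels, threshold: float) -> float:
    """Fraction of positive-class scores strictly above the threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not labels.any():
        raise ValueError("no positive samples")
    pos = scores[labels]
    return float((pos > threshold).mean())


def ppv(sensitivity: float, specificity: float, prevalence: float = DEFAULT_PREVALENCE) -> float:
    """Positive predictive value: sens*p / (sens*p + (1-spec)*(1-p))."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("prevalence", prevalence)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    numerator = sensitivity * prevalence
    denominator = numerator + (1 - specificity) * (1 - prevalence)
    if denominator == 0:
        warnings.warn("PPV denominator is zero (no positives called); returning 0", stacklevel=2)
        return 0.0
    return numerator / denominator


def threshold_to_concentration(
    threshold: float, model: FittedLinearModel, reference: ReferenceRange
) -> tuple[float, float]:
    """Express a single-marker model's score threshold as (zlog, concentration).

    Inverts score = logistic(w*z + b) at the threshold: z = (logit(t) - b)/w,
    then maps z back to a concentration through the inverse zlog transform.
    Only defined for models with exactly one nonzero coefficient.
    """
    nonzero = np.flatnonzero(model.coefficients)
    if len(model.coefficients) != 1 and len(nonzero) != 1:
        raise ValueError("model must have exactly one feature with a nonzero coefficient")
    if not (0 < threshold < 1):
        raise ValueError(f"score threshold must be in (0, 1), got {threshold}")
    w = float(model.coefficients[nonzero[0]] if len(nonzero) == 1 else model.coefficients[0])
    if w == 0:
        raise ValueError("marker coefficient is zero")
    z = (math.log(threshold / (1 - threshold)) - model.intercept) / w
    return z, float(inverse_zlog(z, reference))
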