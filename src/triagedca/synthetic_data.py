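"""Synthetic cohorts with known ground truth.

Two generators cover the pipeline's input surfaces:

* :func:`generate_counts` draws a confusion matrix from the same binomial
  hierarchy the Bayesian model assumes — cases Binomial(n, prevalence),
  true positives Binomial(D, Se), true negatives Binomial(n - D, Sp) — so
  posterior calibration can be checked against known (Se, Sp, p).

* :func:`generate_cohort` draws patient-level continuous classifier scores
  from a binormal model (Gaussian score distribution within cases and within
  controls), the standard idealization of a diagnostic marker.  The implied
  sensitivity and specificity at any cutoff are available in closed form
  from the component distribution functions, giving an exact oracle for the
  cutoff optimizer.

Defaults emulate a cohort of 5,461 symptomatic patients with 6.7% cancer
prevalence, the scale of a large prospective triage study; the default case
and control locations are placed so that a cutoff near 2.14 yields roughly
66% sensitivity and 98% specificity, a realistic operating point for a
high-specificity multicancer detection test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .cutoff_optimizer import ScoreDataset
from .errors import ValidationError
from .summary_ingest import ConfusionCounts

__all__ = ["CohortModel", "generate_counts", "generate_cohort"]


@dataclass(frozen=True)
class CohortModel:
    """Binormal score model: controls ~ N(loc0, scale0), cases ~ N(loc1, scale1)."""

    prevalence: float = 0.067
    control_location: float = 0.0
    control_scale: float = 1.0
    case_location: float = 2.56
    case_scale: float = 1.0
    n_patients: int = 5_461
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValidationError("prevalence must lie in (0, 1)")
        if self.control_scale <= 0 or self.case_scale <= 0:
            raise ValidationError("score component scales must be > 0")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")

    def implied_sensitivity(self, cutoff: float) -> float:
        """P(score >= cutoff | case), exact under the binormal model."""
        return float(stats.norm.sf(cutoff, self.case_location, self.case_scale))

    def implied_specificity(self, cutoff: float) -> float:
        """P(score < cutoff | control), exact under the binormal model."""
        return float(stats.norm.cdf(cutoff, self.control_location, self.control_scale))


def generate_counts(
    n: int,
    prev: float,
    se: float,
    sp: float,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> ConfusionCounts:
    """Draw a confusion matrix from the binomial data-generating model.

    D ~ Binomial(n, prev); TP ~ Binomial(D, se); TN ~ Binomial(n - D, sp);
    FN and FP follow by subtraction.  Reproducible under a fixed seed.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    for name, value in (("prev", prev), ("se", se), ("sp", sp)):
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = int(rng.binomial(n, prev))
    tp = int(rng.binomial(d, se))
    tn = int(rng.binomial(n - d, sp))
    return ConfusionCounts(
        tp=tp, fn=d - tp, tn=tn, fp=n - d - tn, n_total=n, n_cancer=d
    )


def generate_cohort(model: CohortModel) -> ScoreDataset:
    """Draw a patient-level score cohort from a binormal model.

    Labels are Bernoulli(prevalence); each score comes from the case or
    control Gaussian component accordingly.
    """
    rng = np.random.default_rng(model.seed)
    labels = rng.binomial(1, model.prevalence, size=model.n_patients)
    locations = np.where(labels == 1, model.case_location, model.control_location)
    scales = np.where(labels == 1, model.case_scale, model.control_scale)
    scores = rng.normal(locations, scales)
    return ScoreDataset(scores=scores, labels=labels)
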