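"""Closed-form clinical-utility regions in (sensitivity, specificity) space.

For a given disease prevalence ``p`` and risk threshold ``t``, a binary test
is clinically useful when its net benefit strictly exceeds both default
strategies, refer-all and refer-none.  Writing the unreferred-scale net
benefit as ``Sp(1-p) - (1-t)/t * p(1-Se)``, the two comparisons yield linear
boundaries in (Se, Sp):

* beat refer-all:   ``Se > 1 - t*Sp*(1-p) / ((1-t)*p)``
* beat refer-none:  ``Sp > 1 - Se*p*(1-t) / (t*(1-p))``

The utility region is the intersection of the two half-planes.  When
``p > t`` the refer-all constraint binds (high-prevalence settings demand
sensitivity); when ``p < t`` the refer-none constraint binds (low-prevalence
settings demand specificity).  The formulas handle both without branching.

Boundary membership counts as NOT useful (strict inequalities throughout),
matching the tie convention of :func:`triagedca.bayes_dca.prob_useful`.
A requirement that cannot be met by any value in [0, 1] is reported as
``math.inf`` — a meaningful scientific answer, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_core import RiskThreshold, ThresholdLike, as_threshold, nb_referred_rate
from .errors import ValidationError

__all__ = [
    "RegionSpec",
    "UNATTAINABLE",
    "min_sensitivity",
    "min_specificity",
    "region_membership",
    "region_boundary",
]

#: Sentinel for a performance requirement no test in [0, 1] can satisfy.
UNATTAINABLE = math.inf


@dataclass(frozen=True)
class RegionSpec:
    """Prevalence and risk threshold defining one utility region."""

    prev: float
    threshold: RiskThreshold

    def __post_init__(self) -> None:
        object.__setattr__(self, "threshold", as_threshold(self.threshold))
        if not (0.0 < self.prev < 1.0):
            raise ValidationError(f"prevalence must lie in (0, 1), got {self.prev!r}")


def min_sensitivity(sp: float, spec: RegionSpec) -> float:
    """Infimum sensitivity needed to beat refer-all at specificity ``sp``.

    Solves ``Sp(1-p) - (1-t)/t * p(1-Se) > 0`` for Se:
    ``Se_min = 1 - t*Sp*(1-p) / ((1-t)*p)``, clipped below at 0.  Strictly
    greater sensitivity is required for utility; returns ``UNATTAINABLE``
    (infinity) when no sensitivity in [0, 1] strictly satisfies the
    condition (only possible at ``sp == 0``).
    """
    if not (0.0 <= sp <= 1.0):
        raise ValidationError(f"specificity must lie in [0, 1], got {sp!r}")
    p, t = spec.prev, spec.threshold.t
    se_min = 1.0 - t * sp * (1.0 - p) / ((1.0 - t) * p)
    if se_min >= 1.0:
        return UNATTAINABLE
    return max(se_min, 0.0)


def min_specificity(se: float, spec: RegionSpec) -> float:
    """Infimum specificity needed to beat refer-none at sensitivity ``se``.

    Solves ``Se*p - t/(1-t) * (1-p)(1-Sp) > 0`` for Sp:
    ``Sp_min = 1 - Se*p*(1-t) / (t*(1-p))``, clipped below at 0; returns
    ``UNATTAINABLE`` when even a perfectly specific test cannot strictly
    beat refer-none (only possible at ``se == 0``).
    """
    if not (0.0 <= se <= 1.0):
        raise ValidationError(f"sensitivity must lie in [0, 1], got {se!r}")
    p, t = spec.prev, spec.threshold.t
    sp_min = 1.0 - se * p * (1.0 - t) / (t * (1.0 - p))
    if sp_min >= 1.0:
        return UNATTAINABLE
    return max(sp_min, 0.0)


def region_membership(se, sp, spec: RegionSpec):
    """Whether (se, sp) lies strictly inside the clinical-utility region.

    True iff the test's referred-scale net benefit strictly exceeds
    ``max(nb(refer_all), 0)`` — equivalently, iff it beats both default
    strategies on either scale.  Accepts scalars or broadcastable arrays.
    """
    t = spec.threshold
    nb_test = nb_referred_rate(se, sp, spec.prev, t)
    nb_all = spec.prev - t.fp_weight * (1.0 - spec.prev)
    out = np.asarray(nb_test) > max(nb_all, 0.0)
    return bool(out) if out.ndim == 0 else out


def region_boundary(spec: RegionSpec, grid_size: int = 201) -> pd.DataFrame:
    """Trace the lower boundary of the utility region on a specificity grid.

    For each specificity on a uniform grid in [0, 1], the binding minimum
    sensitivity is the larger of the refer-all boundary
    (:func:`min_sensitivity`) and the refer-none boundary solved for Se at
    that specificity.  Grid points whose requirement is unattainable are
    omitted, so every returned point is the infimum of a nonempty vertical
    slice of the region.

    Returns a DataFrame with columns ``sp`` and ``se_min``, suitable for
    export as delimited text.
    """
    if grid_size < 2:
        raise ValidationError("grid_size must be >= 2")
    p, t = spec.prev, spec.threshold.t
    rows = []
    for sp in np.linspace(0.0, 1.0, grid_size):
        se_all = min_sensitivity(float(sp), spec)
        # Se needed so that sp exceeds min_specificity(se): invert the
        # refer-none boundary at this specificity.
        se_none = (1.0 - sp) * t * (1.0 - p) / (p * (1.0 - t))
        se_min = max(se_all, se_none)
        if se_min < 1.0:
            rows.append({"sp": float(sp), "se_min": float(se_min)})
    return pd.DataFrame(rows)
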