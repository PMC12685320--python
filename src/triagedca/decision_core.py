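"""Deterministic net-benefit algebra for referral decisions.

A risk threshold ``t`` encodes the harm:benefit trade-off of a referral
decision: a patient whose probability of cancer is at least ``t`` should be
referred.  The threshold fixes the exchange rate between decision errors —
each missed cancer (false negative) costs ``(1 - t) / t`` avoided referrals,
and each unnecessary referral (false positive) costs ``t / (1 - t)`` detected
cancers.  Net benefit discounts the desirable outcomes of a strategy by the
weighted undesirable ones:

* referred scale (net true positives per patient):
  ``Se * p - t / (1 - t) * (1 - p) * (1 - Sp)``
* unreferred scale (net true negatives per patient, i.e. unnecessary
  referrals avoided): ``Sp * (1 - p) - (1 - t) / t * p * (1 - Se)``

The two scales rank strategies identically; the exact relationship is
``nb_unreferred = (nb_referred(test) - nb_referred(refer_all)) * (1 - t) / t``.

All rates in this module are per patient; multiply by a reporting scale
factor (conventionally 100,000) only when presenting results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Union

import numpy as np

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .summary_ingest import ConfusionCounts

__all__ = [
    "RiskThreshold",
    "StrategyResult",
    "DEFAULT_SCALE_FACTOR",
    "as_threshold",
    "net_true_negatives",
    "net_true_positives",
    "nb_unreferred_rate",
    "nb_referred_rate",
    "comparator_results",
]

DEFAULT_SCALE_FACTOR = 100_000


@dataclass(frozen=True)
class RiskThreshold:
    """A risk threshold strictly inside (0, 1).

    Endpoints are rejected rather than clamped: the false-negative weight
    ``(1 - t) / t`` and false-positive weight ``t / (1 - t)`` must both be
    finite and positive.
    """

    t: float

    def __post_init__(self) -> None:
        if not (0.0 < self.t < 1.0):
            raise ValidationError(
                f"risk threshold must lie strictly in (0, 1), got {self.t!r}"
            )

    @property
    def fn_weight(self) -> float:
        """Relative cost of a false negative in units of true negatives."""
        return (1.0 - self.t) / self.t

    @property
    def fp_weight(self) -> float:
        """Relative cost of a false positive in units of true positives."""
        return self.t / (1.0 - self.t)


ThresholdLike = Union[RiskThreshold, float]


def as_threshold(threshold: ThresholdLike) -> RiskThreshold:
    """Coerce a bare float into a validated :class:`RiskThreshold`."""
    if isinstance(threshold, RiskThreshold):
        return threshold
    return RiskThreshold(float(threshold))


@dataclass(frozen=True)
class StrategyResult:
    """Net benefit of a decision strategy on both scales.

    ``refer_all`` always has zero net benefit for the unreferred (it refers
    everyone, avoiding nothing); ``refer_none`` always has zero net benefit
    for the referred.
    """

    strategy_label: str
    nb_referred: float
    nb_unreferred: float
    scale_factor: int = DEFAULT_SCALE_FACTOR

    @property
    def nb_referred_scaled(self) -> float:
        return self.nb_referred * self.scale_factor

    @property
    def nb_unreferred_scaled(self) -> float:
        return self.nb_unreferred * self.scale_factor


def net_true_negatives(counts: "ConfusionCounts", threshold: ThresholdLike) -> float:
    """Net true negatives: ``TN - (1 - t) / t * FN``.

    Each false negative is discounted at the threshold's relative cost; the
    result may be negative when missed cancers outweigh avoided referrals.
    """
    thr = as_threshold(threshold)
    return counts.tn - thr.fn_weight * counts.fn


def net_true_positives(counts: "ConfusionCounts", threshold: ThresholdLike) -> float:
    """Net true positives: ``TP - t / (1 - t) * FP``."""
    thr = as_threshold(threshold)
    return counts.tp - thr.fp_weight * counts.fp


def _check_proportions(**named) -> None:
    for name, value in named.items():
        arr = np.asarray(value, dtype=float)
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise ValidationError(f"{name} must lie in [0, 1]")


def nb_unreferred_rate(se, sp, prev, threshold: ThresholdLike):
    """Per-patient net benefit on the unreferred scale.

    ``Sp * (1 - p) - (1 - t) / t * p * (1 - Se)`` — unnecessary referrals
    avoided per patient, net of the weighted harm of missed cancers.
    Accepts scalars or equal-shape arrays for ``se``, ``sp``, ``prev``.
    """
    thr = as_threshold(threshold)
    _check_proportions(se=se, sp=sp, prev=prev)
    se, sp, prev = (np.asarray(x, dtype=float) for x in (se, sp, prev))
    out = sp * (1.0 - prev) - thr.fn_weight * prev * (1.0 - se)
    return out.item() if out.ndim == 0 else out


def nb_referred_rate(se, sp, prev, threshold: ThresholdLike):
    """Per-patient net benefit on the referred scale.

    ``Se * p - t / (1 - t) * (1 - p) * (1 - Sp)`` — net cancers detected per
    patient, after charging each unnecessary referral its relative cost.
    """
    thr = as_threshold(threshold)
    _check_proportions(se=se, sp=sp, prev=prev)
    se, sp, prev = (np.asarray(x, dtype=float) for x in (se, sp, prev))
    out = se * prev - thr.fp_weight * (1.0 - prev) * (1.0 - sp)
    return out.item() if out.ndim == 0 else out


def comparator_results(
    prev: float,
    threshold: ThresholdLike,
    scale_factor: int = DEFAULT_SCALE_FACTOR,
) -> tuple[StrategyResult, StrategyResult]:
    """Net benefit of the two default strategies, refer-all and refer-none.

    Refer-all behaves like a test with Se = 1, Sp = 0; refer-none like
    Se = 0, Sp = 1.  At ``prev == t`` both comparators sit exactly at zero
    net benefit on their informative scale (the indifference point).
    """
    thr = as_threshold(threshold)
    _check_proportions(prev=prev)
    p = float(prev)
    refer_all = StrategyResult(
        strategy_label="refer_all",
        nb_referred=p - thr.fp_weight * (1.0 - p),
        nb_unreferred=0.0,
        scale_factor=scale_factor,
    )
    refer_none = StrategyResult(
        strategy_label="refer_none",
        nb_referred=0.0,
        nb_unreferred=(1.0 - p) - thr.fn_weight * p,
        scale_factor=scale_factor,
    )
    return refer_all, refer_none
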