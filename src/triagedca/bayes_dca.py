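"""Conjugate Bayesian inference for decision-curve analysis of a binary test.

The data model treats the three unknowns of a diagnostic accuracy study as
independent binomial proportions with Beta priors:

* sensitivity   Se ~ Beta(a1 + TP, a2 + FN)
* specificity   Sp ~ Beta(b1 + TN, b2 + FP)
* prevalence    p  ~ Beta(c1 + D,  c2 + N - D)

Uniform Beta(1, 1) priors are the default.  Because the posteriors are
conjugate no MCMC is needed: Monte-Carlo draws from the joint posterior are
pushed through the net-benefit algebra of :mod:`triagedca.decision_core` to
give posterior decision curves and the probability of clinical utility —
the posterior probability that the test's net benefit strictly exceeds both
default strategies (refer everyone / refer no one).

Independence of the three posteriors mirrors the binomial factorisation of
the likelihood; it ignores any correlation induced by the same individuals
contributing to several margins.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decision_core import (
    DEFAULT_SCALE_FACTOR,
    ThresholdLike,
    as_threshold,
    nb_referred_rate,
    nb_unreferred_rate,
)
from .errors import ValidationError
from .summary_ingest import ConfusionCounts

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "DEFAULT_N_DRAWS",
    "DEFAULT_THRESHOLD_GRID",
    "sample_posterior",
    "dca_curve",
    "dca_curve_from_counts",
    "prob_useful",
    "credible_interval",
    "pathway_seed",
]

DEFAULT_N_DRAWS = 10_000

#: Default grid of risk thresholds for decision curves: 0.5%-7.5% in 0.25%
#: steps, spanning the 1%-7% range relevant to suspected-cancer referral.
DEFAULT_THRESHOLD_GRID: np.ndarray = np.round(np.arange(0.005, 0.0751, 0.0025), 6)


@dataclass(frozen=True)
class PriorSpec:
    """Beta hyperparameters for (sensitivity, specificity, prevalence)."""

    se_shape1: float = 1.0
    se_shape2: float = 1.0
    sp_shape1: float = 1.0
    sp_shape2: float = 1.0
    prev_shape1: float = 1.0
    prev_shape2: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "se_shape1", "se_shape2", "sp_shape1",
            "sp_shape2", "prev_shape1", "prev_shape2",
        ):
            if getattr(self, name) <= 0.0:
                raise ValidationError(f"Beta hyperparameter {name} must be > 0")

    @classmethod
    def uniform(cls) -> "PriorSpec":
        """The default flat Beta(1, 1) prior on all three proportions."""
        return cls()

    def posterior_shapes(self, counts: ConfusionCounts) -> dict[str, tuple[float, float]]:
        """Conjugate posterior Beta shapes for each parameter."""
        n_healthy = counts.n_total - counts.n_cancer
        return {
            "se": (self.se_shape1 + counts.tp, self.se_shape2 + counts.fn),
            "sp": (self.sp_shape1 + counts.tn, self.sp_shape2 + counts.fp),
            "prev": (self.prev_shape1 + counts.n_cancer, self.prev_shape2 + n_healthy),
        }


@dataclass(frozen=True)
class PosteriorDraws:
    """Joint Monte-Carlo draws of (Se, Sp, p) from their posteriors."""

    se: np.ndarray
    sp: np.ndarray
    prev: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (len(self.se) == len(self.sp) == len(self.prev)):
            raise ValidationError("draw sequences must have identical length")
        for name in ("se", "sp", "prev"):
            arr = getattr(self, name)
            if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
                raise ValidationError(f"{name} draws outside [0, 1]")

    @property
    def n_draws(self) -> int:
        return len(self.se)


def pathway_seed(master_seed: int, label: str) -> int:
    """Derive a stable per-pathway substream seed from a master seed.

    The label enters through CRC-32 so that a pathway's draws do not depend
    on its position in the input table.
    """
    return int(
        np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode("utf-8"))])
        .generate_state(1)[0] % (2**31)
    )


def sample_posterior(
    counts: ConfusionCounts,
    prior: Optional[PriorSpec] = None,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: Optional[int] = None,
) -> PosteriorDraws:
    """Draw from the joint conjugate posterior of (Se, Sp, p).

    The three margins are sampled independently from their Beta posteriors;
    identical ``(counts, prior, n_draws, seed)`` reproduce the draws
    bit-for-bit.
    """
    if n_draws < 1:
        raise ValidationError(f"n_draws must be >= 1, got {n_draws}")
    prior = prior or PriorSpec.uniform()
    shapes = prior.posterior_shapes(counts)
    rng = np.random.default_rng(seed)
    se = rng.beta(*shapes["se"], size=n_draws)
    sp = rng.beta(*shapes["sp"], size=n_draws)
    prev = rng.beta(*shapes["prev"], size=n_draws)
    return PosteriorDraws(se=se, sp=sp, prev=prev, seed=seed)


def credible_interval(values: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval of a sample.

    Quantiles use linear interpolation between order statistics (numpy's
    default rule); the default mass of 0.95 gives the 2.5%/97.5% interval.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("credible_interval requires a nonempty sequence")
    if not (0.0 < mass < 1.0):
        raise ValidationError("interval mass must lie in (0, 1)")
    tail = (1.0 - mass) / 2.0
    lo, hi = np.quantile(arr, [tail, 1.0 - tail])
    return float(lo), float(hi)


def prob_useful(
    draws: PosteriorDraws,
    threshold: ThresholdLike,
    scale: str = "referred",
) -> float:
    """Posterior probability that the test beats both default strategies.

    On the referred scale this is the fraction of draws where the test's net
    benefit strictly exceeds ``max(nb(refer_all), 0)``, with the comparator
    evaluated on the same prevalence draw.  The unreferred-scale comparison
    (beat refer-none and zero) is algebraically identical draw by draw; both
    are exposed so the identity can be verified.  Ties count as not useful.
    """
    thr = as_threshold(threshold)
    if scale == "referred":
        nb_test = nb_referred_rate(draws.se, draws.sp, draws.prev, thr)
        nb_all = draws.prev - thr.fp_weight * (1.0 - draws.prev)
        beats = nb_test > np.maximum(nb_all, 0.0)
    elif scale == "unreferred":
        nb_test = nb_unreferred_rate(draws.se, draws.sp, draws.prev, thr)
        nb_none = (1.0 - draws.prev) - thr.fn_weight * draws.prev
        beats = nb_test > np.maximum(nb_none, 0.0)
    else:
        raise ValidationError(f"scale must be 'referred' or 'unreferred', got {scale!r}")
    return float(np.mean(beats))


def dca_curve(
    draws: PosteriorDraws,
    thresholds: Sequence[ThresholdLike] = DEFAULT_THRESHOLD_GRID,
    scale_factor: int = DEFAULT_SCALE_FACTOR,
) -> pd.DataFrame:
    """Posterior decision curve over a grid of risk thresholds.

    The same draw set is reused at every threshold — (Se, Sp, p) do not
    depend on t — so curves are smooth in t and threshold-to-threshold
    differences have minimal Monte-Carlo variance.  Net benefits are
    reported multiplied by ``scale_factor`` (per 100,000 patients by
    default).

    Returns a DataFrame with one row per threshold: posterior mean and
    2.5%/97.5% percentiles of net benefit on both scales, the probability of
    clinical utility computed on each scale, and the posterior-mean net
    benefit of the two comparators.
    """
    thresholds = [as_threshold(t) for t in thresholds]
    if not thresholds:
        raise ValidationError("at least one threshold is required")
    rows = []
    for thr in thresholds:
        nb_ref = nb_referred_rate(draws.se, draws.sp, draws.prev, thr)
        nb_unref = nb_unreferred_rate(draws.se, draws.sp, draws.prev, thr)
        nb_all = draws.prev - thr.fp_weight * (1.0 - draws.prev)
        nb_none = (1.0 - draws.prev) - thr.fn_weight * draws.prev
        ref_lo, ref_hi = credible_interval(nb_ref)
        unref_lo, unref_hi = credible_interval(nb_unref)
        rows.append(
            {
                "threshold": thr.t,
                "nb_referred_mean": nb_ref.mean() * scale_factor,
                "nb_referred_lo": ref_lo * scale_factor,
                "nb_referred_hi": ref_hi * scale_factor,
                "nb_unreferred_mean": nb_unref.mean() * scale_factor,
                "nb_unreferred_lo": unref_lo * scale_factor,
                "nb_unreferred_hi": unref_hi * scale_factor,
                "p_useful_referred": prob_useful(draws, thr, scale="referred"),
                "p_useful_unreferred": prob_useful(draws, thr, scale="unreferred"),
                "refer_all_nb_referred_mean": nb_all.mean() * scale_factor,
                "refer_none_nb_unreferred_mean": nb_none.mean() * scale_factor,
            }
        )
    return pd.DataFrame(rows)


def dca_curve_from_counts(
    counts: ConfusionCounts,
    thresholds: Sequence[ThresholdLike] = DEFAULT_THRESHOLD_GRID,
    prior: Optional[PriorSpec] = None,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: Optional[int] = None,
    scale_factor: int = DEFAULT_SCALE_FACTOR,
    shared_draws: bool = True,
) -> pd.DataFrame:
    """Sample the posterior and compute the decision curve in one step.

    ``shared_draws=False`` re-samples an independent posterior draw set per
    threshold (each from its own substream of ``seed``) instead of reusing
    one set across the curve.
    """
    if shared_draws:
        draws = sample_posterior(counts, prior=prior, n_draws=n_draws, seed=seed)
        return dca_curve(draws, thresholds, scale_factor=scale_factor)
    thresholds = [as_threshold(t) for t in thresholds]
    children = np.random.SeedSequence(seed).spawn(len(thresholds))
    parts = []
    for thr, child in zip(thresholds, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        draws = sample_posterior(counts, prior=prior, n_draws=n_draws, seed=sub_seed)
        parts.append(dca_curve(draws, [thr], scale_factor=scale_factor))
    return pd.concat(parts, ignore_index=True)
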