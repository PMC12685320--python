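"""Retraining-free cutoff selection maximizing net true negatives.

A continuous classifier score can be binarized at any cutoff; each cutoff
yields a different binary test and hence a different net benefit.  Rather
than fixing an arbitrary sensitivity or specificity target, the optimizer
evaluates net true negatives per 100,000 patients at a fixed risk threshold
for every candidate cutoff and returns the maximizer.  Because net benefit
as a function of the cutoff is a step function that only changes where a
score is crossed, midpoints between consecutive distinct scores (plus -inf
and +inf sentinels) form an exact candidate set.

Selection uses the plug-in (point-estimate) net benefit; honest uncertainty
assessment of the chosen cutoff is a separate Bayesian step
(:func:`evaluate_cutoff_bayes`), mirroring select-then-validate practice.
Apparent net benefit at a selected cutoff is optimistically biased; ideally
the chosen cutoff is re-evaluated on independent validation data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bayes_dca import (
    DEFAULT_N_DRAWS,
    PriorSpec,
    dca_curve,
    sample_posterior,
)
from .decision_core import (
    DEFAULT_SCALE_FACTOR,
    ThresholdLike,
    as_threshold,
    net_true_negatives,
)
from .errors import DegenerateDataError, ValidationError
from .summary_ingest import ConfusionCounts

__all__ = [
    "ScoreDataset",
    "CutoffResult",
    "confusion_at_cutoff",
    "optimize_cutoff",
    "evaluate_cutoff_bayes",
    "read_score_file",
    "write_score_file",
]


@dataclass(frozen=True)
class ScoreDataset:
    """Patient-level continuous scores with binary cancer status.

    Higher scores indicate a more cancer-like profile; labels are 1 for
    confirmed cancer.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValidationError("scores and labels must be equal-length 1-D arrays")
        if not np.all(np.isfinite(scores)):
            raise ValidationError("scores must be finite")
        if not np.isin(labels, (0, 1)).all():
            raise ValidationError("labels must be 0 or 1")

    @property
    def n(self) -> int:
        return self.scores.size

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def prevalence(self) -> float:
        return self.n_cases / self.n


@dataclass(frozen=True)
class CutoffResult:
    """Outcome of the cutoff search.

    ``no_useful_cutoff`` is set when no cutoff strictly improves on the
    refer-all sentinel (whose net true negatives are exactly zero); the
    reported maximum is then zero, never negative.
    """

    cutoff: float
    counts_at_cutoff: ConfusionCounts
    nb_unreferred_per_100k: float
    candidate_curve: pd.DataFrame
    no_useful_cutoff: bool


def confusion_at_cutoff(data: ScoreDataset, cutoff: float) -> ConfusionCounts:
    """Tabulate the confusion matrix when positive means ``score >= cutoff``.

    Ties with the cutoff count as positive.
    """
    positive = data.scores >= cutoff
    cases = data.labels == 1
    tp = int(np.count_nonzero(positive & cases))
    fp = int(np.count_nonzero(positive & ~cases))
    fn = int(np.count_nonzero(~positive & cases))
    tn = int(np.count_nonzero(~positive & ~cases))
    return ConfusionCounts(
        tp=tp, fp=fp, tn=tn, fn=fn, n_total=data.n, n_cancer=data.n_cases
    )


def _default_candidates(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-math.inf], midpoints, [math.inf]))


def optimize_cutoff(
    data: ScoreDataset,
    threshold: ThresholdLike,
    candidates: Optional[Sequence[float]] = None,
    scale_factor: int = DEFAULT_SCALE_FACTOR,
) -> CutoffResult:
    """Choose the cutoff maximizing net true negatives per ``scale_factor``.

    Every candidate cutoff (default: midpoints between consecutive distinct
    scores plus the all-positive/all-negative sentinels) is evaluated as
    ``net TNs / n * scale_factor`` at the given risk threshold.  Ties at the
    maximum are broken toward the fewest positives (highest specificity):
    fewer referrals at equal net benefit.
    """
    thr = as_threshold(threshold)
    if data.n_cases == 0 or data.n_cases == data.n:
        raise DegenerateDataError(
            "cutoff optimization requires at least one case and one control"
        )
    if candidates is None:
        cand = _default_candidates(data.scores)
    else:
        cand = np.asarray(list(candidates), dtype=float)
        if cand.size == 0:
            raise ValidationError("candidate set must be nonempty")

    records = []
    for cutoff in cand:
        counts = confusion_at_cutoff(data, float(cutoff))
        nb = net_true_negatives(counts, thr) / data.n * scale_factor
        records.append((float(cutoff), counts, nb))
    curve = pd.DataFrame(
        {"cutoff": [r[0] for r in records], "nb_unreferred_per_100k": [r[2] for r in records]}
    )
    best_nb = max(r[2] for r in records)
    # Tie-break: fewest positives, i.e. highest cutoff among maximizers.
    ties = [r for r in records if r[2] == best_nb]
    cutoff, counts, nb = max(ties, key=lambda r: r[0])
    return CutoffResult(
        cutoff=cutoff,
        counts_at_cutoff=counts,
        nb_unreferred_per_100k=nb,
        candidate_curve=curve,
        no_useful_cutoff=bool(best_nb <= 0.0),
    )


def evaluate_cutoff_bayes(
    data: ScoreDataset,
    cutoff: float,
    threshold: ThresholdLike,
    prior: Optional[PriorSpec] = None,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: Optional[int] = None,
    scale_factor: int = DEFAULT_SCALE_FACTOR,
) -> pd.Series:
    """Bayesian net-benefit assessment of one cutoff.

    Binarizes the scores at ``cutoff`` and runs the conjugate posterior
    analysis on the resulting counts.  Returns the single decision-curve row
    at ``threshold``: posterior mean and 2.5%/97.5% interval of net benefit
    on both scales (per ``scale_factor``) and the probability of clinical
    utility.
    """
    counts = confusion_at_cutoff(data, cutoff)
    draws = sample_posterior(counts, prior=prior, n_draws=n_draws, seed=seed)
    curve = dca_curve(draws, [as_threshold(threshold)], scale_factor=scale_factor)
    row = curve.iloc[0].copy()
    row["cutoff"] = float(cutoff)
    return row


def read_score_file(path: Union[str, Path], delimiter: str = ",") -> ScoreDataset:
    """Read a two-column (score, label) delimited text file with a header."""
    frame = pd.read_csv(path, sep=delimiter, comment="#")
    frame.columns = [c.strip().lower() for c in frame.columns]
    for column in ("score", "label"):
        if column not in frame.columns:
            raise ValidationError(f"{path}: expected a {column!r} column")
    return ScoreDataset(
        scores=frame["score"].to_numpy(float), labels=frame["label"].to_numpy(int)
    )


def write_score_file(data: ScoreDataset, path: Union[str, Path]) -> None:
    """Write a dataset in the two-column score/label format."""
    pd.DataFrame({"score": data.scores, "label": data.labels}).to_csv(path, index=False)
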