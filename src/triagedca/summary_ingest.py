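"""Parse published diagnostic-accuracy summaries and reconstruct raw counts.

Diagnostic-accuracy publications frequently report sample size, prevalence,
sensitivity, specificity and predictive values but not the underlying
confusion matrix.  This module inverts the arithmetic: given a per-pathway
summary row it recovers integer TP/FP/TN/FN counts via

* ``D  = round(prevalence * N)``          (when D is not printed)
* ``TP = round(Se * D)``
* ``TN = round(Sp * (N - D))``, or ``TN = floor(NPV * (N - P))`` when the
  floor-of-NPV variant is requested (used by some sources to mitigate
  rounding error when NPV and the positive count P are printed),
* ``FP = N - D - TN`` and ``FN = D - TP`` by subtraction.

Rounding is half-away-from-zero so that e.g. 0.5 rounds up, matching how
published proportions are conventionally derived from counts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Union

from .errors import InconsistencyError, SchemaError, ValidationError

__all__ = [
    "SummaryPerformance",
    "ConfusionCounts",
    "parse_performance_table",
    "reconstruct_counts",
]

#: Columns every performance table must declare.
REQUIRED_COLUMNS = ("pathway", "n_total", "sensitivity")
#: Optional columns recognised by the parser.
OPTIONAL_COLUMNS = ("n_cancer", "prevalence", "n_positive", "specificity", "ppv", "npv")
#: Columns holding proportions (subject to percent/proportion dialect).
PROPORTION_COLUMNS = ("prevalence", "sensitivity", "specificity", "ppv", "npv")

Dialect = Literal["auto", "percent", "proportion"]


@dataclass(frozen=True)
class SummaryPerformance:
    """One pathway's published accuracy summary, as printed.

    Optional fields are ``None`` when the source did not print them; a row is
    analyzable only if cancer burden (``n_cancer`` or ``prevalence``) and a
    route to the true-negative count (``specificity``, or ``npv`` together
    with ``n_positive``) are available.
    """

    pathway_label: str
    n_total: Optional[int] = None
    sensitivity: Optional[float] = None
    n_cancer: Optional[int] = None
    prevalence: Optional[float] = None
    n_positive: Optional[int] = None
    specificity: Optional[float] = None
    ppv: Optional[float] = None
    npv: Optional[float] = None

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any invariant is violated."""
        for reason in self.missing_requirements():
            raise ValidationError(f"{self.pathway_label}: {reason}")
        if self.n_total < 1:
            raise ValidationError(f"{self.pathway_label}: n_total must be >= 1")
        for name in PROPORTION_COLUMNS:
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValidationError(
                    f"{self.pathway_label}: {name}={value} outside [0, 1]"
                )
        if self.n_cancer is not None and self.n_cancer > self.n_total:
            raise ValidationError(f"{self.pathway_label}: n_cancer exceeds n_total")
        if self.n_positive is not None and self.n_positive > self.n_total:
            raise ValidationError(f"{self.pathway_label}: n_positive exceeds n_total")

    @property
    def is_analyzable(self) -> bool:
        """Whether counts can be reconstructed from this row."""
        try:
            self.validate()
        except ValidationError:
            return False
        return True

    def missing_requirements(self) -> list[str]:
        """Human-readable reasons the row cannot be analyzed (empty if fine)."""
        reasons = []
        if self.n_total is None:
            reasons.append("sample size N not printed")
        if self.sensitivity is None:
            reasons.append("sensitivity not printed")
        if self.n_cancer is None and self.prevalence is None:
            reasons.append("neither n_cancer nor prevalence printed")
        if self.specificity is None and not (
            self.npv is not None and self.n_positive is not None
        ):
            reasons.append("specificity not printed (and no npv/n_positive fallback)")
        return reasons


@dataclass(frozen=True)
class ConfusionCounts:
    """Integer confusion matrix, with the marginals it must sum to."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_total: int
    n_cancer: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.tp + self.fn != self.n_cancer:
            raise ValidationError("tp + fn must equal n_cancer")
        if self.tn + self.fp != self.n_total - self.n_cancer:
            raise ValidationError("tn + fp must equal n_total - n_cancer")

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_cancer

    @property
    def specificity(self) -> float:
        return self.tn / (self.n_total - self.n_cancer)

    @property
    def prevalence(self) -> float:
        return self.n_cancer / self.n_total


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (x is nonnegative here)."""
    return int(math.floor(x + 0.5))


def _parse_cell(raw: str, column: str, row_index: int) -> Optional[float]:
    raw = raw.strip()
    if raw == "" or raw.lower() in {"na", "nan", "none"}:
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise ValidationError(
            f"row {row_index}: column {column!r} has non-numeric value {raw!r}"
        ) from exc


def parse_performance_table(
    path: Union[str, Path],
    *,
    dialect: Dialect = "auto",
    delimiter: Optional[str] = None,
) -> list[SummaryPerformance]:
    """Read a delimited performance table into :class:`SummaryPerformance` rows.

    The file must carry a header row naming at least ``pathway``, ``n_total``
    and ``sensitivity``; lines starting with ``#`` are provenance comments and
    skipped.  Proportion columns may be given as percentages (``66.3``) or
    proportions (``0.663``); with ``dialect="auto"`` each column is treated as
    percent when any of its values exceeds 1.

    Parsing is deliberately lenient about incomplete rows (publications often
    omit a pathway's specificity, for instance): structural problems raise,
    but incompleteness is only surfaced later via
    :meth:`SummaryPerformance.is_analyzable`.
    """
    path = Path(path)
    if dialect not in ("auto", "percent", "proportion"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    with path.open(newline="", encoding="utf-8") as handle:
        lines = [line for line in handle if not line.lstrip().startswith("#")]
    if not lines:
        raise SchemaError(f"{path}: empty file, expected a header row")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.DictReader(lines, delimiter=delimiter)
    header = [name.strip().lower() for name in reader.fieldnames or []]
    for column in REQUIRED_COLUMNS:
        if column not in header:
            raise SchemaError(f"{path}: missing required column {column!r}")

    raw_rows: list[dict[str, Optional[float]]] = []
    labels: list[str] = []
    for index, row in enumerate(reader):
        cells = {key.strip().lower(): (value or "") for key, value in row.items() if key}
        labels.append(cells.get("pathway", "").strip())
        parsed: dict[str, Optional[float]] = {}
        for column in ("n_total", "n_cancer", "n_positive") + PROPORTION_COLUMNS:
            parsed[column] = _parse_cell(cells.get(column, ""), column, index)
        raw_rows.append(parsed)

    # Resolve the percent/proportion dialect per column.
    scale: dict[str, float] = {}
    for column in PROPORTION_COLUMNS:
        values = [row[column] for row in raw_rows if row[column] is not None]
        if dialect == "percent":
            is_percent = True
        elif dialect == "proportion":
            is_percent = False
        else:
            is_percent = any(v > 1.0 for v in values)
        scale[column] = 0.01 if is_percent else 1.0
        for index, row in enumerate(raw_rows):
            value = row[column]
            if value is None:
                continue
            upper = 100.0 if is_percent else 1.0
            if not (0.0 <= value <= upper):
                raise ValidationError(
                    f"row {index}: {column}={value} outside [0, {upper:g}]"
                )

    records = []
    for label, row in zip(labels, raw_rows):
        records.append(
            SummaryPerformance(
                pathway_label=label,
                n_total=None if row["n_total"] is None else int(row["n_total"]),
                n_cancer=None if row["n_cancer"] is None else int(row["n_cancer"]),
                n_positive=None if row["n_positive"] is None else int(row["n_positive"]),
                prevalence=_scaled(row, "prevalence", scale),
                sensitivity=_scaled(row, "sensitivity", scale),
                specificity=_scaled(row, "specificity", scale),
                ppv=_scaled(row, "ppv", scale),
                npv=_scaled(row, "npv", scale),
            )
        )
    return records


def _scaled(row: dict, column: str, scale: dict) -> Optional[float]:
    value = row[column]
    return None if value is None else value * scale[column]


def reconstruct_counts(
    summary: SummaryPerformance,
    *,
    use_npv_floor: bool = False,
) -> ConfusionCounts:
    """Recover the integer confusion matrix behind a published summary.

    With ``use_npv_floor`` the true-negative count comes from
    ``floor(NPV * (N - P))`` instead of ``round(Sp * (N - D))``; this variant
    requires the negative predictive value and the positive-test count.
    Raises :class:`InconsistencyError` when the printed statistics imply a
    negative cell.
    """
    summary.validate()
    n = summary.n_total
    if summary.n_cancer is not None:
        d = summary.n_cancer
    else:
        d = _round_half_away(summary.prevalence * n)
    tp = _round_half_away(summary.sensitivity * d)

    if use_npv_floor:
        if summary.npv is None or summary.n_positive is None:
            raise ValidationError(
                f"{summary.pathway_label}: npv-floor reconstruction requires "
                "both npv and n_positive"
            )
        tn = int(math.floor(summary.npv * (n - summary.n_positive)))
    else:
        if summary.specificity is None:
            raise ValidationError(
                f"{summary.pathway_label}: specificity required unless "
                "use_npv_floor is set"
            )
        tn = _round_half_away(summary.specificity * (n - d))

    fp = n - d - tn
    fn = d - tp
    if min(tp, fp, tn, fn) < 0:
        raise InconsistencyError(
            f"{summary.pathway_label}: reconstruction yields negative counts "
            f"(tp={tp}, fp={fp}, tn={tn}, fn={fn}) — summary statistics are "
            "mutually inconsistent"
        )
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n_total=n, n_cancer=d)
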