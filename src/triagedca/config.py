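"""Analysis configuration shared by the command-line entry points."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .bayes_dca import DEFAULT_N_DRAWS, PriorSpec
from .decision_core import DEFAULT_SCALE_FACTOR
from .errors import ValidationError

__all__ = ["AnalysisConfig", "packaged_fixture_path"]


def packaged_fixture_path() -> Path:
    """Path of the packaged summary-statistics fixture (printed study values)."""
    return Path(resources.files("triagedca") / "data" / "symplify_summary.csv")


@dataclass
class AnalysisConfig:
    """Everything a reproducible analysis run needs.

    ``thresholds`` is a (start, stop, step) triple defining the decision-curve
    grid; ``highlight`` lists thresholds pulled out into the JSON summary and
    must lie inside the grid range.
    """

    input: Optional[str] = None
    output_dir: str = "triagedca_output"
    thresholds: tuple[float, float, float] = (0.005, 0.075, 0.0025)
    highlight: tuple[float, ...] = (0.03,)
    n_draws: int = DEFAULT_N_DRAWS
    seed: int = 0
    prior: PriorSpec = field(default_factory=PriorSpec.uniform)
    scale_factor: int = DEFAULT_SCALE_FACTOR
    dialect: str = "auto"
    shared_draws: bool = True
    use_npv_floor: bool = False

    def __post_init__(self) -> None:
        start, stop, step = self.thresholds
        if step <= 0:
            raise ValidationError("threshold step must be > 0")
        if not (0.0 < start <= stop < 1.0):
            raise ValidationError("threshold grid must satisfy 0 < start <= stop < 1")
        for t in self.highlight:
            if not (start - 1e-12 <= t <= stop + 1e-12):
                raise ValidationError(
                    f"highlighted threshold {t} lies outside the grid "
                    f"[{start}, {stop}]"
                )
        if self.n_draws < 1:
            raise ValidationError("n_draws must be >= 1")

    @property
    def threshold_grid(self) -> np.ndarray:
        start, stop, step = self.thresholds
        grid = np.round(np.arange(start, stop + step / 2.0, step), 10)
        # Highlighted thresholds are appended if the grid does not hit them.
        extra = [t for t in self.highlight if not np.any(np.isclose(grid, t))]
        return np.unique(np.concatenate([grid, extra])) if extra else grid

    @property
    def input_path(self) -> Path:
        return Path(self.input) if self.input else packaged_fixture_path()

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        if "prior" in raw and not isinstance(raw["prior"], PriorSpec):
            raw["prior"] = PriorSpec(**raw["prior"])
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        if "highlight" in raw:
            raw["highlight"] = tuple(raw["highlight"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with Path(path).open(encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw)

    def to_manifest(self) -> dict:
        """JSON-serializable record sufficient to regenerate every output."""
        manifest = asdict(self)
        manifest["input"] = str(self.input_path)
        return manifest
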