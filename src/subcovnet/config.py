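"""Analysis configuration: sparsity grid, permutations, covariates, seeds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

#: Covariates adjusted for in ANCOVA and partial correlations.
DEFAULT_COVARIATES: tuple[str, ...] = ("sex", "age", "education_years", "tiv")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the volumetric and network analysis.

    Defaults follow the study conditions: networks binarized over a
    sparsity grid of 18%-50% in 1% steps, 100 degree-preserving random
    networks for Gamma/Lambda normalization, 1000 label permutations,
    two-tailed alpha 0.05, Benjamini-Hochberg FDR.
    """

    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    sparsity_min: float = 0.18
    sparsity_max: float = 0.50
    sparsity_step: float = 0.01
    n_random: int = 100
    n_permutations: int = 1000
    alpha: float = 0.05
    fdr_method: str = "bh"
    #: "trapezoid" integrates the metric curve; "step-sum" multiplies the
    #: per-sparsity values by the step width (toolbox-compatibility rule).
    auc_rule: str = "trapezoid"
    correlation_method: str = "pearson"
    #: residualize node volumes on the covariates before correlating
    residualize_edges: bool = False
    #: score used to split SCD into good/bad halves
    grouping_score: str = "navigation"
    #: successful double-edge swaps per rewired network, x edge count
    swap_multiplier: int = 10
    #: attempt cap per rewiring call, x successful-swap budget
    attempt_multiplier: int = 3
    #: "nested": null graphs carried up the sparsity grid with incremental
    #: swaps; "independent": full re-rewiring at every sparsity.
    ensemble_scheme: str = "nested"
    #: "finite": Lp averages finite distances, unreachable pairs logged;
    #: "largest_component": metrics on the largest connected component.
    disconnected: str = "finite"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sparsity_min <= self.sparsity_max <= 1):
            raise ValueError(
                "sparsity bounds must satisfy 0 < min <= max <= 1, got "
                f"[{self.sparsity_min}, {self.sparsity_max}]"
            )
        if self.sparsity_step <= 0:
            raise ValueError("sparsity_step must be > 0")
        if self.n_random < 0 or self.n_permutations < 1:
            raise ValueError("n_random must be >= 0 and n_permutations >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.auc_rule not in ("trapezoid", "step-sum"):
            raise ValueError("auc_rule must be 'trapezoid' or 'step-sum'")
        if self.ensemble_scheme not in ("nested", "independent"):
            raise ValueError("ensemble_scheme must be 'nested' or 'independent'")
        if self.disconnected not in ("finite", "largest_component"):
            raise ValueError("disconnected must be 'finite' or 'largest_component'")
        if self.grouping_score not in ("navigation", "memory", "language", "executive"):
            raise ValueError(
                "grouping_score must be one of navigation|memory|language|executive"
            )
        self.covariates = tuple(self.covariates)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> dict:
    """Load a structured YAML config file (``analysis`` and optional
    ``cohort`` sections) into plain dictionaries."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return raw


def save_config(sections: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(sections, fh, sort_keys=False)
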