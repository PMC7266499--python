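"""Analysis configuration shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    """Stage parameters with the study's defaults.

    min_observations: proteins quantified in fewer samples (whole dataset)
        are dropped before analysis.
    alpha: per-test significance level for p- and q-based filters.
    s0: SAM fudge factor added to the pooled standard error (log10 scale).
    n_permutations: label permutations for the FDR estimate (exhaustive
        enumeration is used instead when feasible).
    term_size_min/max: annotation terms outside [10, 100] dataset members
        are excluded from enrichment (tiny and huge terms dominate
        otherwise without being informative).
    k_folds: cross-validation folds for classifier evaluation.
    cv_threshold: CV fraction under which a protein counts as precisely
        quantified (0.20 = the accepted 20% assay-precision bound).
    """

    min_observations: int = 20
    alpha: float = 0.05
    s0: float = 0.001
    n_permutations: int = 250
    rng_seed: int = 0
    term_size_min: int = 10
    term_size_max: int = 100
    k_folds: int = 6
    cv_threshold: float = 0.20

    def __post_init__(self) -> None:
        if self.min_observations < 1:
            raise ValueError("min_observations must be >= 1")
        for name in ("alpha", "s0", "cv_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not self.term_size_min < self.term_size_max:
            raise ValueError("term_size_min must be < term_size_max")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a YAML mapping; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)
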