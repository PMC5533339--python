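"""Run-wide configuration for feature construction, model fitting and evaluation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict


@dataclass
class Config:
    """Tunable parameters shared across the pipeline.

    Attributes
    ----------
    dos_scale:
        Scaling parameter ``a`` of the degree-augmented orthologous score
        ``DOS(v) = a * DC(v) + OS(v)``. Meaningful range is [0.1, 1];
        0.1 gives the best ranking performance and is the default.
    top_fraction_slc:
        Fraction of proteins (ranked by the LBCC reference score) taken as
        the presumed-essential set when computing per-location enrichment
        coefficients (SLC). Default 0.05 (top 5%).
    top_fraction_measures:
        Fraction of the ranking treated as predicted-positive when computing
        the six confusion-derived statistics. Default 0.20 (top 20%).
    rf_trees:
        Number of trees in the random forest. Default 1000.
    rf_seed:
        Seed for the forest and any seeded shuffling (cross-validation folds).
    log_epsilon:
        Additive constant inside each logarithm of the LBCC combination so
        zero-valued inputs stay finite and rank at the bottom.
    """

    dos_scale: float = 0.1
    top_fraction_slc: float = 0.05
    top_fraction_measures: float = 0.20
    rf_trees: int = 1000
    rf_seed: int = 0
    log_epsilon: float = 1e-10

    def __post_init__(self) -> None:
        if not (0.0 < self.top_fraction_slc < 1.0):
            raise ValueError("top_fraction_slc must lie strictly between 0 and 1")
        if not (0.0 < self.top_fraction_measures < 1.0):
            raise ValueError("top_fraction_measures must lie strictly between 0 and 1")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")
        if not (0.1 <= self.dos_scale <= 1.0):
            warnings.warn(
                f"dos_scale={self.dos_scale} is outside the supported range [0.1, 1]",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return asdict(self)
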