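"""Shared result-record types carried between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

#: estimate scales by model family
FAMILY_SCALE = {
    "linear": "beta",
    "logistic": "OR",
    "modified-poisson": "RR",
    "multinomial": "OR",
}


@dataclass
class FitRecord:
    """One exposure-outcome association from either analysis arm.

    Ratio-family estimates (``OR``/``RR``) are stored exponentiated; ``beta``
    estimates are on the identity scale. ``se`` is always on the link
    (log or identity) scale, which is the scale pooling and Wald CIs use.
    """

    outcome: str
    contrast: str            # "1v0", "2v0", "3v0", "4-5v0", "trend", "per-SD", "Q2v1", ...
    family: str              # linear | logistic | modified-poisson | multinomial
    scale: str               # beta | OR | RR
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float = np.nan
    n_used: int = 0
    stratum: str = "all"
    theme: str = ""
    converged: bool = True
    rejected: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "OR", "RR"):
            raise ValueError(f"unknown estimate scale {self.scale!r}")

    @property
    def link_estimate(self) -> float:
        """Estimate on the link scale (log for ratio families)."""
        if self.scale == "beta":
            return self.estimate
        return float(np.log(self.estimate))

    @property
    def direction(self) -> int:
        """Sign of the association relative to the null (+1, -1 or 0)."""
        return int(np.sign(self.link_estimate))


@dataclass
class EValueRecord:
    """Point and confidence-limit E-values plus robustness call for one fit."""

    outcome: str
    contrast: str
    rr_used: float
    evalue_point: float
    evalue_ci: float
    robust: bool = False
    rule_used: str = ""      # "benchmark-comparison" | "percentile"

    def __post_init__(self) -> None:
        if not (self.evalue_point >= self.evalue_ci >= 1.0 - 1e-12):
            raise ValueError(
                "E-value ordering violated: require point >= CI E-value >= 1 "
                f"(got {self.evalue_point}, {self.evalue_ci})"
            )


@dataclass
class TriangulationRecord:
    """Paired observational/genetic results for one outcome."""

    outcome: str
    theme: str
    obs: FitRecord
    gen: FitRecord
    category: str            # concordant_significant | observational_only | genetic_only | neither | discordant
    robust_observational: bool = False


def records_to_frame(records: list) -> pd.DataFrame:
    """Flatten a list of dataclass records into a DataFrame."""
    if not records:
        return pd.DataFrame()
    return pd.DataFrame([asdict(r) for r in records])
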