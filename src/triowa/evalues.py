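"""E-value sensitivity analysis for unmeasured confounding.

The E-value of a risk ratio ``RR`` is the minimum strength of association,
on the risk-ratio scale, that an unmeasured confounder would need to have
with *both* the exposure and the outcome to fully explain away the observed
association:

    E = RR + sqrt(RR * (RR - 1))        for RR >= 1,

with protective estimates first inverted (E(RR) = E(1/RR)). The CI E-value
applies the same formula to the confidence limit closest to the null and is
the more stringent robustness measure: the confounding needed to move the
whole interval to include the null.

Robustness classification compares the CI E-value against a benchmark
covariate coefficient (a measured proxy for the suspected unmeasured
confounder, e.g. maternal smoking at birth as a childhood-SES proxy); when
the benchmark is a linear-model beta rather than a ratio, a percentile rule
over all CI E-values is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import EValueRecord, FitRecord

#: multiplier converting a standardized mean difference to an approximate RR
SMD_TO_RR = 0.91


@dataclass
class BenchmarkCoefficient:
    """Per-outcome benchmark covariate coefficient on the ratio scale.

    ``ratio`` is None for outcomes where the benchmark was estimated as a
    linear-model beta (continuous outcomes), in which case the percentile
    rule applies.
    """

    covariate: str
    ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ratio is not None and self.ratio <= 0:
            raise ValueError("benchmark ratio must be positive")

    @property
    def available(self) -> bool:
        return self.ratio is not None


def evalue_from_rr(rr: float) -> float:
    """E-value for a point risk ratio.

    Protective ratios are inverted first, so the function is symmetric:
    ``evalue_from_rr(rr) == evalue_from_rr(1/rr)``.
    """
    rr = float(rr)
    if not np.isfinite(rr) or rr <= 0:
        raise ValueError(f"risk ratio must be a positive finite number, got {rr}")
    if rr < 1:
        rr = 1.0 / rr
    return rr + np.sqrt(rr * (rr - 1.0))


def ci_evalue(estimate: float, lcl: float, ucl: float) -> float:
    """E-value at the confidence limit closest to the null.

    Returns 1 when the interval contains (or touches) the null RR of 1:
    no unmeasured confounding at all is needed to render the interval
    compatible with no effect.
    """
    if not (lcl <= estimate <= ucl):
        raise ValueError(
            f"confidence limits must bracket the estimate: {lcl} <= {estimate} <= {ucl}"
        )
    if lcl <= 1.0 <= ucl:
        return 1.0
    limit = lcl if estimate > 1.0 else ucl
    return evalue_from_rr(limit)


def rr_from_standardized_beta(beta: float) -> float:
    """Approximate risk ratio for a standardized-outcome regression beta.

    Uses the standard conversion RR ~= exp(0.91 * beta) for an effect
    expressed in outcome standard deviations, so that E-values can be
    computed for linear-model results. Symmetric: converting ``-beta``
    yields the reciprocal ratio.
    """
    beta = float(beta)
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return float(np.exp(SMD_TO_RR * beta))


def evalue_for_fit(rec: FitRecord) -> EValueRecord:
    """Point and CI E-values for one fitted association.

    Ratio-scale estimates (OR/RR) enter the formula directly; linear-model
    betas and their confidence limits are first mapped to approximate risk
    ratios via :func:`rr_from_standardized_beta`.
    """
    if rec.scale == "beta":
        est = rr_from_standardized_beta(rec.estimate)
        lcl = rr_from_standardized_beta(rec.ci_low)
        ucl = rr_from_standardized_beta(rec.ci_high)
    else:
        est, lcl, ucl = rec.estimate, rec.ci_low, rec.ci_high
    return EValueRecord(
        outcome=rec.outcome,
        contrast=rec.contrast,
        rr_used=est,
        evalue_point=evalue_from_rr(est),
        evalue_ci=ci_evalue(est, lcl, ucl),
    )


def classify_robust(
    record: EValueRecord,
    benchmark: Optional[BenchmarkCoefficient],
    all_ci_evalues: Sequence[float],
) -> EValueRecord:
    """Classify one association as potentially robust to unmeasured confounding.

    Ratio outcomes: robust iff the CI E-value exceeds the benchmark
    coefficient's magnitude on the ratio scale (protective benchmarks are
    inverted, so magnitude means max(b, 1/b)); strict inequality. Outcomes
    without a ratio benchmark: robust iff the CI E-value is in the top 50th
    percentile (>= median, ties robust) of the CI E-values of all outcomes.
    A CI E-value of 1 (interval crossing the null) is never robust.
    """
    if record.evalue_ci <= 1.0:
        record.robust = False
        record.rule_used = (
            "benchmark-comparison" if benchmark is not None and benchmark.available
            else "percentile"
        )
        return record
    if benchmark is not None and benchmark.available:
        b = benchmark.ratio
        record.robust = record.evalue_ci > max(b, 1.0 / b)
        record.rule_used = "benchmark-comparison"
    else:
        vals = np.asarray(list(all_ci_evalues), dtype=float)
        if vals.size == 0:
            raise ValueError(
                "percentile robustness rule requires the CI E-values of all outcomes"
            )
        record.robust = record.evalue_ci >= np.median(vals)
        record.rule_used = "percentile"
    return record


def append_evalues(
    records: Iterable[FitRecord],
    benchmarks: Optional[dict] = None,
) -> list[EValueRecord]:
    """E-value + robustness overlay for a set of fitted associations.

    ``benchmarks`` maps outcome name -> :class:`BenchmarkCoefficient`; an
    outcome absent from the map (or with no ratio-scale benchmark) falls
    back to the percentile rule, evaluated against the CI E-values of every
    association in ``records``.
    """
    records = list(records)
    evrecs = [evalue_for_fit(r) for r in records]
    all_ci = [e.evalue_ci for e in evrecs]
    benchmarks = benchmarks or {}
    return [
        classify_robust(e, benchmarks.get(e.outcome), all_ci) for e in evrecs
    ]
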