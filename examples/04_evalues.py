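"""E-value sensitivity analysis for unmeasured confounding.

Takes ratio-scale associations (estimate plus 95% CI), computes point and
confidence-limit E-values, and classifies robustness against a benchmark
covariate coefficient.
"""

from triowa import (
    evalue_from_rr, ci_evalue, append_evalues, BenchmarkCoefficient,
    FitRecord,
)

# an outcome-wide result as it would be reported: OR 1.57 (1.53, 1.62)
print("point E-value for OR 1.57:", round(evalue_from_rr(1.57), 2))
print("CI E-value (computed at the lower limit 1.53):",
      round(ci_evalue(1.57, 1.53, 1.62), 2))
print("CI E-value when the interval crosses the null:",
      ci_evalue(1.05, 0.98, 1.12))

records = [
    FitRecord(outcome="overall_health", contrast="trend", family="logistic",
              scale="OR", estimate=1.57, se=0.015, ci_low=1.53, ci_high=1.62,
              p=1e-12),
    FitRecord(outcome="weekly_alcohol", contrast="trend", family="logistic",
              scale="OR", estimate=0.90, se=0.006, ci_low=0.89, ci_high=0.91,
              p=1e-10),
    FitRecord(outcome="sexual_partners", contrast="trend", family="linear",
              scale="beta", estimate=0.13, se=0.005, ci_low=0.12, ci_high=0.14,
              p=1e-12),
]
benchmarks = {
    "overall_health": BenchmarkCoefficient("maternal_smoking", 1.35),
    "weekly_alcohol": BenchmarkCoefficient("maternal_smoking", 0.92),
}
for ev in append_evalues(records, benchmarks):
    print(f"{ev.outcome:16s} E_point={ev.evalue_point:.2f} "
          f"E_ci={ev.evalue_ci:.2f} robust={ev.robust} ({ev.rule_used})")
# A CI E-value of 2.43 says an unmeasured confounder would need risk-ratio
# associations of at least 2.43 with both exposure and outcome to move the
# interval onto the null; robustness compares that against the benchmark
# coefficient (or the E-value median for beta-scale outcomes).
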