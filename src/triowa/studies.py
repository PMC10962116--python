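"""Pre-specified synthetic study designs exercising the full pipeline.

The designed triangulation study generates one genotype panel and cohort,
splits it into two non-overlapping samples (observational and genetic, the
genetic one larger, as in the biobank design the pipeline emulates), and
plants three groups of continuous outcomes whose generating causal
structures the two analysis arms are differentially sensitive to:

* ``true_effect``  — moved by the maltreatment count itself; expected
  significant in both arms with the same direction (the genetic arm is
  attenuated by the score's imperfect proxying but powered by its larger
  sample);
* ``confounded``   — driven by the *unmeasured* confounder ``u`` that also
  raises maltreatment liability; expected significant only in the
  observational arm;
* ``pleiotropic``  — driven directly by the genetic score, bypassing the
  exposure; expected significant only in the genetic arm.

Effect sizes are fixed design constants chosen for roughly 90% power at
the default sample sizes; they are part of the study definition, not
tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .simulate import (
    SimulationConfig, OutcomeTruth, simulate_genotypes, simulate_cohort,
    emulate_gwas, SyntheticCohort, GenotypePanel,
)
from .impute import ImputedStack
from .owa import OwaSettings, run_observational_owa, code_exposure
from .prs import PrsSettings, variant_qc, greedy_clump, compute_score
from .genetic import GeneticOwaSettings, run_genetic_owa
from .triangulate import triangulate, summarize, TriangulationRecord

#: expected concordance category per designed outcome group
EXPECTED_CATEGORY = {
    "true_effect": "concordant_significant",
    "confounded": "observational_only",
    "pleiotropic": "genetic_only",
}


def designed_outcomes(n_true: int = 10, n_conf: int = 10,
                      n_pleio: int = 5) -> List[OutcomeTruth]:
    """The three planted outcome groups (all continuous, SD-unit effects).

    The exposure effect (0.25 SD per maltreatment count), hidden-confounder
    loading (0.50 SD per SD of ``u``) and direct genetic-score effect
    (0.05 SD per SD of score) are calibrated so that the arm meant to
    detect each group does so with roughly 90% power at the default sample
    sizes, while the leakage into the other arm (the genetic correlate of
    the count for pleiotropic outcomes, and vice versa) stays well below
    the FDR threshold.
    """
    specs = []
    for i in range(n_true):
        specs.append(OutcomeTruth(
            name=f"true_effect_{i}", true_effect_exposure=0.25,
            theme="true_effect"))
    for i in range(n_conf):
        specs.append(OutcomeTruth(
            name=f"confounded_{i}", confounder_loadings={"u": 0.50},
            theme="confounded"))
    for i in range(n_pleio):
        specs.append(OutcomeTruth(
            name=f"pleiotropic_{i}", pleiotropy_effect=0.05,
            theme="pleiotropic"))
    return specs


def triangulation_study_config(seed: int, n_obs: int = 3000,
                               n_gen: int = 20000) -> SimulationConfig:
    """Study conditions for the designed triangulation simulation.

    Heritability of the exposure liability is set high (0.25) and the item
    noise low (0.8) so the polygenic score is a usable exposure proxy at
    this reduced scale; the genetic sample is several times larger than
    the observational one, mirroring the two-arm biobank design.
    """
    return SimulationConfig(
        n_individuals=n_obs + n_gen,
        n_variants=200, block_size=4, n_causal=20,
        ld_rho=0.4, maf_range=(0.1, 0.5),
        h2_liability=0.25, gwas_n=200_000,
        item_noise_sd=0.8,
        confounder_effects={"u": 0.30, "maternal_smoking": 0.10,
                            "maternal_depression": 0.08},
        outcome_specs=designed_outcomes(),
        seed=seed,
    )


@dataclass
class TriangulationStudyResult:
    records: List[TriangulationRecord]
    theme_summary: pd.DataFrame
    overall: dict
    expected: Dict[str, str]
    obs_results: object
    gen_results: object


def run_triangulation_study(seed: int, n_obs: int = 3000,
                            n_gen: int = 20000) -> TriangulationStudyResult:
    """One full two-arm run of the designed study at the given seed.

    Generates the shared panel and cohort, runs the observational trend
    scan on the first ``n_obs`` individuals, builds the genome-wide
    significant clumping-and-thresholding score for the remaining ``n_gen``
    and runs the genetic scan there, then triangulates the two arms.
    """
    cfg = triangulation_study_config(seed, n_obs, n_gen)
    panel = simulate_genotypes(cfg)
    cohort = simulate_cohort(cfg, panel)

    obs_df = cohort.data.iloc[:n_obs].reset_index(drop=True)
    gen_df = cohort.data.iloc[n_obs:].reset_index(drop=True)
    gen_dosages = panel.dosages.iloc[n_obs:].reset_index(drop=True)
    gen_dosages.attrs["allele_map"] = panel.dosages.attrs.get("allele_map", {})

    catalog = pd.DataFrame({
        "name": [s.name for s in cfg.outcome_specs],
        "type": ["continuous"] * len(cfg.outcome_specs),
        "theme": [s.theme for s in cfg.outcome_specs],
    })

    # observational arm: complete data, trend contrast only
    stack = ImputedStack(datasets=[obs_df], trace=pd.DataFrame())
    obs_settings = OwaSettings(strata=("all",), per_level=False)
    obs_res = run_observational_owa(stack, catalog, obs_settings)

    # genetic arm: QC -> clump -> genome-wide significant score -> scan
    sumstats = emulate_gwas(cfg, panel)
    prs_settings = PrsSettings()
    kept = variant_qc(sumstats, prs_settings)
    clump = greedy_clump(kept, gen_dosages, prs_settings)
    score = compute_score(gen_dosages, kept, prs_settings,
                          threshold=prs_settings.p_thresholds[0], clump=clump)
    gen_res = run_genetic_owa(gen_df, score, catalog, gen_dosages,
                              GeneticOwaSettings())

    records, _ = triangulate(obs_res.records, gen_res.records)
    theme_summary, overall, _ = summarize(records)
    expected = {s.name: EXPECTED_CATEGORY[s.theme] for s in cfg.outcome_specs}
    return TriangulationStudyResult(records=records, theme_summary=theme_summary,
                                    overall=overall, expected=expected,
                                    obs_results=obs_res, gen_results=gen_res)


#: dichotomized type prevalences for the parameter-recovery study. Richer
#: than the maltreatment-emulating defaults so the count exposure carries
#: enough information at n = 10,000 for Wald intervals on rare outcomes to
#: be in their asymptotic regime (a calibration study wants information
#: about the parameter, not tail-leverage pathology).
RECOVERY_TYPE_PREVALENCE = (0.25, 0.20, 0.15, 0.20, 0.15)


def _thresholds_for_prevalence(prevalences, item_noise_sd: float) -> np.ndarray:
    from scipy import stats as _st
    lsd = np.sqrt(1.0 + item_noise_sd**2)
    t = np.empty((5, 4))
    for j, p in enumerate(prevalences):
        t[j, 1] = lsd * _st.norm.ppf(1 - p)
        t[j, 0] = lsd * _st.norm.ppf(1 - min(2.5 * p, 0.9))
        t[j, 2] = lsd * _st.norm.ppf(1 - p / 2.5)
        t[j, 3] = lsd * _st.norm.ppf(1 - p / 6.0)
    return t


def recovery_study_config(seed: int, n: int = 10_000,
                          effect: float = 0.1) -> SimulationConfig:
    """Parameter-recovery study: one outcome per regression family.

    Generating per-count effects of ``effect`` (0.1) on the linear
    predictor: a beta for the continuous outcome, a log-OR for the rare
    (5%) binary outcome fit by logistic regression, and a log-RR for the
    common (30%) binary outcome fit by modified Poisson. Two covariates
    carry 20% MAR missingness to be multiply imputed.
    """
    noise = 0.8
    return SimulationConfig(
        n_individuals=n, n_variants=20, block_size=4, seed=seed,
        item_noise_sd=noise,
        item_thresholds=_thresholds_for_prevalence(RECOVERY_TYPE_PREVALENCE, noise),
        missing_rate_covariates={"birthweight": 0.2, "breastfed": 0.2},
        outcome_specs=[
            OutcomeTruth(name="y_linear", true_effect_exposure=effect),
            OutcomeTruth(name="y_logistic", family_truth="binary",
                         base_rate=0.05, true_effect_exposure=effect),
            OutcomeTruth(name="y_poisson", family_truth="binary", base_rate=0.3,
                         link="log", true_effect_exposure=effect),
        ],
    )


def run_recovery_study(seed: int, m: int = 5,
                       effect: float = 0.1) -> Dict[str, bool]:
    """One recovery run: does each family's pooled 95% CI cover its truth?

    Injects the configured MAR missingness, imputes with chained equations
    (m datasets), fits the trend model per outcome and checks the pooled
    interval against the generating effect (the linear outcome's interval
    is mapped back to the raw scale using the outcome SD, since the scan
    standardizes continuous outcomes). A non-converged record counts as a
    miss.
    """
    from .impute import ImputationSettings, impute_chained
    from .simulate import inject_missingness

    cfg = recovery_study_config(seed, effect=effect)
    panel = simulate_genotypes(cfg)
    cohort = inject_missingness(simulate_cohort(cfg, panel), cfg)
    stack = impute_chained(cohort.data,
                           ImputationSettings(m=m, max_iterations=5, seed=seed))
    catalog = pd.DataFrame({
        "name": ["y_linear", "y_logistic", "y_poisson"],
        "type": ["continuous", "binary", "binary"],
    })
    res = run_observational_owa(stack, catalog,
                                OwaSettings(strata=("all",), per_level=False))
    covered: Dict[str, bool] = {}
    for r in res.records:
        if r.contrast != "trend":
            continue
        if not r.converged:
            covered[r.outcome] = False
            continue
        if r.family == "linear":
            sd = float(stack.datasets[0][r.outcome].std())
            covered[r.outcome] = r.ci_low * sd <= effect <= r.ci_high * sd
        else:
            covered[r.outcome] = np.log(r.ci_low) <= effect <= np.log(r.ci_high)
    return covered


def run_null_fdr_study(seed: int, n_outcomes: int = 20,
                       n: int = 400, alpha: float = 0.05) -> float:
    """One null-catalog scan: realized false-discovery proportion.

    All outcomes are pure noise, so every rejection is false and the FDP is
    1 whenever anything is rejected; averaged over seeds this estimates the
    Benjamini-Hochberg false-discovery rate, which should not exceed alpha.
    """
    cfg = SimulationConfig(
        n_individuals=n, n_variants=8, block_size=4, seed=seed,
        outcome_specs=[OutcomeTruth(name=f"null_{i}") for i in range(n_outcomes)],
    )
    panel = simulate_genotypes(cfg)
    cohort = simulate_cohort(cfg, panel)
    stack = ImputedStack(datasets=[cohort.data], trace=pd.DataFrame())
    catalog = pd.DataFrame({
        "name": [s.name for s in cfg.outcome_specs],
        "type": ["continuous"] * n_outcomes,
    })
    res = run_observational_owa(
        stack, catalog, OwaSettings(strata=("all",), per_level=False, alpha=alpha))
    trend = [r for r in res.records if r.contrast == "trend" and r.converged]
    n_rej = sum(r.rejected for r in trend)
    return 1.0 if n_rej > 0 else 0.0


def classification_accuracy(result: TriangulationStudyResult) -> Dict[str, float]:
    """Per-group fraction of outcomes landing in their expected category."""
    hits: Dict[str, List[bool]] = {}
    for r in result.records:
        hits.setdefault(r.theme, []).append(
            r.category == EXPECTED_CATEGORY[r.theme])
    return {g: float(np.mean(v)) for g, v in hits.items()}
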