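"""Synthetic cohort, genotype and GWAS summary-statistics generator.

Generates the data structures the two analysis arms consume, with a known
ground truth so every downstream stage is testable: LD-structured biallelic
genotype dosages, a liability-threshold exposure (five ordinal screener
items scored 1-5 driven by a shared latent liability), a roster of
sociodemographic / childhood / family covariates, mixed continuous, binary
and categorical outcomes with configurable exposure effects, confounding
and horizontal pleiotropy, emulated discovery-GWAS summary statistics, and
a missingness injector (MAR covariates plus a rare "prefer not to say"
sentinel on the exposure items).

The causal diagram encoded here is the one the two analysis arms are
differentially biased by:

* an **unmeasured confounder** ``u`` raises both maltreatment liability and
  any outcome loading on it — inflating the observational arm only;
* a **pleiotropy effect** lets the genetic score act on an outcome directly,
  bypassing the exposure — inflating the genetic arm only;
* a **true exposure effect** moves the outcome per unit of the maltreatment
  count and is visible (attenuated in the genetic arm) to both.

Liability is standardized to unit variance so the heritability share
``h2_liability`` is directly interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

#: sentinel code for a "prefer not to say" response on an exposure item
PNS_CODE = -1

#: covariates eligible for MAR missingness injection by default
DEFAULT_MISSING_TARGETS = [
    "birthweight", "breastfed", "n_siblings",
    "maternal_smoking", "maternal_depression",
]

ITEM_NAMES = [
    "emotional_abuse", "physical_abuse", "sexual_abuse",
    "emotional_neglect", "physical_neglect",
]

#: approximate marginal prevalence of each dichotomized maltreatment type
DEFAULT_TYPE_PREVALENCE = (0.095, 0.055, 0.040, 0.065, 0.030)


@dataclass
class OutcomeTruth:
    """Generating model for one synthetic outcome.

    ``true_effect_exposure`` is the per-unit effect of the maltreatment
    count on the linear predictor (log-odds, log-risk or SD units depending
    on family/link); ``confounder_loadings`` maps covariate names (or the
    hidden confounder ``"u"``) to linear-predictor loadings;
    ``pleiotropy_effect`` is a direct effect of the standardized genetic
    score bypassing the exposure.
    """

    name: str
    family_truth: str = "continuous"     # continuous | binary | categorical
    true_effect_exposure: float = 0.0
    confounder_loadings: Dict[str, float] = field(default_factory=dict)
    pleiotropy_effect: float = 0.0
    base_rate: float = 0.3               # binary only
    k: int = 3                           # categorical only
    link: Optional[str] = None           # binary: "logit" (default) or "log"
    theme: str = "misc"

    def __post_init__(self) -> None:
        if self.family_truth not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown outcome family {self.family_truth!r}")
        if self.family_truth == "binary" and not (0 < self.base_rate < 1):
            raise ValueError("base_rate must be in (0, 1) for binary outcomes")
        if self.family_truth == "categorical" and self.k < 3:
            raise ValueError("categorical outcomes need k >= 3 levels")
        if self.link is None and self.family_truth == "binary":
            self.link = "logit"


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults emulate the structure of a biobank maltreatment study at
    reduced scale: five 1-5 ordinal screener items whose dichotomized
    type prevalences sit near (9.5%, 5.5%, 4%, 6.5%, 3%), a sub-1%
    "prefer not to say" rate per item, and a discovery GWAS of 185,414
    participants for the summary statistics.
    """

    n_individuals: int = 5000
    n_variants: int = 100
    block_size: int = 10
    ld_rho: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    h2_liability: float = 0.15
    n_causal: Optional[int] = None       # default: one per other block
    confounder_effects: Dict[str, float] = field(default_factory=lambda: {
        "u": 0.25, "maternal_smoking": 0.12, "maternal_depression": 0.08,
        "n_siblings": 0.08, "breastfed": -0.05,
    })
    item_thresholds: Optional[np.ndarray] = None   # (5, 4) latent cutpoints
    item_noise_sd: float = 1.3
    dichotomize_cutoffs: tuple = (3, 3, 3, 3, 3)
    outcome_specs: List[OutcomeTruth] = field(default_factory=list)
    pns_rate: float = 0.005
    missing_rate_covariates: Union[float, Dict[str, float]] = 0.0
    gwas_n: int = 185414
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_variants <= 0 or self.block_size <= 0:
            raise ValueError("cohort and panel dimensions must be positive")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.h2_liability < 1):
            raise ValueError("h2_liability must be in [0, 1)")
        if not (0 <= self.pns_rate <= 0.01):
            raise ValueError("pns_rate must be in [0, 0.01]")
        if self.gwas_n <= 0:
            raise ValueError("gwas_n must be positive")
        if self.item_thresholds is not None:
            t = np.asarray(self.item_thresholds, dtype=float)
            if t.shape != (5, 4):
                raise ValueError("item_thresholds must have shape (5, 4)")
            if not (np.diff(t, axis=1) > 0).all():
                raise ValueError("item thresholds must be strictly increasing")
            self.item_thresholds = t
        if self.n_causal is None:
            self.n_causal = max(1, self.n_variants // self.block_size // 2)


@dataclass
class GenotypePanel:
    """Dosage matrix (individuals x variants) plus per-variant metadata.

    Metadata columns: SNP, CHR, POS, A1 (counted/effect allele), A2,
    MAF (empirical), INFO, HWE_P, beta_liability (true per-allele effect on
    the standardized liability scale).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.dosages.to_numpy(float)
        if d.size and (d.min() < 0 or d.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        for _, grp in self.variants.groupby("CHR"):
            if not grp["POS"].is_monotonic_increasing:
                raise ValueError("positions must be strictly increasing within chromosome")


@dataclass
class SyntheticCohort:
    """Individuals x {exposure items, covariates, outcomes} plus truth channel.

    ``data`` is what the analysis arms see; ``truth`` holds the generating
    quantities (standardized genetic score, liability, hidden confounder,
    true maltreatment count, pre-missingness copies) so tests never need to
    re-run the generator.
    """

    data: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible substream per generator stage
    return np.random.default_rng([config.seed, stream])


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Simulate LD-structured biallelic dosages in equicorrelated blocks.

    Within each block of ``block_size`` variants a Gaussian copula with
    correlation ``ld_rho`` drives all variants; each latent value is cut at
    the two Hardy-Weinberg thresholds for that variant's allele frequency,
    yielding dosages 0/1/2 with probabilities ((1-p)^2, 2p(1-p), p^2).
    Blocks are placed 1 Mb apart (variants 5 kb apart within a block) so LD
    is strictly block-local. Causal liability effects are assigned to
    ``n_causal`` variants, one per block, round-robin over blocks.
    """
    rng = _rng(config, 1)
    n, m, b = config.n_individuals, config.n_variants, config.block_size
    n_blocks = int(np.ceil(m / b))
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    # Hardy-Weinberg cutpoints: P(d=0) = (1-p)^2, P(d<=1) = 1 - p^2
    t0 = stats.norm.ppf((1 - mafs) ** 2)
    t1 = stats.norm.ppf(1 - mafs**2)
    # Thresholding attenuates the latent correlation by the factor
    # a_j = cov(d_j, Z_j) / sd(d_j); inflate each variant's loading on the
    # block factor so the *dosage* correlation approximates ld_rho.
    atten = (stats.norm.pdf(t0) + stats.norm.pdf(t1)) / np.sqrt(2 * mafs * (1 - mafs))
    load = np.sqrt(np.minimum(config.ld_rho / atten**2, 1.0))

    Z = np.empty((n, m))
    for blk in range(n_blocks):
        j0, j1 = blk * b, min((blk + 1) * b, m)
        w = j1 - j0
        shared = rng.standard_normal((n, 1))
        indep = rng.standard_normal((n, w))
        lj = load[j0:j1][None, :]
        Z[:, j0:j1] = lj * shared + np.sqrt(1 - lj**2) * indep
    dosage = (Z > t0).astype(np.int8) + (Z > t1).astype(np.int8)

    pos = np.concatenate([
        1_000_000 * blk + 5_000 * np.arange(1, min(b, m - blk * b) + 1)
        for blk in range(n_blocks)
    ])
    emp_maf = dosage.mean(axis=0) / 2.0
    hwe_p = np.array([_hwe_pvalue(dosage[:, j]) for j in range(m)])

    beta = np.zeros(m)
    causal_blocks = np.arange(config.n_causal) % n_blocks
    causal_idx = []
    for k, blk in enumerate(causal_blocks):
        j = blk * b + (k // n_blocks) % max(1, min(b, m - blk * b))
        causal_idx.append(j)
    causal_idx = np.unique(causal_idx)
    beta[causal_idx] = rng.normal(0.0, 1.0, size=len(causal_idx))
    # scale so the raw genetic score has unit variance in this panel
    raw_score = dosage @ beta
    sd = raw_score.std()
    if sd > 0:
        beta = beta / sd

    snps = [f"rs{blk + 1}_{j - blk * b + 1}"
            for blk in range(n_blocks) for j in range(blk * b, min((blk + 1) * b, m))]
    variants = pd.DataFrame({
        "SNP": snps,
        "CHR": 1,
        "POS": pos,
        "A1": "A",
        "A2": "G",
        "MAF": np.minimum(emp_maf, 1 - emp_maf),
        "INFO": rng.uniform(0.9, 1.0, size=m),
        "HWE_P": hwe_p,
        "beta_liability": beta,
    })
    dosages = pd.DataFrame(dosage, columns=snps)
    dosages.attrs["allele_map"] = {s: ("A", "G") for s in snps}
    return GenotypePanel(dosages=dosages, variants=variants)


def _hwe_pvalue(d: np.ndarray) -> float:
    """Chi-square Hardy-Weinberg test p-value from genotype counts."""
    n = d.size
    p = d.mean() / 2.0
    if p in (0.0, 1.0):
        return 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    obs = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()])
    chi2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(chi2, df=1))


def _default_item_thresholds(latent_sd: float) -> np.ndarray:
    """Latent cutpoints mapping liability+noise to the 1-5 item scale.

    The second cutpoint (between scores 2 and 3, i.e. at the default
    dichotomization cutoff of 3) is placed at the normal quantile giving
    each item its target dichotomized type prevalence; the remaining
    cutpoints shape the lower and upper categories.
    """
    t = np.empty((5, 4))
    for j, prev in enumerate(DEFAULT_TYPE_PREVALENCE):
        # score >= 3 (the default cutoff) should occur with prob `prev`
        t[j, 1] = latent_sd * stats.norm.ppf(1 - prev)
        t[j, 0] = latent_sd * stats.norm.ppf(1 - 2.5 * prev)
        t[j, 2] = latent_sd * stats.norm.ppf(1 - prev / 2.5)
        t[j, 3] = latent_sd * stats.norm.ppf(1 - prev / 6.0)
    return t


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def simulate_cohort(config: SimulationConfig, panel: GenotypePanel) -> SyntheticCohort:
    """Generate covariates, liability-driven exposure items and outcomes.

    Liability = sqrt(h2) * standardized genetic score + confounder terms +
    Gaussian noise scaled so the total variance is 1. Each of the five
    ordinal items is the latent liability plus item-specific noise cut at
    four ordered thresholds. Outcomes follow their :class:`OutcomeTruth`
    generating model with identity, logit, log or baseline-category-logit
    link.
    """
    if len(panel.dosages) != config.n_individuals:
        raise ValueError("genotype panel row count must equal n_individuals")
    rng = _rng(config, 2)
    n = config.n_individuals

    cov = pd.DataFrame({
        "sex": rng.binomial(1, 0.566, n),                       # 1 = female
        "age_enrollment": np.clip(rng.normal(55.9, 7.7, n), 38, 72).round(1),
        "ethnicity": rng.choice(
            ["white", "mixed", "asian", "black", "other"], n,
            p=[0.971, 0.005, 0.011, 0.007, 0.006]),
        "country_of_birth_uk": rng.binomial(1, 0.928, n),
        "breastfed": rng.binomial(1, 0.735, n),
        "multiple_birth": rng.binomial(1, 0.020, n),
        "n_siblings": rng.poisson(2.0, n),
        "birthweight": np.clip(rng.normal(3.34, 0.62, n), 0.4, 10.0).round(2),
        "maternal_smoking": rng.binomial(1, 0.287, n),
        "maternal_depression": rng.binomial(1, 0.069, n),
        "array": rng.binomial(1, 0.5, n),                       # sequencing batch
    })
    cov["age_mhq"] = (cov["age_enrollment"] + 7.1).round(1)
    cov["birth_year"] = (2008 - cov["age_enrollment"]).round().astype(int)
    u = rng.standard_normal(n)                                  # hidden confounder

    raw_score = panel.dosages.to_numpy(float) @ panel.variants["beta_liability"].to_numpy()
    score_std = _standardize(raw_score)

    h2 = config.h2_liability
    liab = np.sqrt(h2) * score_std
    c2 = 0.0
    for name, eff in config.confounder_effects.items():
        x = u if name == "u" else cov[name].to_numpy(float)
        liab = liab + eff * _standardize(x)
        c2 += eff**2
    noise_var = max(1.0 - h2 - c2, 0.05)
    liab = liab + np.sqrt(noise_var) * rng.standard_normal(n)

    latent_sd = np.sqrt(1.0 + config.item_noise_sd**2)
    thresholds = (config.item_thresholds if config.item_thresholds is not None
                  else _default_item_thresholds(latent_sd))
    items = {}
    for j, item in enumerate(ITEM_NAMES):
        lat = liab + config.item_noise_sd * rng.standard_normal(n)
        items[item] = 1 + (lat[:, None] > thresholds[j][None, :]).sum(axis=1)
    items = pd.DataFrame(items)

    flags = np.column_stack([
        items[ITEM_NAMES[j]].to_numpy() >= config.dichotomize_cutoffs[j]
        for j in range(5)
    ])
    count_true = flags.sum(axis=1)

    # generating exposure is the five-level count category scored 0-4
    # (counts of 4 and 5 share the top level)
    count_score = np.minimum(count_true, 4).astype(float)
    outcomes = {}
    for spec in config.outcome_specs:
        lp = spec.true_effect_exposure * count_score
        for name, load in spec.confounder_loadings.items():
            x = u if name == "u" else cov[name].to_numpy(float)
            lp = lp + load * _standardize(x)
        if spec.pleiotropy_effect:
            lp = lp + spec.pleiotropy_effect * score_std
        outcomes[spec.name] = _draw_outcome(spec, lp, rng)
    outcomes = pd.DataFrame(outcomes, index=cov.index)

    data = pd.concat([items, cov, outcomes], axis=1)
    data.insert(0, "iid", np.arange(n))
    truth = pd.DataFrame({
        "iid": np.arange(n),
        "score_raw": raw_score,
        "score_std": score_std,
        "liability": liab,
        "u": u,
        "count_true": count_true,
    })
    return SyntheticCohort(data=data, truth=truth, config=config)


def _draw_outcome(spec: OutcomeTruth, lp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if spec.family_truth == "continuous":
        return lp + rng.standard_normal(lp.size)
    if spec.family_truth == "binary":
        if spec.link == "logit":
            b = _solve_intercept(lambda b: expit(b + lp).mean(), spec.base_rate)
            p = expit(b + lp)
        else:  # log link -> risk-ratio generating model
            b = _solve_intercept(
                lambda b: np.minimum(np.exp(b + lp), 0.99).mean(), spec.base_rate
            )
            p = np.minimum(np.exp(b + lp), 0.99)
        return rng.binomial(1, p)
    # categorical: baseline-category logit, level c gets (c/(k-1)) * lp
    k = spec.k
    eta = np.zeros((lp.size, k))
    for c in range(1, k):
        eta[:, c] = (c / (k - 1)) * lp
    pr = np.exp(eta - eta.max(axis=1, keepdims=True))
    pr /= pr.sum(axis=1, keepdims=True)
    cum = pr.cumsum(axis=1)
    udraw = rng.uniform(size=lp.size)[:, None]
    return (udraw > cum).sum(axis=1)


def _solve_intercept(mean_fn, target: float, lo: float = -20.0, hi: float = 10.0) -> float:
    """Bisection for the intercept giving a target marginal prevalence."""
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_fn(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def emulate_gwas(config: SimulationConfig, panel: GenotypePanel) -> pd.DataFrame:
    """Emulate discovery-GWAS summary statistics for the panel's variants.

    Per-variant reported effect = true liability effect + Gaussian noise
    with SE = 1 / sqrt(gwas_n * 2 * MAF * (1 - MAF)), the standard error of
    a per-allele regression coefficient on a unit-variance trait; p-values
    from the two-sided Wald statistic. Null variants therefore carry
    approximately uniform p-values.
    """
    rng = _rng(config, 3)
    v = panel.variants
    maf = v["MAF"].to_numpy(float).clip(1e-6, 0.5)
    se = 1.0 / np.sqrt(config.gwas_n * 2.0 * maf * (1.0 - maf))
    beta_hat = v["beta_liability"].to_numpy() + rng.normal(0.0, se)
    z = beta_hat / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "SNP": v["SNP"], "CHR": v["CHR"], "POS": v["POS"],
        "A1": v["A1"], "A2": v["A2"],
        "BETA": beta_hat, "SE": se, "P": p,
        "MAF": maf, "INFO": v["INFO"], "HWE_P": v["HWE_P"],
    })


def inject_missingness(cohort: SyntheticCohort, config: SimulationConfig) -> SyntheticCohort:
    """Introduce MAR covariate missingness and "prefer not to say" items.

    Covariate cells go missing at random *conditional on observed sex and
    age* (the missingness probability is modulated by a logistic weight in
    those two, rescaled so the marginal rate matches the configured rate).
    Exposure items are set to the PNS sentinel independently with
    ``pns_rate``. Original values are retained in the truth channel under
    ``orig_<column>``.
    """
    rng = _rng(config, 4)
    data = cohort.data.copy()
    truth = cohort.truth.copy()

    rates = config.missing_rate_covariates
    if isinstance(rates, dict):
        rate_map = dict(rates)
    else:
        rate_map = {c: float(rates) for c in DEFAULT_MISSING_TARGETS} if rates else {}

    age_z = _standardize(data["age_enrollment"].to_numpy(float))
    w = expit(0.5 * age_z + 0.4 * (data["sex"].to_numpy(float) - 0.5))
    w = w / w.mean()
    for col, rate in rate_map.items():
        if rate <= 0:
            continue
        p = np.clip(rate * w, 0.0, 1.0)
        mask = rng.uniform(size=len(data)) < p
        truth[f"orig_{col}"] = data[col].to_numpy()
        if pd.api.types.is_numeric_dtype(data[col]):
            vals = data[col].to_numpy(float).copy()
            vals[mask] = np.nan
            data[col] = vals
        else:
            data[col] = data[col].astype(object).mask(mask, np.nan)

    if config.pns_rate > 0:
        for item in ITEM_NAMES:
            mask = rng.uniform(size=len(data)) < config.pns_rate
            truth[f"orig_{item}"] = data[item].to_numpy()
            vals = data[item].to_numpy().copy()
            vals[mask] = PNS_CODE
            data[item] = vals
    return SyntheticCohort(data=data, truth=truth, config=cohort.config)
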