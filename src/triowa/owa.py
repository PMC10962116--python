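"""Observational outcome-wide analysis engine.

Codes the count exposure from five dichotomized ordinal screener items,
screens the outcome catalog (prevalence and missingness rules), dispatches
each outcome to the correct regression family — linear on the standardized
outcome, logistic for rare binary outcomes, modified Poisson (log-link
Poisson with a robust sandwich variance) for common binary outcomes,
baseline-category multinomial for categoricals — and produces per-level
and trend estimates pooled over multiply imputed datasets, with
Benjamini-Hochberg FDR correction applied separately per contrast, overall
and sex-stratified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .impute import ImputedStack, pool_rubin
from .records import FitRecord, FAMILY_SCALE
from .simulate import ITEM_NAMES, PNS_CODE

EXPOSURE_LEVELS = ["0", "1", "2", "3", "4-5"]
#: numeric score per category level for the test of trend ("4-5" scores 4)
TREND_CODES = {"0": 0.0, "1": 1.0, "2": 2.0, "3": 3.0, "4-5": 4.0}

DEFAULT_COVARIATES = [
    "sex", "age_enrollment", "age_mhq", "ethnicity", "country_of_birth_uk",
    "breastfed", "multiple_birth", "n_siblings", "birthweight",
    "maternal_smoking", "maternal_depression",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class MaltreatmentExposure:
    """Dichotomized maltreatment type flags and their count coding."""

    flags: Tuple[bool, bool, bool, bool, bool]
    count: int
    category: str

    def __post_init__(self) -> None:
        if self.count != sum(self.flags):
            raise ValueError("count must equal the number of set flags")
        expected = "4-5" if self.count >= 4 else str(self.count)
        if self.category != expected:
            raise ValueError(f"category {self.category!r} inconsistent with count {self.count}")


@dataclass
class OutcomeSpec:
    """Catalog entry for one outcome after screening."""

    name: str
    declared_type: str                  # continuous | binary | categorical
    theme: str = "misc"
    prevalence: Optional[float] = None  # binary only
    missing_fraction: float = 0.0
    included: bool = True
    exclusion_reason: Optional[str] = None


@dataclass
class FdrSettings:
    alpha: float = 0.05


@dataclass
class OwaSettings:
    """Configuration of the observational scan."""

    cutoffs: Tuple[int, ...] = (3, 3, 3, 3, 3)
    alpha: float = 0.05
    covariates: List[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    strata: Tuple[str, ...] = ("all", "female", "male")
    per_level: bool = True
    include_trend: bool = True
    prevalence_poisson_cutoff: float = 0.10
    rare_exclusion_prevalence: float = 0.01
    missingness_exclusion: float = 0.40


@dataclass
class OwaResults:
    """Fitted records plus the logged multiplicity enumeration."""

    records: List[FitRecord]
    test_enumeration: Dict[str, int] = field(default_factory=dict)
    n_nonconverged: int = 0
    screened: List[OutcomeSpec] = field(default_factory=list)


def dichotomize_items(scores: Sequence[float], cutoffs: Sequence[int]) -> MaltreatmentExposure:
    """Dichotomize five 1-5 item scores at per-item cutoffs (inclusive).

    A flag is set when the item score is at or above its cutoff. The count
    of set flags is recoded to the five-level category 0/1/2/3/"4-5" (the
    top two counts are combined because of their low prevalence).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (5,) or len(cutoffs) != 5:
        raise ValueError("expected five item scores and five cutoffs")
    if np.any(np.isnan(scores)) or np.any(scores == PNS_CODE):
        raise ValueError(
            "unresolved missing/'prefer not to say' item scores: impute before coding"
        )
    if scores.min() < 1 or scores.max() > 5:
        raise ValueError("item scores must lie on the 1-5 scale")
    flags = tuple(bool(s >= c) for s, c in zip(scores, cutoffs))
    count = int(sum(flags))
    category = "4-5" if count >= 4 else str(count)
    return MaltreatmentExposure(flags=flags, count=count, category=category)


def code_exposure(df: pd.DataFrame, cutoffs: Sequence[int],
                  item_cols: Sequence[str] = tuple(ITEM_NAMES)) -> pd.DataFrame:
    """Vectorized exposure coding: adds count, category and trend columns."""
    items = df[list(item_cols)].to_numpy(float)
    if np.any(np.isnan(items)) or np.any(items == PNS_CODE):
        raise ValueError(
            "unresolved missing/'prefer not to say' item scores: impute before coding"
        )
    flags = items >= np.asarray(cutoffs, dtype=float)[None, :]
    count = flags.sum(axis=1).astype(int)
    out = df.copy()
    out["maltreatment_count"] = count
    cat = np.where(count >= 4, "4-5", count.astype(str))
    out["maltreatment_cat"] = pd.Categorical(cat, categories=EXPOSURE_LEVELS)
    out["maltreatment_trend"] = np.minimum(count, 4).astype(float)
    return out


def screen_outcomes(catalog: pd.DataFrame, cohort: pd.DataFrame,
                    settings: Optional[OwaSettings] = None) -> List[OutcomeSpec]:
    """Apply the outcome inclusion rules to a catalog.

    Binary outcomes with prevalence at or below 1% are excluded
    (inclusion requires prevalence > 1%); any outcome with more than 40%
    missingness is excluded. Reasons are recorded on the returned specs.
    ``catalog`` needs columns ``name`` and ``type`` (optionally ``theme``).
    """
    settings = settings or OwaSettings()
    specs = []
    for _, row in catalog.iterrows():
        name, typ = row["name"], row["type"]
        theme = row.get("theme", "misc")
        y = cohort[name]
        miss = float(y.isna().mean())
        prev = float(y.dropna().mean()) if typ == "binary" else None
        spec = OutcomeSpec(name=name, declared_type=typ, theme=theme,
                           prevalence=prev, missing_fraction=miss)
        if miss > settings.missingness_exclusion:
            spec.included, spec.exclusion_reason = False, "missingness"
        elif typ == "binary" and prev is not None and prev <= settings.rare_exclusion_prevalence:
            spec.included, spec.exclusion_reason = False, "prevalence"
        specs.append(spec)
    return specs


def select_family(spec: OutcomeSpec,
                  settings: Optional[OwaSettings] = None) -> str:
    """Regression-family dispatch.

    Continuous outcomes: linear regression on the z-scored outcome. Binary
    outcomes: logistic below 10% prevalence, modified Poisson (robust
    variance, risk-ratio scale) at or above 10%. Categorical: multinomial.
    """
    settings = settings or OwaSettings()
    if not spec.included:
        raise ValueError(f"outcome {spec.name!r} was excluded ({spec.exclusion_reason})")
    if spec.declared_type == "continuous":
        return "linear"
    if spec.declared_type == "binary":
        if spec.prevalence is None:
            raise ValueError("binary outcome needs a prevalence for dispatch")
        return ("modified-poisson"
                if spec.prevalence >= settings.prevalence_poisson_cutoff
                else "logistic")
    if spec.declared_type == "categorical":
        return "multinomial"
    raise ValueError(f"unknown outcome type {spec.declared_type!r}")


def check_proportional_odds(y: pd.Series, X: pd.DataFrame,
                            term: str) -> Tuple[float, float, bool]:
    """Brant-style Wald test of the proportional-odds assumption.

    Fits a separate binary logistic model at each cumulative split of the
    ordered outcome and tests equality of the coefficient on ``term``
    across splits with a chi-square on (J-2) degrees of freedom (splits
    treated as independent, a conservative approximation). Returns
    (statistic, p, holds) with ``holds = (p >= 0.05)``.
    """
    levels = np.sort(pd.unique(y.dropna()))
    if len(levels) < 3:
        raise ValueError("proportional-odds check requires >= 3 ordered levels")
    Xd = _design_frame(X)
    j = list(Xd.columns).index(term)
    betas, vars_ = [], []
    for cut in levels[1:]:
        yy = (y >= cut).astype(float)
        if yy.nunique() < 2:
            raise ValueError(f"degenerate cumulative split at level {cut}")
        res = sm.GLM(yy, sm.add_constant(Xd), family=sm.families.Binomial()).fit()
        betas.append(res.params.iloc[j + 1])
        vars_.append(res.cov_params().iloc[j + 1, j + 1])
    betas, vars_ = np.asarray(betas), np.asarray(vars_)
    w = 1.0 / vars_
    bbar = np.sum(w * betas) / np.sum(w)
    stat = float(np.sum(w * (betas - bbar) ** 2))
    dof = len(betas) - 1
    p = float(stats.chi2.sf(stat, dof))
    return stat, p, p >= 0.05


def _design_frame(X: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode object/categorical covariates; pass numerics through."""
    cols = {}
    for c in X.columns:
        s = X[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            for d in dummies.columns:
                cols[d] = dummies[d]
        else:
            cols[c] = s.astype(float)
    return pd.DataFrame(cols, index=X.index)


def _exposure_design(df: pd.DataFrame, contrast: str) -> Tuple[pd.DataFrame, List[str]]:
    """Exposure columns: per-level dummies or the numeric trend score."""
    if contrast == "trend":
        return df[["maltreatment_trend"]].astype(float), ["maltreatment_trend"]
    cat = df["maltreatment_cat"]
    if cat.nunique() < 2:
        raise ValueError("exposure is constant: no contrast estimable")
    present = set(cat.value_counts()[lambda s: s > 0].index)
    terms = []
    cols = {}
    for lev in EXPOSURE_LEVELS[1:]:
        if lev not in present:
            continue  # level absent in this stratum/dataset: no contrast
        col = f"malt_{lev}"
        cols[col] = (cat == lev).astype(float)
        terms.append(col)
    if not terms:
        raise ValueError("exposure is constant: no contrast estimable")
    return pd.DataFrame(cols, index=df.index), terms


def _fit_single(df: pd.DataFrame, outcome: str, family: str,
                contrast: str, covariates: Sequence[str]):
    """Fit one model on one completed dataset.

    Returns a dict mapping contrast label -> (link-scale coef, SE), plus n.
    Multinomial keys are (outcome_level, contrast_label).
    """
    Xe, terms = _exposure_design(df, contrast)
    Xc = _design_frame(df[list(covariates)])
    X = sm.add_constant(pd.concat([Xe, Xc], axis=1))
    y = df[outcome]
    keep = y.notna()
    X, y = X.loc[keep], y.loc[keep]
    n = int(keep.sum())

    label = {f"malt_{lev}": f"{lev}v0" for lev in EXPOSURE_LEVELS[1:]}
    label["maltreatment_trend"] = "trend"

    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "linear":
            yz = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
            res = sm.OLS(yz.astype(float), X.astype(float)).fit()
        elif family == "logistic":
            res = sm.GLM(y.astype(float), X.astype(float),
                         family=sm.families.Binomial()).fit(maxiter=100)
        elif family == "modified-poisson":
            res = sm.GLM(y.astype(float), X.astype(float),
                         family=sm.families.Poisson()).fit(cov_type="HC1", maxiter=100)
        elif family == "multinomial":
            codes, levels = _most_frequent_reference(y)
            res = sm.MNLogit(codes, X.astype(float)).fit(disp=0, maxiter=200)
            params, bse = np.asarray(res.params), np.asarray(res.bse)
            xcols = list(X.columns)
            for k, lev in enumerate(levels[1:]):
                for t in terms:
                    i = xcols.index(t)
                    out[(str(lev), label[t])] = (params[i, k], bse[i, k])
            return out, n
        else:
            raise ValueError(f"unknown family {family!r}")
    for t in terms:
        out[label[t]] = (float(res.params[t]), float(res.bse[t]))
    return out, n


def _most_frequent_reference(y: pd.Series):
    counts = y.value_counts()
    levels = [counts.idxmax()] + [l for l in counts.index if l != counts.idxmax()]
    mapping = {lev: i for i, lev in enumerate(levels)}
    return y.map(mapping).astype(int).to_numpy(), levels


def _pooled_record(outcome: str, contrast: str, family: str, theme: str,
                   ests: List[float], ses: List[float], n: int,
                   stratum: str) -> FitRecord:
    est, se, dfp = pool_rubin(ests, ses)
    scale = FAMILY_SCALE[family]
    # reference distribution: t with Rubin's pooled df (normal when df=inf)
    if np.isfinite(dfp):
        crit = stats.t.ppf(0.975, dfp)
        p = 2 * stats.t.sf(abs(est / se), dfp) if se > 0 else 1.0
    else:
        crit = Z95
        p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else 1.0
    lo, hi = est - crit * se, est + crit * se
    if scale in ("OR", "RR"):
        est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
    return FitRecord(outcome=outcome, contrast=contrast, family=family,
                     scale=scale, estimate=float(est), se=float(se),
                     ci_low=float(lo), ci_high=float(hi), p=float(p),
                     n_used=n, stratum=stratum, theme=theme)


def fit_outcome(stack: ImputedStack, spec: OutcomeSpec,
                covariates: Sequence[str], contrast: str = "per-level",
                stratum: str = "all",
                settings: Optional[OwaSettings] = None) -> List[FitRecord]:
    """Fit one outcome across the imputed stack and pool with Rubin's rules.

    ``contrast="per-level"`` yields one record per non-reference exposure
    level (1, 2, 3 and 4-5 versus 0); ``contrast="trend"`` a single record
    treating the five-level category as a numeric 0-4 score. A fit that
    fails (separation, non-convergence) yields a flagged record rather than
    raising.
    """
    settings = settings or OwaSettings()
    family = select_family(spec, settings)
    fit_contrast = "trend" if contrast == "trend" else "per-level"
    per_fit: Dict = {}
    n = 0
    try:
        for df in stack.datasets:
            sub = _stratify(df, stratum)
            coefs, n = _fit_single(sub, spec.name, family,
                                   "trend" if fit_contrast == "trend" else "levels",
                                   covariates)
            for key, (b, s) in coefs.items():
                per_fit.setdefault(key, []).append((b, s))
    except np.linalg.LinAlgError:
        return [_failed_record(spec, contrast, family, stratum)]
    except (ValueError, RuntimeError) as err:
        if "no contrast estimable" in str(err):
            raise
        return [_failed_record(spec, contrast, family, stratum)]

    records = []
    for key, pairs in per_fit.items():
        # drop per-dataset fits that degenerated numerically (separation,
        # runaway log-link cells); a link-scale SE above 50 can only come
        # from such a fit. Pool the sound ones; flag if most are degenerate.
        good = [(b, s) for b, s in pairs
                if np.isfinite(b) and np.isfinite(s) and 0 < s <= 50]
        if len(good) < max(1, (len(pairs) + 1) // 2):
            records.append(_failed_record(spec, _key_contrast(key), family, stratum,
                                          outcome=_key_outcome(spec.name, key)))
            continue
        records.append(_pooled_record(_key_outcome(spec.name, key),
                                      _key_contrast(key), family, spec.theme,
                                      [b for b, _ in good], [s for _, s in good],
                                      n, stratum))
    return records


def _key_contrast(key) -> str:
    return key[1] if isinstance(key, tuple) else key


def _key_outcome(name: str, key) -> str:
    return f"{name}[{key[0]}]" if isinstance(key, tuple) else name


def _failed_record(spec: OutcomeSpec, contrast: str, family: str,
                   stratum: str, outcome: Optional[str] = None) -> FitRecord:
    return FitRecord(outcome=outcome or spec.name, contrast=contrast,
                     family=family, scale=FAMILY_SCALE[family],
                     estimate=np.nan, se=np.nan, ci_low=np.nan,
                     ci_high=np.nan, p=np.nan, stratum=stratum,
                     theme=spec.theme, converged=False)


def _stratify(df: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return df
    if stratum == "female":
        return df[df["sex"] == 1]
    if stratum == "male":
        return df[df["sex"] == 0]
    raise ValueError(f"unknown stratum {stratum!r}")


def trend_fit(stack: ImputedStack, spec: OutcomeSpec,
              covariates: Sequence[str], stratum: str = "all",
              settings: Optional[OwaSettings] = None) -> List[FitRecord]:
    """Test of trend: the five-level count treated as a numeric 0-4 score."""
    return fit_outcome(stack, spec, covariates, contrast="trend",
                       stratum=stratum, settings=settings)


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up q-values and rejection flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def _strata_for(settings: OwaSettings, covariates: Sequence[str]) -> List[Tuple[str, List[str]]]:
    out = []
    for s in settings.strata:
        covs = list(covariates)
        if s in ("female", "male") and "sex" in covs:
            covs = [c for c in covs if c != "sex"]
        out.append((s, covs))
    return out


def apply_fdr(records: List[FitRecord], alpha: float = 0.05) -> Dict[str, int]:
    """Assign q-values within each (contrast, stratum) test family.

    Non-convergent records are excluded from the enumeration (their q stays
    NaN). Returns the per-family test counts actually used. Categorical
    outcomes contribute one test per non-reference outcome level, so a
    catalog of 414 outcomes with a few categoricals enumerates to slightly
    more tests than outcomes.
    """
    groups: Dict[Tuple[str, str], List[FitRecord]] = {}
    for r in records:
        if r.converged and np.isfinite(r.p):
            groups.setdefault((r.contrast, r.stratum), []).append(r)
    enumeration = {}
    for (contrast, stratum), grp in groups.items():
        q, rej = bh_fdr([r.p for r in grp], alpha)
        for r, qi, ri in zip(grp, q, rej):
            r.q, r.rejected = float(qi), bool(ri)
        enumeration[f"{contrast}|{stratum}"] = len(grp)
    return enumeration


def run_observational_owa(stack: ImputedStack, catalog: pd.DataFrame,
                          settings: Optional[OwaSettings] = None) -> OwaResults:
    """Full observational scan over a screened outcome catalog.

    Codes the exposure within every imputed dataset, screens outcomes on
    the first completed dataset, fits per-level and trend models in each
    requested stratum, pools across imputations, and FDR-corrects each
    (contrast, stratum) family separately. Per-outcome failures are
    recorded, never propagated.
    """
    settings = settings or OwaSettings()
    coded = ImputedStack(
        datasets=[code_exposure(df, settings.cutoffs) for df in stack.datasets],
        trace=stack.trace,
    )
    specs = screen_outcomes(catalog, coded.datasets[0], settings)
    records: List[FitRecord] = []
    for spec in specs:
        if not spec.included:
            continue
        for stratum, covs in _strata_for(settings, settings.covariates):
            if settings.per_level:
                records.extend(fit_outcome(coded, spec, covs,
                                           stratum=stratum, settings=settings))
            if settings.include_trend:
                records.extend(trend_fit(coded, spec, covs,
                                         stratum=stratum, settings=settings))
    enumeration = apply_fdr(records, settings.alpha)
    n_fail = sum(1 for r in records if not r.converged)
    return OwaResults(records=records, test_enumeration=enumeration,
                      n_nonconverged=n_fail, screened=specs)
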