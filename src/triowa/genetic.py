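"""Genetic outcome-wide analysis: outcomes regressed on a polygenic score.

Mirrors the observational engine's family dispatch and FDR machinery, with
the standardized polygenic score (or its quintiles) as the exposure and
the genetic covariate set — birth year, sex, sequencing array, and the top
20 principal components of the dosage matrix — as adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .owa import (
    OutcomeSpec, OwaSettings, screen_outcomes, select_family,
    apply_fdr, _design_frame, _stratify, Z95,
)
from .records import FitRecord, FAMILY_SCALE
from .prs import ScoreVector


@dataclass
class GeneticOwaSettings:
    """Configuration of the genetic scan."""

    alpha: float = 0.05
    n_pcs: int = 20
    covariates: List[str] = field(default_factory=lambda: ["birth_year", "sex", "array"])
    strata: Tuple[str, ...] = ("all",)
    use_quintiles: bool = False
    include_trend: bool = True
    prevalence_poisson_cutoff: float = 0.10


def compute_pcs(dosages: pd.DataFrame, k: int = 20) -> np.ndarray:
    """Top-k principal component scores of the column-standardized dosages.

    Components are orthogonal; each component's sign is fixed by making its
    largest-magnitude variant loading positive, so the result is invariant
    to sign indeterminacy of the SVD. Monomorphic variants are dropped.
    """
    G = dosages.to_numpy(float)
    sd = G.std(axis=0)
    G = G[:, sd > 0]
    G = (G - G.mean(axis=0)) / G[:, :].std(axis=0)
    U, S, Vt = np.linalg.svd(G, full_matrices=False)
    rank = int((S > S[0] * 1e-10).sum()) if S.size else 0
    if k > rank:
        raise ValueError(f"requested {k} components but matrix rank is {rank}")
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def _score_design(df: pd.DataFrame, scores: ScoreVector,
                  mode: str) -> Tuple[pd.DataFrame, List[str], Dict[str, str]]:
    if mode == "per-SD":
        s = scores.standardized
        if s is None:
            s = scores.raw
        if np.std(s) == 0:
            raise ValueError("PRS has zero variance: no contrast estimable")
        return (pd.DataFrame({"prs": s}, index=df.index), ["prs"], {"prs": "per-SD"})
    if mode == "quintile":
        q = scores.quintile
        cols, terms, labels = {}, [], {}
        for lev in (2, 3, 4, 5):
            col = f"prs_q{lev}"
            cols[col] = (q == lev).astype(float)
            terms.append(col)
            labels[col] = f"Q{lev}v1"
        return pd.DataFrame(cols, index=df.index), terms, labels
    if mode == "quintile-trend":
        return (pd.DataFrame({"prs_qt": scores.quintile.astype(float)}, index=df.index),
                ["prs_qt"], {"prs_qt": "quintile-trend"})
    raise ValueError(f"unknown score mode {mode!r}")


def _fit_genetic(df: pd.DataFrame, spec: OutcomeSpec, family: str,
                 scores: ScoreVector, mode: str,
                 covariates: Sequence[str], pcs: np.ndarray,
                 stratum: str) -> List[FitRecord]:
    sub = _stratify(df, stratum)
    idx = sub.index
    Xe, terms, labels = _score_design(df, scores, mode)
    Xc = _design_frame(sub[list(covariates)])
    pc_cols = pd.DataFrame(pcs, index=df.index,
                           columns=[f"PC{i+1}" for i in range(pcs.shape[1])])
    X = sm.add_constant(pd.concat([Xe.loc[idx], Xc, pc_cols.loc[idx]], axis=1))
    y = sub[spec.name]
    keep = y.notna()
    X, y = X.loc[keep], y.loc[keep]
    n = int(keep.sum())

    scale = FAMILY_SCALE[family]
    records = []
    try:
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
                             family=sm.families.Poisson()).fit(cov_type="HC1",
                                                               maxiter=100)
            elif family == "multinomial":
                return _fit_genetic_multinomial(X, y, spec, terms, labels,
                                                n, stratum)
            else:
                raise ValueError(f"unknown family {family!r}")
        for t in terms:
            b, s = float(res.params[t]), float(res.bse[t])
            records.append(_mk_record(spec, labels[t], family, scale,
                                      b, s, n, stratum))
    except (np.linalg.LinAlgError, RuntimeError):
        records.append(FitRecord(outcome=spec.name, contrast=mode, family=family,
                                 scale=scale, estimate=np.nan, se=np.nan,
                                 ci_low=np.nan, ci_high=np.nan, p=np.nan,
                                 stratum=stratum, theme=spec.theme,
                                 converged=False))
    return records


def _fit_genetic_multinomial(X, y, spec, terms, labels, n, stratum):
    from .owa import _most_frequent_reference
    codes, levels = _most_frequent_reference(y)
    res = sm.MNLogit(codes, X.astype(float)).fit(disp=0, maxiter=200)
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    xcols = list(X.columns)
    records = []
    for k, lev in enumerate(levels[1:]):
        for t in terms:
            i = xcols.index(t)
            records.append(_mk_record(
                spec, labels[t], "multinomial", "OR",
                params[i, k], bse[i, k], n, stratum,
                outcome=f"{spec.name}[{lev}]"))
    return records


def _mk_record(spec, contrast, family, scale, b, s, n, stratum, outcome=None):
    # SEs above 50 on the link scale only arise from degenerate fits
    if not (np.isfinite(b) and np.isfinite(s)) or s <= 0 or s > 50:
        return FitRecord(outcome=outcome or spec.name, contrast=contrast,
                         family=family, scale=scale, estimate=np.nan, se=np.nan,
                         ci_low=np.nan, ci_high=np.nan, p=np.nan,
                         stratum=stratum, theme=spec.theme, converged=False)
    lo, hi = b - Z95 * s, b + Z95 * s
    p = 2 * stats.norm.sf(abs(b / s))
    est = b
    if scale in ("OR", "RR"):
        est, lo, hi = np.exp(b), np.exp(lo), np.exp(hi)
    return FitRecord(outcome=outcome or spec.name, contrast=contrast,
                     family=family, scale=scale, estimate=float(est),
                     se=float(s), ci_low=float(lo), ci_high=float(hi),
                     p=float(p), n_used=n, stratum=stratum, theme=spec.theme)


def run_genetic_owa(cohort: pd.DataFrame, scores: ScoreVector,
                    catalog: pd.DataFrame, dosages: pd.DataFrame,
                    settings: Optional[GeneticOwaSettings] = None):
    """Scan all screened outcomes against the polygenic score.

    Primary run: one record per outcome, effect per SD of the standardized
    score, adjusted for birth year, sex, sequencing array and the top
    ``n_pcs`` dosage principal components, FDR-corrected across the
    enumerated tests. ``use_quintiles=True`` adds per-quintile contrasts
    versus the bottom quintile plus a quintile trend. Family dispatch
    reuses the observational rule (linear / logistic / modified Poisson /
    multinomial by declared type and prevalence).
    """
    from .owa import OwaResults

    settings = settings or GeneticOwaSettings()
    owa_like = OwaSettings(alpha=settings.alpha,
                           prevalence_poisson_cutoff=settings.prevalence_poisson_cutoff)
    specs = screen_outcomes(catalog, cohort, owa_like)
    pcs = compute_pcs(dosages, settings.n_pcs)

    modes = ["per-SD"]
    if settings.use_quintiles:
        modes = ["quintile", "quintile-trend"] + modes
    records: List[FitRecord] = []
    for spec in specs:
        if not spec.included:
            continue
        family = select_family(spec, owa_like)
        for stratum in settings.strata:
            covs = [c for c in settings.covariates
                    if not (stratum in ("female", "male") and c == "sex")]
            for mode in modes:
                if mode == "quintile-trend" and not settings.include_trend:
                    continue
                records.extend(_fit_genetic(cohort, spec, family, scores, mode,
                                            covs, pcs, stratum))
    enumeration = apply_fdr(records, settings.alpha)
    n_fail = sum(1 for r in records if not r.converged)
    return OwaResults(records=records, test_enumeration=enumeration,
                      n_nonconverged=n_fail, screened=specs)
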