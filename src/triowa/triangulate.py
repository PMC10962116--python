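"""Triangulation of observational and genetic outcome-wide results.

Joins the two arms per outcome (observational trend contrast against the
per-SD polygenic-score contrast), classifies each pair into a concordance
category, overlays the E-value robustness flag from the observational arm,
and summarizes counts and proportions by health theme.

The four-way taxonomy (plus the never-hoped-for fifth):

* ``concordant_significant`` — significant in both arms, same direction;
* ``observational_only``     — significant only in the observational arm;
* ``genetic_only``           — significant only in the genetic arm;
* ``neither``                — significant in neither;
* ``discordant``             — significant in both, opposite directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .records import FitRecord, TriangulationRecord

CATEGORIES = ["concordant_significant", "observational_only",
              "genetic_only", "neither", "discordant"]


def classify_concordance(obs: FitRecord, gen: FitRecord) -> str:
    """Concordance category for one outcome's pair of results.

    Significance means FDR-rejected within each arm separately. Direction
    is the sign of the link-scale estimate (log for ratio scales, the beta
    itself for linear models), so protective ratio estimates compare
    correctly.
    """
    if obs.outcome != gen.outcome:
        raise ValueError(
            f"cannot join results for different outcomes: {obs.outcome!r} vs {gen.outcome!r}"
        )
    if obs.rejected and gen.rejected:
        if obs.direction == gen.direction or obs.direction == 0 or gen.direction == 0:
            return "concordant_significant"
        return "discordant"
    if obs.rejected:
        return "observational_only"
    if gen.rejected:
        return "genetic_only"
    return "neither"


def triangulate(
    obs_records: Iterable[FitRecord],
    gen_records: Iterable[FitRecord],
    robust_flags: Optional[Dict[str, bool]] = None,
    obs_contrast: str = "trend",
    gen_contrast: str = "per-SD",
    stratum: str = "all",
) -> Tuple[List[TriangulationRecord], List[str]]:
    """Join the two arms per outcome and classify.

    Returns (records, unjoined outcome names). Outcomes present in only one
    arm are reported separately, never forced into a category. Only
    converged records of the requested contrast and stratum participate.
    """
    robust_flags = robust_flags or {}
    obs_map = {r.outcome: r for r in obs_records
               if r.contrast == obs_contrast and r.stratum == stratum and r.converged}
    gen_map = {r.outcome: r for r in gen_records
               if r.contrast == gen_contrast and r.stratum == stratum and r.converged}
    shared = [o for o in obs_map if o in gen_map]
    unjoined = sorted(set(obs_map) ^ set(gen_map))
    records = []
    for name in shared:
        o, g = obs_map[name], gen_map[name]
        records.append(TriangulationRecord(
            outcome=name, theme=o.theme, obs=o, gen=g,
            category=classify_concordance(o, g),
            robust_observational=bool(robust_flags.get(name, False)),
        ))
    return records, unjoined


def summarize(records: List[TriangulationRecord]):
    """Theme-level and overall concordance summary.

    Returns (theme_summary DataFrame, overall dict, scatter DataFrame).
    Theme proportions sum to 1 within each theme; the overall dict carries
    category proportions and the robust share among the concordant and
    observational-only sets; the scatter table pairs the two arms'
    estimates per outcome for plotting.
    """
    if not records:
        return pd.DataFrame(), {}, pd.DataFrame()
    rows = [{"outcome": r.outcome, "theme": r.theme, "category": r.category,
             "robust": r.robust_observational,
             "obs_estimate": r.obs.estimate, "gen_estimate": r.gen.estimate,
             "obs_scale": r.obs.scale, "gen_scale": r.gen.scale}
            for r in records]
    df = pd.DataFrame(rows)

    theme_rows = []
    for theme, grp in df.groupby("theme"):
        n = len(grp)
        row = {"theme": theme, "n": n}
        for cat in CATEGORIES:
            row[f"n_{cat}"] = int((grp["category"] == cat).sum())
            row[f"prop_{cat}"] = row[f"n_{cat}"] / n
        row["prop_robust"] = float(grp["robust"].mean())
        theme_rows.append(row)
    theme_summary = pd.DataFrame(theme_rows)

    n = len(df)
    overall = {"n_outcomes": n}
    for cat in CATEGORIES:
        overall[f"prop_{cat}"] = float((df["category"] == cat).mean())
    for cat in ("concordant_significant", "observational_only"):
        sub = df[df["category"] == cat]
        overall[f"prop_robust_{cat}"] = (
            float(sub["robust"].mean()) if len(sub) else np.nan)

    scatter = df[["outcome", "theme", "category",
                  "obs_estimate", "gen_estimate"]].copy()
    return theme_summary, overall, scatter
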