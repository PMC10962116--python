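"""Clumping-and-thresholding polygenic score construction.

Builds a per-individual polygenic risk score (PRS) from GWAS summary
statistics and a genotype dosage matrix: variant QC (MAF, Hardy-Weinberg,
imputation info), greedy LD clumping (ascending p-value, removing
correlated neighbours within a distance window), p-value thresholding,
allele-aligned weighted allele-dosage summation, standardization, and
rank-based quintile binning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: required summary-statistics columns
SUMSTATS_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "P", "MAF", "INFO"]


@dataclass
class PrsSettings:
    """QC, clumping and thresholding parameters.

    Defaults follow common biobank-scale practice: common variants only
    (MAF > 0.01), a permissive Hardy-Weinberg filter (p > 1e-10), well
    imputed variants (info > 0.8), clumping at pairwise R^2 >= 0.1 within
    250 kb, and two p-value thresholds — genome-wide significance (5e-8)
    and a liberal 0.5 threshold.
    """

    maf_min: float = 0.01
    hwe_p_min: float = 1e-10
    info_min: float = 0.8
    clump_r2: float = 0.1
    clump_kb: float = 250.0
    p_thresholds: tuple = (5e-8, 0.5)
    standardize: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.clump_kb <= 0:
            raise ValueError("clump_kb must be positive")
        if not (0 < self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in (0, 1]")


@dataclass
class ClumpResult:
    """Index variants retained by clumping plus per-variant removal reasons."""

    retained: list
    removed: dict = field(default_factory=dict)  # snp -> "qc" | "clumped-by:<snp>"


@dataclass
class ScoreVector:
    """Per-individual polygenic score at one p-value threshold."""

    raw: np.ndarray
    standardized: Optional[np.ndarray]
    quintile: np.ndarray
    threshold: float
    n_variants: int


def _require_columns(summary: pd.DataFrame) -> None:
    missing = [c for c in SUMSTATS_COLUMNS if c not in summary.columns]
    if missing:
        raise ValueError(f"summary statistics missing required columns: {missing}")


def variant_qc(summary: pd.DataFrame, settings: PrsSettings) -> pd.DataFrame:
    """Filter variants on MAF, Hardy-Weinberg p and imputation info.

    All three comparisons are strict: a variant is retained only if
    MAF > maf_min, HWE p > hwe_p_min and info > info_min. Removal reasons
    are recorded in a ``qc_fail`` column of the returned copy's attrs.
    """
    _require_columns(summary)
    if "HWE_P" not in summary.columns:
        raise ValueError("summary statistics missing required columns: ['HWE_P']")
    maf = np.minimum(summary["MAF"].to_numpy(float), 1 - summary["MAF"].to_numpy(float))
    ok_maf = maf > settings.maf_min
    ok_hwe = summary["HWE_P"].to_numpy(float) > settings.hwe_p_min
    ok_info = summary["INFO"].to_numpy(float) > settings.info_min
    keep = ok_maf & ok_hwe & ok_info
    reasons = {}
    for i, snp in enumerate(summary["SNP"]):
        if not keep[i]:
            why = []
            if not ok_maf[i]:
                why.append("maf")
            if not ok_hwe[i]:
                why.append("hwe")
            if not ok_info[i]:
                why.append("info")
            reasons[snp] = "+".join(why)
    out = summary.loc[keep].reset_index(drop=True)
    out.attrs["qc_removed"] = reasons
    return out


def greedy_clump(
    summary: pd.DataFrame,
    dosages: pd.DataFrame,
    settings: PrsSettings,
) -> ClumpResult:
    """Greedy LD clumping on dosage correlations.

    Variants are visited in ascending p-value order (ties broken by
    chromosome then position, so the result is deterministic); each visited
    variant is retained as an index variant and all not-yet-decided variants
    on the same chromosome within ``clump_kb`` kilobases whose squared
    Pearson dosage correlation with it is >= ``clump_r2`` are removed.
    R^2 is estimated in the scoring sample itself. Variants absent from the
    dosage panel are skipped with a warning.
    """
    _require_columns(summary)
    present = summary["SNP"].isin(dosages.columns)
    n_absent = int((~present).sum())
    if n_absent:
        warnings.warn(
            f"{n_absent} variant(s) absent from genotype panel; skipped in clumping"
        )
    tab = summary.loc[present].sort_values(
        ["P", "CHR", "POS"], kind="stable"
    ).reset_index(drop=True)

    G = dosages[tab["SNP"]].to_numpy(float)
    # column-standardize once so R^2 is a dot product
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic: correlates with nothing
    Z = (G - mu) / sd
    n = Z.shape[0]

    chrom = tab["CHR"].to_numpy()
    pos = tab["POS"].to_numpy(float)
    window = settings.clump_kb * 1000.0

    status = np.zeros(len(tab), dtype=int)  # 0 undecided, 1 retained, -1 removed
    removed: dict = {}
    retained: list = []
    for i in range(len(tab)):
        if status[i] != 0:
            continue
        status[i] = 1
        retained.append(tab.at[i, "SNP"])
        near = np.flatnonzero(
            (status == 0)
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        if near.size:
            r2 = (Z[:, near].T @ Z[:, i]) ** 2 / n**2
            hit = near[r2 >= settings.clump_r2]
            status[hit] = -1
            for j in hit:
                removed[tab.at[int(j), "SNP"]] = f"clumped-by:{tab.at[i, 'SNP']}"
    return ClumpResult(retained=retained, removed=removed)


def compute_score(
    dosages: pd.DataFrame,
    summary: pd.DataFrame,
    settings: PrsSettings,
    threshold: float,
    clump: Optional[ClumpResult] = None,
) -> ScoreVector:
    """Weighted effect-allele dosage sum over retained variants below ``threshold``.

    ``score_i = sum_j beta_j * dosage_ij`` where ``dosage_ij`` counts copies
    of the summary-statistics effect allele (A1). When the panel's counted
    allele is A2 instead, the dosage is flipped (``2 - d``); a variant whose
    alleles match neither orientation is dropped with a warning. Raw scores
    are therefore invariant to the panel's allele orientation.
    """
    _require_columns(summary)
    tab = summary
    if clump is not None:
        tab = tab[tab["SNP"].isin(clump.retained)]
    tab = tab[tab["P"] < threshold]

    n = len(dosages)
    raw = np.zeros(n, dtype=float)
    used = 0
    allele_map = dosages.attrs.get("allele_map", {})  # snp -> (counted, other)
    for _, row in tab.iterrows():
        snp = row["SNP"]
        if snp not in dosages.columns:
            continue
        d = dosages[snp].to_numpy(float)
        counted, other = allele_map.get(snp, (row["A1"], row["A2"]))
        if counted == row["A1"]:
            raw += row["BETA"] * d
        elif counted == row["A2"] and other == row["A1"]:
            raw += row["BETA"] * (2.0 - d)
        else:
            warnings.warn(f"variant {snp}: alleles {counted}/{other} do not match "
                          f"{row['A1']}/{row['A2']}; dropped from score")
            continue
        used += 1
    if used == 0:
        warnings.warn(f"no variants pass p < {threshold}; score is identically zero")

    std = None
    if settings.standardize:
        sd = raw.std()
        std = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    quint = quintile_bins(raw) if n >= 5 else np.ones(n, dtype=int)
    return ScoreVector(raw=raw, standardized=std, quintile=quint,
                       threshold=threshold, n_variants=used)


def quintile_bins(raw: np.ndarray) -> np.ndarray:
    """Rank-based quintile labels 1-5 on the raw (unstandardized) score.

    Ties are broken by stable input order, so bin sizes never differ by more
    than one even for constant input.
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.size
    if n < 5:
        raise ValueError("quintile binning requires at least 5 individuals")
    order = np.argsort(raw, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * 5) // n + 1


def check_clump_invariant(
    clump: ClumpResult, summary: pd.DataFrame, dosages: pd.DataFrame,
    settings: PrsSettings,
) -> bool:
    """Post-hoc check: no two retained variants on one chromosome within the
    clump window have pairwise R^2 >= the clump threshold."""
    tab = summary[summary["SNP"].isin(clump.retained)].reset_index(drop=True)
    for i in range(len(tab)):
        for j in range(i + 1, len(tab)):
            if tab.at[i, "CHR"] != tab.at[j, "CHR"]:
                continue
            if abs(tab.at[i, "POS"] - tab.at[j, "POS"]) > settings.clump_kb * 1000:
                continue
            a = dosages[tab.at[i, "SNP"]].to_numpy(float)
            b = dosages[tab.at[j, "SNP"]].to_numpy(float)
            if a.std() == 0 or b.std() == 0:
                continue
            if np.corrcoef(a, b)[0, 1] ** 2 >= settings.clump_r2:
                return False
    return True
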