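"""Plain-text readers and writers for the pipeline's tables.

Cohort tables are TSV with ``NA`` for missing cells and a ``PNS`` sentinel
for "prefer not to say" exposure items; genotypes travel as a TSV dosage
matrix or a minimal VCF (DS/GT fields, 1-based positions); GWAS summary
statistics use the conventional SNP/CHR/POS/A1/A2/BETA/SE/P/MAF/INFO
column layout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .simulate import GenotypePanel, SyntheticCohort, ITEM_NAMES, PNS_CODE

PathLike = Union[str, Path]


def write_cohort(cohort: SyntheticCohort, path: PathLike,
                 truth_path: Optional[PathLike] = None) -> None:
    """Write the cohort table (and optionally its truth channel) as TSV."""
    df = cohort.data.copy()
    for item in ITEM_NAMES:
        if item in df.columns:
            vals = df[item].astype(object)
            df[item] = vals.mask(df[item] == PNS_CODE, "PNS")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    if truth_path is not None:
        cohort.truth.to_csv(truth_path, sep="\t", index=False, na_rep="NA")


def read_cohort(path: PathLike) -> pd.DataFrame:
    """Read a cohort TSV, mapping the PNS sentinel back to its code."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for item in ITEM_NAMES:
        if item in df.columns and df[item].dtype == object:
            df[item] = df[item].replace("PNS", PNS_CODE).astype(float)
    return df


def write_sumstats(sumstats: pd.DataFrame, path: PathLike) -> None:
    sumstats.to_csv(path, sep="\t", index=False)


def read_sumstats(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dosages(panel: GenotypePanel, path: PathLike) -> None:
    """TSV dosage matrix, individuals in rows, variant IDs as columns."""
    panel.dosages.to_csv(path, sep="\t", index=False)


def read_dosages(path: PathLike,
                 variants: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if variants is not None:
        df.attrs["allele_map"] = {
            r["SNP"]: (r["A1"], r["A2"]) for _, r in variants.iterrows()}
    return df


def write_vcf(panel: GenotypePanel, path: PathLike) -> None:
    """Minimal uncompressed VCF with GT and DS fields (1-based positions).

    REF is the panel's non-counted allele (A2) and ALT the counted/effect
    allele (A1), so DS equals the stored alt-allele dosage.
    """
    v = panel.variants
    D = panel.dosages.to_numpy(float)
    samples = [f"S{i}" for i in range(D.shape[0])]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, (_, row) in enumerate(v.iterrows()):
            d = D[:, j]
            cells = [
                f"{gt_map.get(int(round(x)), './.')}:{x:g}" for x in d
            ]
            fh.write(f"{row['CHR']}\t{row['POS']}\t{row['SNP']}\t{row['A2']}\t"
                     f"{row['A1']}\t.\tPASS\t.\tGT:DS\t" + "\t".join(cells) + "\n")


def read_vcf_dosages(path: PathLike) -> pd.DataFrame:
    """Read dosages from a VCF, preferring DS and falling back to GT counts.

    The returned frame counts the ALT allele; the allele map records
    (ALT, REF) as (counted, other) per variant for downstream scoring.
    """
    snps, cols, allele_map = [], [], {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            f = line.rstrip("\n").split("\t")
            snp, ref, alt = f[2], f[3], f[4]
            fmt = f[8].split(":")
            vals = np.empty(len(f) - 9)
            for i, cell in enumerate(f[9:]):
                parts = cell.split(":")
                if "DS" in fmt:
                    vals[i] = float(parts[fmt.index("DS")])
                else:
                    gt = parts[fmt.index("GT")].replace("|", "/")
                    vals[i] = sum(a == "1" for a in gt.split("/"))
            snps.append(snp)
            cols.append(vals)
            allele_map[snp] = (alt, ref)
    df = pd.DataFrame(np.column_stack(cols) if cols else np.empty((0, 0)),
                      columns=snps)
    df.attrs["allele_map"] = allele_map
    return df


def write_results(records, path: PathLike) -> None:
    """Flatten fit or E-value records to a results TSV."""
    from .records import records_to_frame
    records_to_frame(list(records)).to_csv(path, sep="\t", index=False, na_rep="NA")
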