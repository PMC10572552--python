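"""Readers and writers for the package's plain-text data dialects.

GWAS summary statistics travel as tab-delimited text with the header
``SNP EA OA EAF BETA SE P N`` (``NA`` for missing optional fields); LD
matrices as square TSVs with rsIDs on the first row and column; genotype
count tables as CSV with genotype rows and risk-stratum columns.
"""
from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mr.records import LDMatrix, SummaryStatRecord

SUMMARY_COLUMNS = ["SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]


class FormatError(ValueError):
    pass


def _parse_optional(value: str, row: int, col: str, cast=float):
    if value in ("", "NA", "NaN", "."):
        return None
    try:
        return cast(value)
    except ValueError:
        raise FormatError(f"row {row}: non-numeric {col} value {value!r}") from None


def read_summary_stats(path, trait: str = "") -> list[SummaryStatRecord]:
    """Read a GWAS summary-statistics TSV into validated records.

    Raises :class:`FormatError` naming the offending row on malformed
    alleles, non-numeric coefficients, or duplicated rsIDs; an empty file
    is an explicit error.
    """
    path = Path(path)
    records: list[SummaryStatRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty summary-statistics file") from None
        if [h.strip().upper() for h in header] != SUMMARY_COLUMNS:
            raise FormatError(
                f"{path}: expected header {' '.join(SUMMARY_COLUMNS)}, got {header}"
            )
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(SUMMARY_COLUMNS):
                raise FormatError(f"{path} row {i}: expected 8 fields, got {len(row)}")
            snp, ea, oa, eaf, beta, se, p, n = (c.strip() for c in row)
            if snp in seen:
                raise FormatError(f"{path} row {i}: duplicated rsID {snp}")
            seen.add(snp)
            try:
                beta_f = float(beta)
                se_f = float(se)
                p_f = float(p)
            except ValueError:
                raise FormatError(
                    f"{path} row {i}: non-numeric BETA/SE/P for {snp}"
                ) from None
            try:
                rec = SummaryStatRecord(
                    snp_id=snp,
                    effect_allele=ea,
                    other_allele=oa,
                    beta=beta_f,
                    se=se_f,
                    pval=p_f,
                    eaf=_parse_optional(eaf, i, "EAF"),
                    n=_parse_optional(n, i, "N", cast=lambda s: int(float(s))),
                    trait=trait,
                )
            except ValueError as exc:
                raise FormatError(f"{path} row {i}: {exc}") from None
            records.append(rec)
    if not records:
        raise FormatError(f"{path}: no summary-statistic rows")
    return records


def write_summary_stats(records: Sequence[SummaryStatRecord], path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SUMMARY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.snp_id,
                    r.effect_allele,
                    r.other_allele,
                    "NA" if r.eaf is None else f"{r.eaf:.6g}",
                    f"{r.beta:.6g}",
                    f"{r.se:.6g}",
                    f"{r.pval:.6g}",
                    "NA" if r.n is None else r.n,
                ]
            )


def read_ld_matrix(path) -> LDMatrix:
    """Read a square LD r² TSV whose first row and column are rsIDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: LD matrix row and column rsIDs disagree")
    return LDMatrix(snp_ids=list(df.index), r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.6g"
    )


def write_instruments(results, path) -> None:
    """Write per-SNP harmonized coefficients and Wald ratios as TSV."""
    results.instruments_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_mr_results(results, path) -> None:
    """Write the per-method MR estimate table as TSV."""
    results.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


COHORT_COLUMNS = [
    "age", "sex", "smoker", "htn", "dm", "bmi",
    "tc", "hdl", "tg", "ldl", "lpa", "genotype", "carrier", "category",
]


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("lpa", "genotype") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cohort file missing columns {missing}")
    if (df["lpa"] < 0).any():
        raise FormatError(f"{path}: negative Lp(a) values")
    return df
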