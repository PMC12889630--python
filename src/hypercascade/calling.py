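"""Per-read base calls at target positions -> edit states, with filters.

This module consumes position-resolved call tables (one row per read:
per-site base call in {A, G, N} plus a quality score), not raw FASTQ —
alignment, merging and UMI handling happen upstream in standard tools.  The
filters implemented are the recorder pipeline's stated rules: quality-10
masking to N, exclusion of N-containing reads for layer analysis with a
group-size floor of 30, and, for the hybrid-line allele analysis, strict
5/5-SNP matching at quality >= 20 with a 30-read sample floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cascade import CascadeError

VALID_BASES = frozenset("AG")


def call_sites(base: str, quality: float, q_min: float = 10.0) -> str:
    """A/G calls at or above ``q_min`` pass through; everything else is N."""
    if quality < q_min or base not in VALID_BASES:
        return "N"
    return base


def call_table(
    reads: pd.DataFrame, q_min: float = 10.0
) -> pd.DataFrame:
    """Apply :func:`call_sites` across a read table.

    Expects paired columns ``site_i`` (bases) and ``qual_i``; returns a copy
    with the masked calls in the ``site_i`` columns.
    """
    out = reads.copy()
    site_cols = [c for c in reads.columns if c.startswith("site_")]
    for sc in site_cols:
        qc = "qual_" + sc.split("_", 1)[1]
        if qc not in reads.columns:
            raise CascadeError(f"missing quality column {qc!r}")
        bases = reads[sc].astype(str)
        quals = reads[qc].astype(float)
        out[sc] = np.where(
            (quals >= q_min) & bases.isin(list(VALID_BASES)), bases, "N"
        )
    return out


def edited_fraction(calls: Sequence[str]) -> float:
    """G / (G + A); N calls are excluded from both numerator and denominator."""
    arr = pd.Series(list(calls))
    g = int((arr == "G").sum())
    a = int((arr == "A").sum())
    if g + a == 0:
        raise CascadeError("all calls are N; edited fraction undefined")
    return g / (g + a)


def edited_fraction_table(reads: pd.DataFrame, by: str = "timepoint") -> pd.DataFrame:
    """Edited fraction pooled over all site calls, per group of ``by``."""
    site_cols = [c for c in reads.columns if c.startswith("site_")]
    rows = []
    for key, grp in reads.groupby(by):
        calls = grp[site_cols].to_numpy().ravel()
        g = int((calls == "G").sum())
        a = int((calls == "A").sum())
        rows.append(
            {by: key, "edited_fraction": g / (g + a) if g + a else np.nan,
             "n_calls": g + a, "n_reads": len(grp)}
        )
    return pd.DataFrame(rows)


def filter_for_layer_analysis(reads: pd.DataFrame, min_group: int = 30) -> pd.DataFrame:
    """Layer-analysis filter: drop reads containing any N, group the rest by
    total G count and drop groups smaller than ``min_group``."""
    site_cols = [c for c in reads.columns if c.startswith("site_")]
    calls = reads[site_cols]
    clean = reads[~(calls == "N").any(axis=1)].copy()
    clean["total_edits"] = (clean[site_cols] == "G").sum(axis=1)
    sizes = clean.groupby("total_edits")["total_edits"].transform("size")
    return clean[sizes >= min_group]


@dataclass(frozen=True)
class AlleleReferences:
    """Reference SNP base sets for the two distinguishable alleles."""

    allele_1: tuple[str, ...]
    allele_2: tuple[str, ...]
    name_1: str = "allele_1"
    name_2: str = "allele_2"

    def __post_init__(self) -> None:
        if len(self.allele_1) != len(self.allele_2):
            raise CascadeError("reference SNP sets must have equal length")
        if not any(a != b for a, b in zip(self.allele_1, self.allele_2)):
            raise CascadeError(
                "reference SNP sets are not disjoint at any position; alleles "
                "would be indistinguishable"
            )


def classify_allele(
    snp_calls: Sequence[str],
    refs: AlleleReferences,
) -> str:
    """Assign a read to an allele only on a perfect full-SNP-set match."""
    calls = tuple(snp_calls)
    if len(calls) != len(refs.allele_1):
        raise CascadeError("SNP call count does not match references")
    m1 = calls == refs.allele_1
    m2 = calls == refs.allele_2
    if m1 and not m2:
        return refs.name_1
    if m2 and not m1:
        return refs.name_2
    return "unassigned"


def classify_allele_table(
    reads: pd.DataFrame,
    refs: AlleleReferences,
    q_min: float = 20.0,
    min_reads: int = 30,
) -> pd.DataFrame:
    """Allele classification over a read table with the hybrid-line rules.

    SNP calls below ``q_min`` are masked to N first (failing the perfect
    match); per-sample groups with fewer than ``min_reads`` assigned reads
    are discarded entirely.
    """
    snp_cols = sorted(
        (c for c in reads.columns if c.startswith("snp_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not snp_cols:
        raise CascadeError("no snp_* columns present")
    out = reads.copy()
    for sc in snp_cols:
        qc = "snpq_" + sc.split("_", 1)[1]
        if qc in reads.columns:
            out[sc] = np.where(reads[qc].astype(float) >= q_min, reads[sc], "N")
    out["allele"] = [
        classify_allele(tuple(row), refs) for row in out[snp_cols].itertuples(index=False)
    ]
    if "sample" in out.columns:
        assigned = out[out["allele"] != "unassigned"]
        keep = assigned.groupby("sample")["allele"].transform("size") >= min_reads
        bad_samples = set(assigned[~keep]["sample"])
        out = out[~out["sample"].isin(bad_samples)]
    return out


def read_call_table(path) -> pd.DataFrame:
    """Read a TSV call table (columns: read_id, sample, timepoint,
    site_*, qual_*, optional snp_*/snpq_*)."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    return df


def write_call_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
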