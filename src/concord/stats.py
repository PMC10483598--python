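"""Descriptive/associative statistics over the per-patient cohort frame."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "DegenerateInputError",
    "ChiSquareResult",
    "build_cohort_frame",
    "correlate",
    "bin_counts",
    "chisq_residual_table",
    "group_compare",
]

#: Columns of the per-patient cohort frame (one record per patient_id).
COHORT_COLUMNS = [
    "patient_id",
    "age_at_diagnosis",
    "sex",
    "tumor_type",
    "gap_months",
    "tmb",
    "pct_ctdna",
    "tissue_gene_count",
    "ctdna_gene_count",
    "mutual_gene_count",
    "mutual_mutation_count",
    "status",
    "time_months",
    "event",
]


class DegenerateInputError(ValueError):
    """Zero-variance / empty-group input for which the statistic is undefined."""


def build_cohort_frame(clinical: pd.DataFrame, profiles, gene_counts) -> pd.DataFrame:
    """Join clinical data with per-patient concordance results.

    ``profiles`` maps patient_id -> ConcordanceProfile; ``gene_counts`` maps
    patient_id -> (tissue distinct gene count, ctdna distinct gene count).
    Patients present in the clinical table but missing from the alteration
    tables get zero counts (no alterations reported).
    """
    frame = clinical.copy()
    if frame["patient_id"].duplicated().any():
        dupes = frame.loc[frame["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id in clinical table: {dupes}")
    pids = frame["patient_id"]
    frame["tissue_gene_count"] = [
        gene_counts.get(p, (0, 0))[0] for p in pids
    ]
    frame["ctdna_gene_count"] = [gene_counts.get(p, (0, 0))[1] for p in pids]
    frame["mutual_gene_count"] = [
        profiles[p].mutual_gene_count if p in profiles else 0 for p in pids
    ]
    frame["mutual_mutation_count"] = [
        profiles[p].mutual_mutation_count if p in profiles else 0 for p in pids
    ]
    frame["status"] = [
        profiles[p].status.value if p in profiles else "N_N" for p in pids
    ]
    return frame


def correlate(frame: pd.DataFrame, x: str, y: str) -> tuple[float, float]:
    """Pearson correlation with two-sided p; pairwise deletion of missing.

    Every dropped record is logged with its patient_id when available.
    """
    sub = frame[[x, y]].dropna()
    dropped = frame.index.difference(sub.index)
    if len(dropped) and "patient_id" in frame.columns:
        log.info(
            "correlate(%s, %s): dropped %d incomplete records: %s",
            x, y, len(dropped),
            ", ".join(map(str, frame.loc[dropped, "patient_id"].head(20))),
        )
    if len(sub) < 3:
        raise DegenerateInputError(f"fewer than 3 complete ({x}, {y}) pairs")
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        bad = x if np.ptp(xv) == 0 else y
        raise DegenerateInputError(f"zero variance in {bad!r}")
    r, p = sps.pearsonr(xv, yv)
    return float(r), float(p)


def bin_counts(values, edges=(0, 1, 2)) -> pd.Categorical:
    """Bin non-negative integer counts into ordered categories.

    Default edges (0, 1, 2) produce the categories "0", "1", "2", ">=3":
    each edge labels its own bin and everything beyond the last edge is
    pooled.
    """
    edges = tuple(edges)
    labels = [str(e) for e in edges] + [f">={edges[-1] + 1}"]

    def lab(v):
        v = int(v)
        return labels[-1] if v > edges[-1] else str(v)

    return pd.Categorical([lab(v) for v in values], categories=labels, ordered=True)


@dataclass
class ChiSquareResult:
    statistic: float
    p_value: float
    dof: int
    observed: pd.DataFrame
    expected: pd.DataFrame
    residuals: pd.DataFrame = field(repr=False)


def chisq_residual_table(
    frame: pd.DataFrame,
    row_factor: str,
    col_factor: str,
    count_bin_edges=(0, 1, 2),
) -> ChiSquareResult:
    """Chi-square independence test with Pearson standardized residuals.

    Integer-count factors are binned via :func:`bin_counts` first.  The
    residual for each cell is (observed - expected) / sqrt(expected); the
    residuals' squares sum to the chi-square statistic.
    """
    sub = frame[[row_factor, col_factor]].dropna()

    def as_factor(col: pd.Series) -> pd.Series:
        if pd.api.types.is_numeric_dtype(col):
            return pd.Series(bin_counts(col, count_bin_edges), index=col.index)
        return col.astype(str)

    tab = pd.crosstab(as_factor(sub[row_factor]), as_factor(sub[col_factor]))
    tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
    if tab.size == 0:
        raise DegenerateInputError("empty contingency table")
    stat, p, dof, expected = sps.chi2_contingency(tab.to_numpy(), correction=False)
    expected = pd.DataFrame(expected, index=tab.index, columns=tab.columns)
    zero = expected <= 0
    if zero.to_numpy().any():
        r, c = np.argwhere(zero.to_numpy())[0]
        raise DegenerateInputError(
            f"expected count 0 in cell ({tab.index[r]}, {tab.columns[c]})"
        )
    residuals = (tab - expected) / np.sqrt(expected)
    return ChiSquareResult(
        statistic=float(stat),
        p_value=float(p),
        dof=int(dof),
        observed=tab,
        expected=expected,
        residuals=residuals,
    )


def group_compare(frame: pd.DataFrame, value: str, group: str) -> tuple[float, float]:
    """Kruskal-Wallis rank test of ``value`` across levels of ``group``."""
    sub = frame[[value, group]].dropna()
    groups = [g[value].to_numpy(dtype=float) for _, g in sub.groupby(group, observed=True)]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise DegenerateInputError("need >= 2 non-empty groups")
    stat, p = sps.kruskal(*groups)
    return float(stat), float(p)
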