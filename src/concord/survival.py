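"""Proportional-hazards survival layer.

Fits are delegated to lifelines (Efron tie handling, Wald intervals);
this module owns design-matrix construction (categorical encoding against
declared reference levels), the fixed multivariable covariate set, the
concordance-threshold refits, time-gap sensitivity filters, and the
leave-one-covariate-out diagnostic scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .stats import DegenerateInputError

__all__ = [
    "DEFAULT_COVARIATES",
    "FitError",
    "TermResult",
    "CoxResult",
    "KMResult",
    "cox_fit",
    "km_logrank",
    "threshold_analysis",
    "gap_sensitivity",
    "covariate_omission_scan",
]

#: Fixed multivariable adjustment set; the concordance term under test is
#: appended to this list by the threshold / sensitivity / omission drivers.
DEFAULT_COVARIATES = [
    "age_at_diagnosis",
    "sex",
    "tumor_type",
    "gap_months",
    "pct_ctdna",
    "tissue_gene_count",
    "ctdna_gene_count",
    "tmb",
]


class FitError(RuntimeError):
    """Model failed to converge; carries the solver's diagnostic message."""


@dataclass(frozen=True)
class TermResult:
    term: str
    coef: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxResult:
    terms: list[TermResult]
    log_likelihood: float
    n: int
    n_events: int
    covariates: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)
    p_likelihood_ratio: float | None = None

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(f"no term {name!r}; have {[t.term for t in self.terms]}")

    def terms_for(self, covariate: str) -> list[TermResult]:
        """All fitted terms that encode ``covariate`` (dummies included)."""
        hits = [
            t
            for t in self.terms
            if t.term == covariate or t.term.startswith(covariate + "=")
        ]
        if not hits:
            raise KeyError(f"no terms for covariate {covariate!r}")
        return hits


def _is_categorical(col: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(col) or isinstance(
        col.dtype, pd.CategoricalDtype
    )


def build_design(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    reference_levels: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Encode covariates numerically; dummy-code categoricals.

    Reference level defaults to the most frequent category.  Dummy columns
    are named ``covariate=level``.  Continuous covariates pass through
    untransformed.
    """
    reference_levels = dict(reference_levels or {})
    cols: dict[str, pd.Series] = {}
    refs: dict[str, str] = {}
    for cov in covariates:
        if cov not in frame.columns:
            raise KeyError(f"covariate {cov!r} not in frame")
        col = frame[cov]
        if _is_categorical(col):
            col = col.astype(str)
            levels = col.value_counts()
            ref = reference_levels.get(cov, str(levels.index[0]))
            if ref not in levels.index:
                raise ValueError(f"reference level {ref!r} absent from {cov!r}")
            refs[cov] = ref
            for level in sorted(levels.index):
                if level == ref:
                    continue
                cols[f"{cov}={level}"] = (col == level).astype(float)
        else:
            cols[cov] = col.astype(float)
    design = pd.DataFrame(cols, index=frame.index)
    for name, col in design.items():
        if col.nunique(dropna=True) <= 1:
            raise DegenerateInputError(f"covariate column {name!r} has zero variance")
    return design, refs


def cox_fit(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "time_months",
    event_col: str = "event",
    reference_levels: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> CoxResult:
    """Partial-likelihood proportional-hazards fit (Efron ties, Wald CIs).

    Rows with missing values in any used column are dropped listwise.
    """
    use = list(covariates) + [time_col, event_col]
    data = frame[use].dropna()
    if int(data[event_col].sum()) < 1:
        raise DegenerateInputError("no events in data")
    design, refs = build_design(data, covariates, reference_levels)
    design[time_col] = data[time_col].astype(float)
    design[event_col] = data[event_col].astype(int)

    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(design, duration_col=time_col, event_col=event_col)
    except ConvergenceError as exc:  # pragma: no cover - exercised via tests
        raise FitError(f"Cox model failed to converge: {exc}") from exc

    summary = cph.summary
    terms = [
        TermResult(
            term=str(idx),
            coef=float(row["coef"]),
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(math.exp(row["coef lower 95%"])),
            ci_high=float(math.exp(row["coef upper 95%"])),
            p=float(row["p"]),
        )
        for idx, row in summary.iterrows()
    ]
    lr = cph.log_likelihood_ratio_test()
    return CoxResult(
        terms=terms,
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(design)),
        n_events=int(design[event_col].sum()),
        covariates=list(covariates),
        reference_levels=refs,
        p_likelihood_ratio=float(lr.p_value),
    )


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> columns (timeline, survival)
    n_per_group: dict[str, int]
    p_likelihood_ratio: float | None  # headline comparison p
    p_score: float | None
    p_wald: float | None  # only for a single-coefficient comparison
    all_censored: bool = False


def km_logrank(
    frame: pd.DataFrame,
    group_field: str,
    time_col: str = "time_months",
    event_col: str = "event",
) -> KMResult:
    """Kaplan-Meier curves per group plus a single-covariate PH comparison.

    The comparison treats a numeric grouping column as a continuous trend
    covariate and a categorical one as dummy-coded levels; likelihood-ratio,
    score (logrank) and Wald p-values are all reported, the likelihood-ratio
    p being the headline.  With zero events the curves are still returned
    and every p is None.
    """
    data = frame[[group_field, time_col, event_col]].dropna()
    curves: dict[str, pd.DataFrame] = {}
    n_per_group: dict[str, int] = {}
    for key, grp in data.groupby(group_field, observed=True):
        kmf = KaplanMeierFitter()
        kmf.fit(grp[time_col], event_observed=grp[event_col].astype(int))
        sf = kmf.survival_function_
        curves[str(key)] = pd.DataFrame(
            {"timeline": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
        n_per_group[str(key)] = int(len(grp))

    if int(data[event_col].sum()) == 0:
        return KMResult(curves, n_per_group, None, None, None, all_censored=True)

    fit = cox_fit(data, [group_field], time_col=time_col, event_col=event_col)
    p_wald = fit.terms[0].p if len(fit.terms) == 1 else None
    score = multivariate_logrank_test(
        data[time_col], data[group_field], data[event_col].astype(int)
    )
    return KMResult(
        curves=curves,
        n_per_group=n_per_group,
        p_likelihood_ratio=fit.p_likelihood_ratio,
        p_score=float(score.p_value),
        p_wald=p_wald,
    )


def threshold_analysis(
    frame: pd.DataFrame,
    count_field: str,
    k: int,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    time_col: str = "time_months",
    event_col: str = "event",
    reference_levels: Mapping[str, str] | None = None,
) -> CoxResult:
    """Refit the multivariable model with the indicator [count >= k]."""
    if k < 1:
        raise ValueError("k must be >= 1")
    indicator = f"{count_field}_ge{k}"
    data = frame.copy()
    data[indicator] = (data[count_field] >= k).astype(float)
    if data[indicator].nunique() <= 1:
        raise DegenerateInputError(
            f"indicator [{count_field} >= {k}] is constant in the data"
        )
    covs = [c for c in covariates if c != count_field] + [indicator]
    return cox_fit(
        data, covs, time_col=time_col, event_col=event_col,
        reference_levels=reference_levels,
    )


@dataclass(frozen=True)
class GapSensitivityRow:
    max_gap_months: float
    n: int
    n_events: int
    hazard_ratio: float
    p: float
    low_events: bool  # fewer than 5 events per fitted coefficient


def gap_sensitivity(
    frame: pd.DataFrame,
    max_gap_months: Sequence[float],
    target: str = "mutual_gene_count",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    gap_col: str = "gap_months",
    time_col: str = "time_months",
    event_col: str = "event",
    reference_levels: Mapping[str, str] | None = None,
) -> list[GapSensitivityRow]:
    """Refit the full model on |gap| <= threshold subsets; report target p."""
    if any(t <= 0 for t in max_gap_months):
        raise ValueError("gap thresholds must be positive")
    covs = [c for c in covariates if c != target] + [target]
    rows = []
    for thr in max_gap_months:
        sub = frame[frame[gap_col].abs() <= thr]
        fit = cox_fit(
            sub, covs, time_col=time_col, event_col=event_col,
            reference_levels=reference_levels,
        )
        term = fit.term(target)
        rows.append(
            GapSensitivityRow(
                max_gap_months=float(thr),
                n=fit.n,
                n_events=fit.n_events,
                hazard_ratio=term.hazard_ratio,
                p=term.p,
                low_events=fit.n_events < 5 * len(fit.terms),
            )
        )
    return rows


@dataclass(frozen=True)
class OmissionRow:
    omitted: str
    target_terms: tuple[TermResult, ...]
    error: str | None = None

    @property
    def min_p(self) -> float | None:
        return min((t.p for t in self.target_terms), default=None)


def covariate_omission_scan(
    frame: pd.DataFrame,
    target: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    time_col: str = "time_months",
    event_col: str = "event",
    reference_levels: Mapping[str, str] | None = None,
) -> tuple[CoxResult, list[OmissionRow]]:
    """Refit the full model leaving out one adjustment covariate at a time.

    Returns the full-model fit plus one row per omitted covariate with the
    target's terms under that omission (errors annotated, not raised).
    """
    covs = [c for c in covariates if c != target] + [target]
    full = cox_fit(
        frame, covs, time_col=time_col, event_col=event_col,
        reference_levels=reference_levels,
    )
    rows = []
    for omit in covs[:-1]:
        reduced = [c for c in covs if c != omit]
        try:
            fit = cox_fit(
                frame, reduced, time_col=time_col, event_col=event_col,
                reference_levels=reference_levels,
            )
            rows.append(OmissionRow(omitted=omit, target_terms=tuple(fit.terms_for(target))))
        except (FitError, DegenerateInputError) as exc:
            rows.append(OmissionRow(omitted=omit, target_terms=(), error=str(exc)))
    return full, rows
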