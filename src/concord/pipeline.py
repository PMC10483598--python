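"""End-to-end composition: harmonize -> concordance -> stats -> survival."""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import platform
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .concordance import (
    ConcordanceProfile,
    cohort_gene_table,
    conditional_mutation_frequency,
    profile_patient,
)
from .io import (
    AlterationRecord,
    RunConfig,
    SchemaAdapter,
    format_float,
    format_p,
    read_alteration_table,
    read_clinical_table,
    read_survival_table,
    write_alteration_table,
)
from .panels import (
    Alteration,
    AlterationKind,
    Assay,
    PanelDefinition,
    filter_characterized,
    load_panel_definitions,
    resolve_comparable_set,
    restrict_alterations,
)
from .stats import (
    DegenerateInputError,
    build_cohort_frame,
    chisq_residual_table,
    correlate,
    group_compare,
)
from .survival import (
    CoxResult,
    cox_fit,
    covariate_omission_scan,
    gap_sensitivity,
    km_logrank,
    threshold_analysis,
)

__all__ = ["PipelineError", "harmonize_cohort", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def harmonize_cohort(
    records: Sequence[AlterationRecord],
    panels: Sequence[PanelDefinition],
    era_dates: Mapping[str, dt.date] | None = None,
) -> tuple[dict[str, tuple[list[Alteration], list[Alteration]]], list[str]]:
    """Group records by patient, resolve each patient's comparable set, and
    restrict to characterized alterations in it.

    The panel era is resolved from the patient's ctDNA blood-draw date:
    ``era_dates`` if given, else the latest ctDNA ``sample_date`` seen for
    the patient.  The tissue gene universe is the union of all panel eras'
    genes (both published comparable lists are tissue-covered).  Returns the
    per-patient (tissue, ctdna) lists plus a drop log.
    """
    tissue_universe = frozenset().union(*(p.genes for p in panels))
    by_patient: dict[str, dict[Assay, list[Alteration]]] = {}
    ctdna_dates: dict[str, dt.date] = {}
    for rec in records:
        a = rec.alteration
        by_patient.setdefault(a.patient_id, {Assay.TISSUE: [], Assay.CTDNA: []})[
            a.assay
        ].append(a)
        if rec.sample_date is not None:
            # prefer the blood-draw date; fall back to the tissue date for
            # patients with no ctDNA records at all
            key = 1 if a.assay is Assay.CTDNA else 0
            prev = ctdna_dates.get(a.patient_id)
            if prev is None or (key, rec.sample_date) > prev:
                ctdna_dates[a.patient_id] = (key, rec.sample_date)

    out: dict[str, tuple[list[Alteration], list[Alteration]]] = {}
    dropped: list[str] = []
    for pid in sorted(by_patient):
        fallback = ctdna_dates.get(pid)
        date = (era_dates or {}).get(pid) or (fallback[1] if fallback else None)
        if date is None:
            raise PipelineError(
                "harmonize", f"patient {pid}: no ctDNA sample date to resolve panel era"
            )
        cgs = resolve_comparable_set(date, panels, tissue_universe)
        t_in = by_patient[pid][Assay.TISSUE]
        c_in = by_patient[pid][Assay.CTDNA]
        t_out = restrict_alterations(filter_characterized(t_in), cgs)
        c_out = restrict_alterations(filter_characterized(c_in), cgs)
        for a in t_in + c_in:
            if not a.characterized:
                dropped.append(f"{pid}\t{a.assay.value}\t{a.gene}\tVUS/synonymous")
            elif a.gene not in cgs.genes:
                dropped.append(f"{pid}\t{a.assay.value}\t{a.gene}\toutside comparable set")
            elif a.kind is AlterationKind.AMPLIFICATION and a.gene not in cgs.amp_genes:
                dropped.append(f"{pid}\t{a.assay.value}\t{a.gene}\tamplification not eligible")
        out[pid] = (t_out, c_out)
    return out, dropped


def _cox_result_dict(res: CoxResult) -> dict:
    return {
        "n": res.n,
        "n_events": res.n_events,
        "log_likelihood": res.log_likelihood,
        "p_likelihood_ratio": res.p_likelihood_ratio,
        "reference_levels": res.reference_levels,
        "terms": [dataclasses.asdict(t) for t in res.terms],
    }


def _forest_rows(model: str, res: CoxResult) -> list[dict]:
    return [
        {
            "model": model,
            "term": t.term,
            "hazard_ratio": format_float(t.hazard_ratio),
            "ci_low": format_float(t.ci_low),
            "ci_high": format_float(t.ci_high),
            "p": format_p(t.p),
            "n": res.n,
            "n_events": res.n_events,
        }
        for t in res.terms
    ]


def summarize_cohort(
    harmonized: Mapping[str, tuple[list[Alteration], list[Alteration]]],
    profiles: Mapping[str, ConcordanceProfile],
) -> dict:
    """Headline genomic-landscape and concordance counts for the cohort."""
    def tally(index: int) -> dict:
        alts = [a for pair in harmonized.values() for a in pair[index]]
        return {
            "total": len(alts),
            "point_mutations": sum(
                a.kind in (AlterationKind.POINT_MUTATION, AlterationKind.INDEL)
                for a in alts
            ),
            "amplifications": sum(
                a.kind is AlterationKind.AMPLIFICATION for a in alts
            ),
        }

    n = len(harmonized)
    mutual = [p.mutual_gene_count for p in profiles.values()]
    mutation = [p.mutual_mutation_count for p in profiles.values()]
    statuses = [p.status.value for p in profiles.values()]
    return {
        "n_patients": n,
        "tissue": tally(0),
        "ctdna": tally(1),
        "mean_tissue_alterations": (tally(0)["total"] / n) if n else 0.0,
        "mean_ctdna_alterations": (tally(1)["total"] / n) if n else 0.0,
        "n_with_mutual_gene": sum(m >= 1 for m in mutual),
        "fraction_with_mutual_gene": (sum(m >= 1 for m in mutual) / n) if n else 0.0,
        "mean_mutual_gene_count": (sum(mutual) / n) if n else 0.0,
        "max_mutual_gene_count": max(mutual, default=0),
        "mean_mutual_mutation_count": (sum(mutation) / n) if n else 0.0,
        "status_counts": {s: statuses.count(s) for s in ("N_N", "Y_N", "Y_Y")},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain and write all artifacts to out_dir."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    adapter = (
        SchemaAdapter.from_json(config.adapter_path) if config.adapter_path else None
    )
    try:
        records = read_alteration_table(
            config.alterations_path, adapter=adapter, synonym_map=config.synonym_map
        )
        clinical = read_clinical_table(config.clinical_path)
        survival = read_survival_table(config.survival_path)
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc

    panels = load_panel_definitions(config.panels_path)
    era_dates = {}
    if "blood_date" in clinical.columns:
        for rec in clinical.itertuples(index=False):
            raw = str(rec.blood_date)
            if raw and raw.lower() not in ("nan", "none", ""):
                era_dates[str(rec.patient_id)] = dt.date.fromisoformat(raw[:10])
    harmonized, dropped = harmonize_cohort(records, panels, era_dates)

    # patients in the clinical table with no alteration rows at all still count
    for pid in clinical["patient_id"].astype(str):
        harmonized.setdefault(pid, ([], []))

    try:
        profiles = {
            pid: profile_patient(t, c) for pid, (t, c) in harmonized.items()
        }
        gene_table = cohort_gene_table(harmonized)
        freqs, freq_median = conditional_mutation_frequency(
            gene_table, min_mutual=config.min_mutual
        )
    except Exception as exc:
        raise PipelineError("concordance", str(exc)) from exc

    gene_counts = {
        pid: (len({a.gene for a in t}), len({a.gene for a in c}))
        for pid, (t, c) in harmonized.items()
    }
    clinical = clinical.copy()
    clinical["patient_id"] = clinical["patient_id"].astype(str)
    survival = survival.copy()
    survival["patient_id"] = survival["patient_id"].astype(str)
    frame = build_cohort_frame(clinical, profiles, gene_counts)
    frame = frame.merge(
        survival[["patient_id", "time_months", "event"]], on="patient_id", how="left"
    )

    stats_out: dict = {"correlations": {}, "chi_square": {}, "group_compare": {}}
    for name, (x, y) in {
        "mutual_gene_vs_tissue_genes": ("mutual_gene_count", "tissue_gene_count"),
        "mutual_gene_vs_tmb": ("mutual_gene_count", "tmb"),
        "mutual_gene_vs_gap": ("mutual_gene_count", "gap_months"),
        "mutual_gene_vs_pct_ctdna": ("mutual_gene_count", "pct_ctdna"),
        "mutual_mutation_vs_tissue_genes": ("mutual_mutation_count", "tissue_gene_count"),
    }.items():
        try:
            r, p = correlate(frame, x, y)
            stats_out["correlations"][name] = {"r": r, "p": p}
        except DegenerateInputError as exc:
            stats_out["correlations"][name] = {"error": str(exc)}
    for name, col in {
        "tumor_type_vs_mutual_gene": "mutual_gene_count",
        "tumor_type_vs_mutual_mutation": "mutual_mutation_count",
    }.items():
        try:
            chi = chisq_residual_table(
                frame, "tumor_type", col, count_bin_edges=config.chi_bin_edges
            )
            stats_out["chi_square"][name] = {
                "statistic": chi.statistic, "p": chi.p_value, "dof": chi.dof,
            }
            chi.residuals.to_csv(out_dir / f"residuals_{name}.tsv", sep="\t")
        except DegenerateInputError as exc:
            stats_out["chi_square"][name] = {"error": str(exc)}
    try:
        stat, p = group_compare(frame, "ctdna_gene_count", "status")
        stats_out["group_compare"]["ctdna_genes_by_status"] = {"statistic": stat, "p": p}
    except DegenerateInputError as exc:
        stats_out["group_compare"]["ctdna_genes_by_status"] = {"error": str(exc)}

    # survival layer
    surv_frame = frame.dropna(subset=["time_months", "event"])
    refs = dict(config.reference_levels)
    refs.setdefault("status", "N_N")
    covs = list(config.covariates)
    survival_out: dict = {}
    forest: list[dict] = []
    try:
        km = km_logrank(surv_frame, "mutual_gene_count")
        survival_out["univariate_mutual_gene"] = {
            "p_likelihood_ratio": km.p_likelihood_ratio,
            "p_score": km.p_score,
            "p_wald": km.p_wald,
            "n_per_group": km.n_per_group,
        }
        full = cox_fit(
            surv_frame, covs + ["mutual_gene_count"], reference_levels=refs
        )
        survival_out["multivariable_mutual_gene"] = _cox_result_dict(full)
        forest += _forest_rows("multivariable_mutual_gene", full)
        full_mut = cox_fit(
            surv_frame, covs + ["mutual_mutation_count"], reference_levels=refs
        )
        survival_out["multivariable_mutual_mutation"] = _cox_result_dict(full_mut)
        forest += _forest_rows("multivariable_mutual_mutation", full_mut)
        survival_out["thresholds"] = {}
        for k in config.thresholds:
            try:
                res = threshold_analysis(
                    surv_frame, "mutual_gene_count", k,
                    covariates=covs, reference_levels=refs,
                )
                survival_out["thresholds"][str(k)] = _cox_result_dict(res)
                forest += _forest_rows(f"threshold_ge{k}", res)
            except DegenerateInputError as exc:
                survival_out["thresholds"][str(k)] = {"error": str(exc)}
        rows = gap_sensitivity(
            surv_frame, config.gap_filters, target="mutual_gene_count",
            covariates=covs, reference_levels=refs,
        )
        survival_out["gap_sensitivity"] = [dataclasses.asdict(r) for r in rows]
        status_full, omissions = covariate_omission_scan(
            surv_frame, "status", covariates=covs + ["status"],
            reference_levels=refs,
        )
        survival_out["status_multivariable"] = _cox_result_dict(status_full)
        survival_out["status_omission_scan"] = [
            {
                "omitted": row.omitted,
                "error": row.error,
                "terms": [dataclasses.asdict(t) for t in row.target_terms],
            }
            for row in omissions
        ]
    except DegenerateInputError as exc:
        survival_out["error"] = str(exc)
    except Exception as exc:
        raise PipelineError("survival", str(exc)) from exc

    summary = summarize_cohort(harmonized, profiles)
    summary["conditional_mutation_frequency"] = {
        "per_gene": freqs,
        "median": freq_median,
        "n_genes": len(freqs),
    }

    # ---- write artifacts ----
    harmonized_records = [
        AlterationRecord(a, era_dates.get(pid), -1)
        for pid, (t, c) in sorted(harmonized.items())
        for a in (*t, *c)
    ]
    write_alteration_table(harmonized_records, out_dir / "harmonized_alterations.tsv")
    pd.DataFrame(
        [
            {
                "gene": r.gene, "tissue_n": r.tissue_n, "ctdna_n": r.ctdna_n,
                "mutual_gene_n": r.mutual_gene_n, "mutual_mutation_n": r.mutual_mutation_n,
            }
            for r in gene_table
        ]
    ).to_csv(out_dir / "gene_table.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": pid,
                "mutual_gene_count": p.mutual_gene_count,
                "mutual_mutation_count": p.mutual_mutation_count,
                "status": p.status.value,
            }
            for pid, p in sorted(profiles.items())
        ]
    ).to_csv(out_dir / "profiles.tsv", sep="\t", index=False)
    frame.to_csv(out_dir / "cohort_frame.tsv", sep="\t", index=False)
    with open(out_dir / "statistics.json", "w", encoding="utf-8") as fh:
        json.dump(stats_out, fh, indent=1, sort_keys=True)
    with open(out_dir / "survival.json", "w", encoding="utf-8") as fh:
        json.dump(survival_out, fh, indent=1, sort_keys=True)
    pd.DataFrame(forest).to_csv(out_dir / "forest.tsv", sep="\t", index=False)
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(out_dir / "dropped_records.tsv", "w", encoding="utf-8") as fh:
        fh.write("patient_id\tassay\tgene\treason\n")
        fh.write("\n".join(dropped) + ("\n" if dropped else ""))

    config_json = json.dumps(dataclasses.asdict(config), sort_keys=True)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_dropped_records": len(dropped),
        "artifacts": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "harmonized": harmonized,
        "profiles": profiles,
        "gene_table": gene_table,
        "frame": frame,
        "summary": summary,
        "statistics": stats_out,
        "survival": survival_out,
        "manifest": manifest,
    }
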