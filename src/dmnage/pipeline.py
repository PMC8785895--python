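"""Cohort QC, per-subject metric computation, and the full analysis pipeline.

The pipeline runs: QC filtering -> static FC strength and dFC variability per
subject -> diagnosis-by-age interaction regressions for both outcomes ->
within-group age correlations with the between-group Fisher z comparison ->
clinical partial correlations and the episodicity ANCOVA -> heteroscedasticity
diagnostics (with a log refit when significant) -> a window-width x step-length
validation grid for the dynamic outcome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .dynamic_connectivity import dfc_stack, network_variability, window_plan
from .io_core import SubjectRecord, TimeSeriesMatrix, write_metrics
from .static_connectivity import fc_matrix, within_network_strength
from .stats_models import (
    CorrelationComparison,
    HeteroscedasticityCheck,
    RegressionResult,
    ancova_binary,
    compare_independent_correlations,
    fit_interaction_model,
    group_age_correlation,
    heteroscedasticity_check,
    log_transform_refit,
    partial_correlation,
)
from .synthetic_cohort import SimulationConfig, simulate_cohort

logger = logging.getLogger("dmnage")

__all__ = [
    "QcReport",
    "AnalysisConfig",
    "AnalysisReport",
    "qc_filter",
    "compute_all_metrics",
    "run_analysis",
]

#: QC criteria in exclusion-attribution order (a subject counts once, under
#: the first criterion it fails). Manual image-quality review has no
#: computable definition and is logged as not applied.
QC_CRITERIA = (
    "age_under_18",
    "incomplete_demographics",
    "tr_not_2s",
    "mean_fd_over_0.2mm",
    "zero_variance_roi",
    "timeseries_missing",
)


@dataclass
class QcReport:
    n_input: int
    n_retained: int
    excluded: dict[str, int]  # per-criterion counts
    reasons: dict[str, str]  # subject_id -> first failing criterion
    notes: tuple[str, ...] = (
        "manual image-quality review not applied (no computable definition)",
        "mask-coverage criterion approximated by zero-variance ROI detection",
    )

    def __post_init__(self) -> None:
        assert self.n_retained + sum(self.excluded.values()) == self.n_input


def _first_failure(
    rec: SubjectRecord, ts: Optional[TimeSeriesMatrix], check_series: bool
) -> Optional[str]:
    if not np.isnan(rec.age) and rec.age < 18:
        return "age_under_18"
    if not rec.complete_demographics:
        return "incomplete_demographics"
    if check_series:
        if ts is None:
            return "timeseries_missing"
        if abs(ts.tr_s - 2.0) > 1e-9:
            return "tr_not_2s"
    if rec.mean_fd > 0.2:
        return "mean_fd_over_0.2mm"
    if check_series and ts is not None and np.any(ts.data.std(axis=0) == 0):
        return "zero_variance_roi"
    return None


def qc_filter(
    phenotypes: list[SubjectRecord],
    timeseries: Optional[dict[str, TimeSeriesMatrix]] = None,
) -> tuple[list[SubjectRecord], QcReport]:
    """Apply the automatable exclusion criteria, in a fixed order.

    Criteria: age < 18; incomplete demographics; scan TR != 2 s; mean
    framewise displacement > 0.2 mm; any zero-variance ROI series (a proxy
    for signal loss / bad mask coverage). When ``timeseries`` is None the
    scan-dependent criteria are skipped (phenotype-only QC).
    """
    check_series = timeseries is not None
    counts = {c: 0 for c in QC_CRITERIA}
    reasons: dict[str, str] = {}
    retained = []
    for rec in phenotypes:
        ts = timeseries.get(rec.subject_id) if check_series else None
        why = _first_failure(rec, ts, check_series)
        if why is None:
            retained.append(rec)
        else:
            counts[why] += 1
            reasons[rec.subject_id] = why
    report = QcReport(
        n_input=len(phenotypes),
        n_retained=len(retained),
        excluded={c: n for c, n in counts.items() if n},
        reasons=reasons,
    )
    if not retained:
        logger.warning("QC retained no subjects (n_input=%d)", len(phenotypes))
    return retained, report


def _record_row(rec: SubjectRecord) -> dict:
    return {
        "subject_id": rec.subject_id,
        "diagnosis": rec.diagnosis,
        "age": rec.age,
        "sex": rec.sex,
        "education": rec.education,
        "site": rec.site,
        "mean_fd": rec.mean_fd,
        "illness_duration": np.nan if rec.illness_duration is None else rec.illness_duration,
        "hamd": np.nan if rec.hamd is None else rec.hamd,
        "hama": np.nan if rec.hama is None else rec.hama,
        "episodicity": rec.episodicity,
    }


def compute_all_metrics(
    cohort: list[SubjectRecord],
    timeseries: dict[str, TimeSeriesMatrix],
    width_s: float = 100.0,
    step_s: float = 6.0,
    transform: bool = False,
) -> pd.DataFrame:
    """Per-subject FC strength and dFC variability at one window setting.

    Subjects whose metrics cannot be computed (e.g. a zero-variance window)
    are dropped with a log entry; the dropped ids and errors are kept in
    ``table.attrs['dropped']``.
    """
    rows = []
    dropped: dict[str, str] = {}
    for rec in cohort:
        ts = timeseries[rec.subject_id]
        try:
            fc = fc_matrix(ts, transform=transform)
            strength = within_network_strength(fc)
            spec = window_plan(ts.n_volumes, ts.tr_s, width_s, step_s)
            v = network_variability(dfc_stack(ts, spec, transform=transform))
        except ValueError as exc:
            dropped[rec.subject_id] = str(exc)
            logger.warning("dropping subject %s: %s", rec.subject_id, exc)
            continue
        row = _record_row(rec)
        row.update(
            fc_strength=strength,
            dfc_variability=v,
            window_width_s=width_s,
            step_s=step_s,
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["dropped"] = dropped
    return table


@dataclass
class AnalysisConfig:
    """Configuration for a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    width_s: float = 100.0
    step_s: float = 6.0
    fisher_z: bool = False
    grid_widths_s: tuple[float, ...] = (80.0, 100.0, 120.0)
    grid_steps_s: tuple[float, ...] = (6.0, 8.0, 10.0)
    run_grid: bool = True
    outdir: Optional[Path] = None


@dataclass
class AnalysisReport:
    qc: QcReport
    metrics: pd.DataFrame
    regressions: dict[str, RegressionResult]
    group_correlations: dict[str, dict[str, float]]
    comparisons: dict[str, CorrelationComparison]
    clinical_partials: pd.DataFrame
    episodicity_ancova: dict[str, tuple[float, float]]
    heteroscedasticity: dict[str, HeteroscedasticityCheck]
    log_refits: dict[str, Optional[RegressionResult]]
    grid: dict[tuple[float, float], RegressionResult]

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(self.regressions)


OUTCOMES = ("fc_strength", "dfc_variability")
CLINICAL_VARS = ("illness_duration", "hamd", "hama")
PARTIAL_COVARIATES = ("age", "sex", "education", "site", "mean_fd")


def _covariate_matrix(sub: pd.DataFrame) -> np.ndarray:
    """Numeric covariate columns for partial correlations: age, sex (female=1),
    education, site dummies (first level reference), mean FD."""
    cols = [sub["age"].to_numpy(float)]
    cols.append((sub["sex"] == "female").to_numpy(float))
    cols.append(sub["education"].to_numpy(float))
    sites = sorted(sub["site"].astype(str).unique())
    for s in sites[1:]:
        cols.append((sub["site"].astype(str) == s).to_numpy(float))
    cols.append(sub["mean_fd"].to_numpy(float))
    return np.column_stack(cols)


def _clinical_partials(metrics: pd.DataFrame) -> pd.DataFrame:
    rows = []
    patients = metrics[metrics["diagnosis"] == "MDD"]
    for outcome in OUTCOMES:
        for var in CLINICAL_VARS:
            sub = patients.dropna(subset=[var])
            cov = _covariate_matrix(sub) if len(sub) else None
            # partial correlation needs n > k + 3 residual degrees of freedom
            if cov is None or len(sub) <= cov.shape[1] + 4:
                rows.append({"outcome": outcome, "clinical": var, "n": len(sub),
                             "r": np.nan, "p": np.nan})
                continue
            r, p = partial_correlation(
                sub[outcome].to_numpy(float),
                sub[var].to_numpy(float),
                cov,
            )
            rows.append({"outcome": outcome, "clinical": var, "n": len(sub), "r": r, "p": p})
    return pd.DataFrame(rows)


def run_analysis(
    config: AnalysisConfig,
    cohort: Optional[list[SubjectRecord]] = None,
    timeseries: Optional[dict[str, TimeSeriesMatrix]] = None,
) -> AnalysisReport:
    """Run the full analysis; simulates the cohort when none is supplied."""
    if cohort is None or timeseries is None:
        logger.info("simulating cohort (seed=%d)", config.simulation.seed)
        cohort, timeseries = simulate_cohort(config.simulation)

    retained, qc = qc_filter(cohort, timeseries)
    if not retained:
        raise RuntimeError("qc stage: no subjects retained")

    metrics = compute_all_metrics(
        retained, timeseries, config.width_s, config.step_s, config.fisher_z
    )
    if metrics.empty:
        raise RuntimeError("metrics stage: no subject metrics computed")

    regressions, hetero, refits = {}, {}, {}
    for outcome in OUTCOMES:
        try:
            res = fit_interaction_model(metrics, outcome)
        except ValueError as exc:
            raise RuntimeError(f"regression stage ({outcome}): {exc}") from exc
        regressions[outcome] = res
        check = heteroscedasticity_check(res, metrics["age"].to_numpy(float))
        hetero[outcome] = check
        if check.p < 0.05:
            try:
                refits[outcome] = log_transform_refit(metrics, outcome)
            except ValueError as exc:
                logger.warning("log refit skipped for %s: %s", outcome, exc)
                refits[outcome] = None
        else:
            refits[outcome] = None

    correlations, comparisons = {}, {}
    for outcome in OUTCOMES:
        try:
            r_mdd = group_age_correlation(metrics, outcome, "MDD")
            r_hc = group_age_correlation(metrics, outcome, "HC")
        except ValueError as exc:
            raise RuntimeError(f"correlation stage ({outcome}): {exc}") from exc
        n_mdd = int((metrics["diagnosis"] == "MDD").sum())
        n_hc = int((metrics["diagnosis"] == "HC").sum())
        correlations[outcome] = {"MDD": r_mdd, "HC": r_hc}
        comparisons[outcome] = compare_independent_correlations(r_mdd, n_mdd, r_hc, n_hc)

    clinical = _clinical_partials(metrics)

    ancova = {}
    epi = metrics.dropna(subset=["episodicity"])
    if epi["episodicity"].nunique() == 2 and len(epi) >= 20:
        for outcome in OUTCOMES:
            ancova[outcome] = ancova_binary(
                epi, outcome, "episodicity", list(PARTIAL_COVARIATES)
            )

    grid: dict[tuple[float, float], RegressionResult] = {}
    if config.run_grid:
        for w in config.grid_widths_s:
            for s in config.grid_steps_s:
                if (w, s) == (config.width_s, config.step_s):
                    grid[(w, s)] = regressions["dfc_variability"]
                    continue
                cell = compute_all_metrics(retained, timeseries, w, s, config.fisher_z)
                try:
                    grid[(w, s)] = fit_interaction_model(cell, "dfc_variability")
                except ValueError as exc:
                    raise RuntimeError(f"grid stage ({w}s/{s}s): {exc}") from exc

    report = AnalysisReport(
        qc=qc,
        metrics=metrics,
        regressions=regressions,
        group_correlations=correlations,
        comparisons=comparisons,
        clinical_partials=clinical,
        episodicity_ancova=ancova,
        heteroscedasticity=hetero,
        log_refits=refits,
        grid=grid,
    )
    if config.outdir is not None:
        write_report(Path(config.outdir), report, config)
    return report


def interaction_sign_recovery(
    n_replicates: int = 20,
    base_config: Optional[SimulationConfig] = None,
    seed: int = 0,
) -> float:
    """Fraction of simulated cohorts whose fitted diagnosis-by-age interaction
    coefficient for FC strength has the sign the generator slopes imply.

    Each replicate simulates a full cohort (time series included), computes
    per-subject static FC strength and fits the interaction model. With
    diagnosis coded MDD = 0 / HC = 1, a patient slope more negative than the
    control slope implies a positive interaction coefficient.
    """
    import dataclasses

    base = base_config or SimulationConfig()
    expected = np.sign(base.slope_hc - base.slope_mdd)
    if expected == 0:
        raise ValueError("generator slopes are equal: no implied sign")
    hits = 0
    for rep in range(n_replicates):
        cfg = dataclasses.replace(base, seed=seed + 1000 * (rep + 1))
        cohort, series = simulate_cohort(cfg)
        retained, _ = qc_filter(cohort, series)
        rows = []
        for rec in retained:
            strength = within_network_strength(fc_matrix(series[rec.subject_id]))
            row = _record_row(rec)
            row["fc_strength"] = strength
            rows.append(row)
        table = pd.DataFrame(rows)
        res = fit_interaction_model(table, "fc_strength")
        if np.sign(res.coef("diagnosis_x_age")) == expected:
            hits += 1
    return hits / n_replicates


def interaction_type1_error(
    n_replicates: int = 500,
    n_per_group: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the interaction test under a null generator.

    Replicates draw phenotypes and noise-free correlation targets with equal
    age slopes in both groups (the target itself, which carries the
    between-subject noise, serves as the outcome), fit the interaction model
    and count rejections at the given two-tailed level.
    """
    import dataclasses

    from .synthetic_cohort import simulate_phenotypes

    base = SimulationConfig(n_per_group=n_per_group, slope_mdd=-0.0010, slope_hc=-0.0010)
    rejections = 0
    for rep in range(n_replicates):
        cfg = dataclasses.replace(base, seed=seed + 1000 * (rep + 1))
        pheno = simulate_phenotypes(cfg)
        pheno = pheno.rename(columns={"rho_target": "fc_strength"})
        res = fit_interaction_model(pheno, "fc_strength")
        if res.pvalue("diagnosis_x_age") < alpha:
            rejections += 1
    return rejections / n_replicates


def _fmt_frame(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_report(outdir: Path, report: AnalysisReport, config: AnalysisConfig) -> None:
    """Write all result tables and a plain-text run log with fixed formatting."""
    outdir.mkdir(parents=True, exist_ok=True)
    write_metrics(outdir / "metrics.tsv", report.metrics)
    for outcome, res in report.regressions.items():
        _fmt_frame(res.to_frame(), outdir / f"regression_{outcome}.tsv")
    for outcome, res in report.log_refits.items():
        if res is not None:
            _fmt_frame(res.to_frame(), outdir / f"regression_{outcome}_log.tsv")
    corr_rows = []
    for outcome, d in report.group_correlations.items():
        cmp_ = report.comparisons[outcome]
        corr_rows.append(
            {"outcome": outcome, "r_mdd": d["MDD"], "r_hc": d["HC"],
             "z": cmp_.z, "p": cmp_.p}
        )
    _fmt_frame(pd.DataFrame(corr_rows), outdir / "age_correlations.tsv")
    _fmt_frame(report.clinical_partials, outdir / "clinical_partials.tsv")
    grid_rows = []
    for (w, s), res in report.grid.items():
        grid_rows.append(
            {"width_s": w, "step_s": s,
             "age_b": res.coef("age"), "age_t": res.tstat("age"), "age_p": res.pvalue("age"),
             "interaction_t": res.tstat("diagnosis_x_age"),
             "interaction_p": res.pvalue("diagnosis_x_age")}
        )
    if grid_rows:
        _fmt_frame(pd.DataFrame(grid_rows), outdir / "validation_grid.tsv")
    lines = [
        f"dmnage {__version__}",
        f"seed: {config.simulation.seed}",
        f"window: width {config.width_s} s, step {config.step_s} s, fisher_z={config.fisher_z}",
        f"qc: n_input={report.qc.n_input} n_retained={report.qc.n_retained} "
        f"excluded={json.dumps(report.qc.excluded)}",
        *[f"qc note: {n}" for n in report.qc.notes],
        f"heteroscedasticity: "
        + ", ".join(
            f"{o}: rho={c.rho:.4f} p={c.p:.4g}" for o, c in report.heteroscedasticity.items()
        ),
        f"episodicity ANCOVA: "
        + (", ".join(
            f"{o}: F={f:.4f} p={p:.4g}" for o, (f, p) in report.episodicity_ancova.items()
        ) or "not run"),
    ]
    (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")
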