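"""End-to-end run: simulate -> preprocess -> score -> fit -> report.

A run is a pure function of its validated configuration (which embeds the
master seed), so repeated runs write byte-identical tables.  The report
mirrors the structure of a conditioning-study results section: per-phase
CS+/CS- trial means by group, coefficient tables for every fitted model, the
retention early-differential regression, and the motion-censoring summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .lmm import FitResult
from .models import (ModelSpec, awareness_column, fit_group_lmm, fit_phase_lmm,
                     fit_ratings_clmm, fit_us_habituation,
                     retention_early_differential, sensitivity_suite)
from .motion_qc import censor, compute_fd
from .preprocess import PreprocessConfig, score_phase, trials_to_frame
from .synthetic import (CohortParams, SubjectData, parameter_set,
                        simulate_cohort, subject_metadata, write_cohort)
from .task_design import PHASES

log = logging.getLogger("fearcond")

MODEL_PHASES = ("acquisition", "extinction", "retention")


class PreprocessSettings(BaseModel):
    """Config-file mirror of PreprocessConfig."""

    model_config = ConfigDict(extra="forbid")
    median_window_s: float = 0.010
    band_low_hz: float = 0.03
    band_high_hz: float = 5.0
    filter_order: int = 1
    target_rate_hz: float = 100.0
    baseline_window_s: tuple[float, float] = (0.0, 1.0)
    peak_window_s: tuple[float, float] = (1.0, 5.0)
    floor_uS: float = 0.01
    ceiling_uS: float = 5.0
    zero_phase: bool = True

    def to_config(self, score_us: bool = False) -> PreprocessConfig:
        return PreprocessConfig(score_us_events=score_us,
                                **self.model_dump())


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    master_seed: int = 0
    group_sizes: dict[str, int] = Field(
        default_factory=lambda: {"child": 36, "adolescent": 40, "adult": 44})
    parameter_set: str = "default"
    sampling_rate_hz: Optional[float] = None   # override of the set's native rate
    preprocess: PreprocessSettings = Field(default_factory=PreprocessSettings)
    fd_threshold_mm: float = 0.9
    head_radius_mm: float = 50.0
    reinforcement_expected: int = 8            # audit value for acquisition
    iti_mean_s: float = 12.0                   # audit value for ITI sampler
    fit_group_models: bool = True
    fit_ratings_models: bool = True
    ratings_group_model: bool = False
    run_sensitivity: bool = True
    score_us: bool = True
    clmm_quadrature_nodes: int = 15

    @model_validator(mode="after")
    def _check_bands(self) -> "RunConfig":
        pre = self.preprocess
        native = self.sampling_rate_hz if self.sampling_rate_hz else 1000.0
        if pre.band_high_hz >= min(native, pre.target_rate_hz) / 2.0:
            raise ValueError(
                f"band_high_hz={pre.band_high_hz} must be below the Nyquist "
                f"frequency of the configured rates")
        parameter_set(self.parameter_set)  # raises on unknown name
        return self

    def cohort_params(self) -> CohortParams:
        params = parameter_set(self.parameter_set)
        params.group_sizes = dict(self.group_sizes)
        if self.sampling_rate_hz:
            params.sampling_rate_hz = self.sampling_rate_hz
        return params

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(path: str | Path | None = None,
                    overrides: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML run config; an empty/absent file means all
    defaults (the published protocol constants)."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        raw = loaded
    if overrides:
        raw.update(overrides)
    return RunConfig(**raw)


@dataclass
class RunReport:
    """Everything a finished run produced, plus provenance."""

    trial_means: pd.DataFrame
    fits: dict[str, FitResult]
    retention_scores: pd.DataFrame
    censoring: pd.DataFrame
    trials: pd.DataFrame
    ratings: pd.DataFrame
    metadata: pd.DataFrame
    sensitivity: Optional[dict] = None
    provenance: dict = field(default_factory=dict)

    @property
    def all_converged(self) -> bool:
        return all(f.converged for f in self.fits.values())


def score_cohort(subjects: list[SubjectData],
                 pre_config: PreprocessConfig) -> pd.DataFrame:
    """Score every subject's four phases into one long trial table."""
    trials = []
    n_missing = 0
    for s in subjects:
        for phase in PHASES:
            scored = score_phase(s.recordings[phase], s.schedules[phase], pre_config)
            n_missing += sum(t.scr_uS is None for t in scored)
            trials.extend(scored)
    log.info("scored %d trials across %d subjects (%d missing)",
             len(trials), len(subjects), n_missing)
    return trials_to_frame(trials)


def censoring_summary(subjects: list[SubjectData], threshold_mm: float = 0.9,
                      head_radius_mm: float = 50.0) -> pd.DataFrame:
    rows = []
    for s in subjects:
        fd = compute_fd(s.motion, head_radius_mm)
        res = censor(fd, threshold_mm)
        rows.append({"subject": s.spec.subject_id, "group": s.spec.age_group,
                     "n_volumes": int(fd.size), "n_censored": res.n_censored,
                     "mean_fd_mm": float(np.mean(fd)), "max_fd_mm": float(np.max(fd))})
    return pd.DataFrame(rows)


def trial_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean sqrt-SCR per phase x group x CS x trial (the summary-figure table)."""
    df = trials[trials["cs"].isin(["CS+", "CS-"])]
    out = (df.groupby(["phase", "group", "cs", "trial"], observed=True)["scr_sqrt"]
           .agg(["mean", "sem", "count"]).reset_index())
    return out.rename(columns={"mean": "mean_sqrt_scr", "sem": "sem_sqrt_scr",
                               "count": "n"})


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline deterministically and return the report."""
    log.info("simulating cohort (seed=%d, parameter set=%s)",
             config.master_seed, config.parameter_set)
    params = config.cohort_params()
    subjects = simulate_cohort(params, config.master_seed)
    meta = subject_metadata(subjects)
    meta["aware"] = awareness_column(meta)

    pre = config.preprocess.to_config(score_us=config.score_us)
    trials = score_cohort(subjects, pre).merge(meta, on="subject", how="left")
    ratings = pd.concat([s.ratings for s in subjects], ignore_index=True)

    fits: dict[str, FitResult] = {}
    for phase in MODEL_PHASES:
        fits[f"phase_{phase}"] = fit_phase_lmm(trials, phase)
        if config.fit_group_models:
            for ref in ("adolescent", "child"):
                fits[f"group_{phase}_ref_{ref}"] = fit_group_lmm(
                    trials, phase, reference_group=ref)
    scores, retention_fit = retention_early_differential(trials, meta)
    fits["retention_early_differential"] = retention_fit
    if config.score_us:
        fits["us_habituation"] = fit_us_habituation(trials)
    if config.fit_ratings_models:
        fits["ratings"] = fit_ratings_clmm(ratings, n_quad=config.clmm_quadrature_nodes)
        if config.ratings_group_model:
            fits["ratings_group"] = fit_ratings_clmm(
                ratings, include_group=True, n_quad=config.clmm_quadrature_nodes)
    sens = None
    if config.run_sensitivity:
        sens = sensitivity_suite(trials.drop(columns=["aware"]), ratings, meta)

    report = RunReport(
        trial_means=trial_means(trials),
        fits=fits,
        retention_scores=pd.DataFrame(
            {"subject": [s.subject_id for s in scores],
             "early_diff": [s.early_diff for s in scores]}),
        censoring=censoring_summary(subjects, config.fd_threshold_mm,
                                    config.head_radius_mm),
        trials=trials, ratings=ratings, metadata=meta,
        sensitivity=sens,
        provenance={
            "config_hash": config.config_hash(),
            "master_seed": config.master_seed,
            "parameter_set": config.parameter_set,
            "package_version": __version__,
            "n_subjects": len(subjects),
        },
    )
    for name, fit in fits.items():
        if not fit.converged:
            log.warning("model %s did not converge", name)
    return report


# ---------------------------------------------------------------------------
# report serialization

_FLOAT_FMT = "%.10g"


def write_report(report: RunReport, out_dir: str | Path,
                 make_figure: bool = True) -> Path:
    """Write CSV tables, a Markdown report, and the summary figure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.trial_means.to_csv(out / "trial_means.csv", index=False,
                              float_format=_FLOAT_FMT)
    report.retention_scores.to_csv(out / "retention_scores.csv", index=False,
                                   float_format=_FLOAT_FMT)
    report.censoring.to_csv(out / "censoring.csv", index=False,
                            float_format=_FLOAT_FMT)
    report.trials.to_csv(out / "trials.csv", index=False, float_format=_FLOAT_FMT)
    report.ratings.to_csv(out / "ratings.csv", index=False)
    report.metadata.to_csv(out / "participants.csv", index=False,
                           float_format=_FLOAT_FMT)
    for name, fit in report.fits.items():
        fit.table.to_csv(out / f"coef_{name}.csv", index=False,
                         float_format=_FLOAT_FMT)
    if report.sensitivity is not None:
        cmp_table = report.sensitivity.get("comparison")
        if isinstance(cmp_table, pd.DataFrame):
            cmp_table.to_csv(out / "sensitivity_comparison.csv", index=False,
                             float_format=_FLOAT_FMT)
    (out / "provenance.json").write_text(
        json.dumps(report.provenance, indent=1, sort_keys=True) + "\n")
    _write_markdown(report, out / "report.md")
    if make_figure:
        _figure(report, out / "scr_by_phase.png")
    return out


def _write_markdown(report: RunReport, path: Path) -> None:
    lines = ["# Fear-conditioning synthetic-cohort run", ""]
    lines += [f"- config hash: `{report.provenance.get('config_hash')}`",
              f"- master seed: {report.provenance.get('master_seed')}",
              f"- subjects: {report.provenance.get('n_subjects')}",
              f"- all models converged: {report.all_converged}", ""]
    cens = report.censoring.groupby("group", observed=True)["n_censored"].mean()
    lines += ["## Motion censoring (mean censored volumes per subject)", ""]
    lines += [f"- {g}: {v:.2f}" for g, v in cens.items()] + [""]
    for name, fit in report.fits.items():
        lines += [f"## {name}", "",
                  f"(method {fit.method}; n_obs={fit.n_obs}, "
                  f"n_subjects={fit.n_subjects}; {'; '.join(fit.notes)})", "",
                  "```", fit.table.to_string(index=False, float_format="%.4g"), "```", ""]
    path.write_text("\n".join(lines), encoding="utf-8")


def _figure(report: RunReport, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(report.trial_means["group"].unique())
    phases = [p for p in PHASES if p in set(report.trial_means["phase"])]
    fig, axes = plt.subplots(len(groups), len(phases),
                             figsize=(3 * len(phases), 2.4 * len(groups)),
                             sharey=True, squeeze=False)
    colors = {"CS+": "tab:red", "CS-": "tab:blue"}
    for gi, group in enumerate(groups):
        for pi, phase in enumerate(phases):
            ax = axes[gi][pi]
            sel = report.trial_means.query("group == @group and phase == @phase")
            for cs, sub in sel.groupby("cs", observed=True):
                ax.errorbar(sub["trial"], sub["mean_sqrt_scr"],
                            yerr=sub["sem_sqrt_scr"], label=cs,
                            color=colors.get(cs), marker="o", ms=3, lw=1)
            if gi == 0:
                ax.set_title(phase)
            if pi == 0:
                ax.set_ylabel(f"{group}\nsqrt SCR (uS^0.5)")
            if gi == len(groups) - 1:
                ax.set_xlabel("trial")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def regenerate_report(intermediates_dir: str | Path, out_dir: str | Path,
                      config: Optional[RunConfig] = None) -> Path:
    """Rebuild model fits and the report from stored trial-level tables.

    Reads ``trials.csv``, ``ratings.csv`` and ``participants.csv`` from a
    previous run's output; refitting the same tables is idempotent.
    """
    config = config if config is not None else RunConfig()
    src = Path(intermediates_dir)
    trials = pd.read_csv(src / "trials.csv")
    ratings = pd.read_csv(src / "ratings.csv")
    meta = pd.read_csv(src / "participants.csv")
    if "aware" not in meta.columns:
        meta["aware"] = awareness_column(meta)
    fits: dict[str, FitResult] = {}
    for phase in MODEL_PHASES:
        fits[f"phase_{phase}"] = fit_phase_lmm(trials, phase)
    scores, retention_fit = retention_early_differential(trials, meta)
    fits["retention_early_differential"] = retention_fit
    if (trials["cs"] == "US").any():
        fits["us_habituation"] = fit_us_habituation(trials)
    if config.fit_ratings_models:
        fits["ratings"] = fit_ratings_clmm(ratings, n_quad=config.clmm_quadrature_nodes)
    censoring = (pd.read_csv(src / "censoring.csv")
                 if (src / "censoring.csv").exists()
                 else pd.DataFrame(columns=["subject", "group", "n_volumes",
                                            "n_censored", "mean_fd_mm", "max_fd_mm"]))
    report = RunReport(
        trial_means=trial_means(trials), fits=fits,
        retention_scores=pd.DataFrame(
            {"subject": [s.subject_id for s in scores],
             "early_diff": [s.early_diff for s in scores]}),
        censoring=censoring, trials=trials, ratings=ratings, metadata=meta,
        provenance={"regenerated_from": str(src), "config_hash": config.config_hash(),
                    "package_version": __version__},
    )
    return write_report(report, out_dir)
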