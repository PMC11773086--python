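"""Trial-level statistical models for the fear-conditioning analyses.

Phase-wise linear mixed models of sqrt-transformed SCR (CS, trial and their
interaction; optionally age group with all its interactions), the
extinction-retention early-trial differential regressed on group, the
US-habituation model, cumulative-link mixed models for ordinal fear ratings,
the contingency-awareness rule, and covariate sensitivity re-fits.

Coding conventions: treatment (dummy) coding with CS- as the reference
stimulus; the reference age group is switchable (adolescents for the
dip-hypothesis contrasts, children for the development contrasts); trial is
a numeric 1-based within-phase index.  No multiple-testing correction is
applied; tables carry a note saying so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .clmm import CumulativeLinkMixedModel
from .lmm import FitResult, RandomInterceptLMM

__all__ = [
    "ModelSpec", "RetentionScore",
    "fit_phase_lmm", "fit_group_lmm", "retention_early_differential",
    "fit_us_habituation", "fit_ratings_clmm", "contingency_aware",
    "sensitivity_suite",
]

NO_CORRECTION_NOTE = "p-values are unadjusted (no multiple-testing correction)"


@dataclass
class ModelSpec:
    """Declarative description of one model fit."""

    outcome: str = "scr_sqrt"
    fixed_terms: list[str] = field(default_factory=lambda: ["cs * trial"])
    random_intercept_by: str = "subject"
    reference_levels: dict[str, str] = field(
        default_factory=lambda: {"cs": "CS-", "group": "adolescent",
                                 "phase": "post_acquisition"})
    covariates: list[str] = field(default_factory=list)

    def formula(self) -> str:
        rhs = " + ".join(self.fixed_terms + self.covariates)
        return rhs


@dataclass
class RetentionScore:
    """Per-subject early-retention differential responding."""

    subject_id: str
    early_diff: Optional[float]   # mean sqrt-SCR CS+ trials 1-2 minus CS- trials 1-2
    n_trials_used: int = 4


# ---------------------------------------------------------------------------
# design-matrix helpers

def _design(df: pd.DataFrame, rhs: str, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    env = {}
    data = df.copy()
    # apply treatment references by reordering category levels
    for col, ref in spec.reference_levels.items():
        if col in data.columns and not pd.api.types.is_numeric_dtype(data[col]):
            levels = [ref] + sorted(set(data[col].astype(str)) - {ref})
            data[col] = pd.Categorical(data[col].astype(str),
                                       categories=[l for l in levels
                                                   if l in set(data[col].astype(str))])
    mat = patsy.dmatrix("1 + " + rhs, data, return_type="dataframe")
    return mat.to_numpy(), list(mat.columns)


def _clean_names(names: Sequence[str]) -> list[str]:
    out = []
    for n in names:
        n = n.replace("T.", "").replace("[", ":").replace("]", "")
        n = n.replace("C(cs):", "cs:").replace("C(group):", "group:")
        out.append(n)
    return out


def _prepare_trials(trials: pd.DataFrame, phase: Optional[str],
                    outcome: str) -> pd.DataFrame:
    df = trials.copy()
    if phase is not None:
        df = df[df["phase"] == phase]
    df = df.dropna(subset=[outcome])  # row-wise deletion of missing outcomes
    if df.empty:
        raise ValueError(f"no usable rows for phase {phase!r}")
    return df


# ---------------------------------------------------------------------------
# phase-wise LMMs

def fit_phase_lmm(trials: pd.DataFrame, phase: str,
                  spec: Optional[ModelSpec] = None,
                  reml: bool = True) -> FitResult:
    """Whole-sample phase model: outcome ~ CS * trial + (1 | subject).

    Missing outcomes are dropped row-wise; p-values use Satterthwaite df.
    """
    spec = spec if spec is not None else ModelSpec()
    df = _prepare_trials(trials[trials["cs"].isin(["CS+", "CS-"])], phase, spec.outcome)
    _check_minimum(df, spec)
    rhs = spec.formula()
    X, names = _design(df, rhs, spec)
    fit = RandomInterceptLMM(reml=reml).fit(
        df[spec.outcome].to_numpy(), X, df[spec.random_intercept_by].to_numpy(),
        term_names=_clean_names(names))
    fit.notes.append(NO_CORRECTION_NOTE)
    return fit


def fit_group_lmm(trials: pd.DataFrame, phase: str,
                  reference_group: str = "adolescent",
                  spec: Optional[ModelSpec] = None,
                  reml: bool = True) -> FitResult:
    """Group model: adds group and all group x CS, group x trial and
    group x CS x trial interactions; reference group switchable."""
    if "group" not in trials.columns:
        raise ValueError("trials table has no 'group' column")
    if trials["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    spec = spec if spec is not None else ModelSpec()
    spec = ModelSpec(outcome=spec.outcome,
                     fixed_terms=["cs * trial * group"],
                     random_intercept_by=spec.random_intercept_by,
                     reference_levels={**spec.reference_levels,
                                       "group": reference_group},
                     covariates=spec.covariates)
    return fit_phase_lmm(trials, phase, spec, reml=reml)


def _check_minimum(df: pd.DataFrame, spec: ModelSpec) -> None:
    if df[spec.random_intercept_by].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    per_cs = df.groupby("cs", observed=True)["trial"].nunique()
    if (per_cs < 2).any():
        raise ValueError("need at least 2 trials per CS type")


# ---------------------------------------------------------------------------
# extinction-retention early differential

def retention_early_differential(trials: pd.DataFrame,
                                 metadata: Optional[pd.DataFrame] = None,
                                 require_complete: bool = True,
                                 outcome: str = "scr_sqrt"
                                 ) -> tuple[list[RetentionScore], FitResult]:
    """Mean sqrt-SCR of the first two CS+ trials minus the first two CS-
    trials of the retention phase, then OLS of that score on age group.

    With ``require_complete`` (default) a subject is scored only if all four
    early trials are present; otherwise available-case means are used.
    Returns the per-subject scores and the group-regression fit (overall
    group F appended to the coefficient table).
    """
    df = trials[(trials["phase"] == "retention")
                & trials["cs"].isin(["CS+", "CS-"])
                & (trials["trial"] <= 2)]
    scores: list[RetentionScore] = []
    for sid, sub in df.groupby("subject", observed=True):
        plus = sub.loc[sub["cs"] == "CS+", outcome].dropna()
        minus = sub.loc[sub["cs"] == "CS-", outcome].dropna()
        n_used = len(plus) + len(minus)
        if require_complete and n_used < 4:
            scores.append(RetentionScore(str(sid), None, n_used))
            continue
        if len(plus) == 0 or len(minus) == 0:
            scores.append(RetentionScore(str(sid), None, n_used))
            continue
        scores.append(RetentionScore(str(sid), float(plus.mean() - minus.mean()), n_used))

    sdf = pd.DataFrame({"subject": [s.subject_id for s in scores],
                        "early_diff": [s.early_diff for s in scores]})
    if metadata is not None:
        sdf = sdf.merge(metadata[["subject", "group"]], on="subject", how="left")
    elif "group" in trials.columns:
        sdf = sdf.merge(trials[["subject", "group"]].drop_duplicates(),
                        on="subject", how="left")
    else:
        raise ValueError("group labels required (metadata or trials 'group' column)")
    sdf = sdf.dropna(subset=["early_diff", "group"])
    if sdf["group"].nunique() < 2:
        raise ValueError("need at least 2 groups with scored subjects")

    levels = ["adolescent"] + sorted(set(sdf["group"]) - {"adolescent"})
    sdf["group"] = pd.Categorical(sdf["group"], categories=[l for l in levels
                                                            if l in set(sdf["group"])])
    X = patsy.dmatrix("1 + group", sdf, return_type="dataframe")
    ols = sm.OLS(sdf["early_diff"].to_numpy(), X.to_numpy()).fit()
    table = pd.DataFrame({
        "term": _clean_names(list(X.columns)),
        "estimate": ols.params, "se": ols.bse,
        "stat": ols.tvalues, "df": float(ols.df_resid), "p": ols.pvalues,
    })
    if ols.df_resid > 0:
        f_test = ols.f_test(np.eye(X.shape[1])[1:])  # overall group effect
        f_val, f_p = float(f_test.fvalue), float(f_test.pvalue)
    else:  # saturated fit: no residual df for an F test
        f_val, f_p = np.nan, np.nan
    table = pd.concat([table, pd.DataFrame([{
        "term": "group (overall F)", "estimate": np.nan, "se": np.nan,
        "stat": f_val, "df": float(ols.df_resid), "p": f_p}])],
        ignore_index=True)
    fit = FitResult(table=table, variance_components={"residual_var": float(ols.scale)},
                    converged=True, n_obs=int(ols.nobs), n_subjects=int(ols.nobs),
                    loglik=float(ols.llf), method="OLS", model="retention_regression",
                    notes=[NO_CORRECTION_NOTE])
    return scores, fit


# ---------------------------------------------------------------------------
# US habituation

def fit_us_habituation(trials: pd.DataFrame,
                       reference_group: str = "adolescent",
                       reml: bool = True) -> FitResult:
    """LMM of sqrt-SCR to the US over acquisition trials:
    outcome ~ trial * group + (1 | subject)."""
    df = trials[(trials["cs"] == "US") & (trials["phase"] == "acquisition")].copy()
    df = df.dropna(subset=["scr_sqrt"])
    if df.empty:
        raise ValueError("no US-locked responses in the trial table")
    if df.groupby("subject", observed=True)["trial"].nunique().max() < 2:
        raise ValueError("need at least 2 US trials per subject")
    spec = ModelSpec(fixed_terms=["trial * group"],
                     reference_levels={"group": reference_group})
    X, names = _design(df, spec.formula(), spec)
    fit = RandomInterceptLMM(reml=reml).fit(
        df["scr_sqrt"].to_numpy(), X, df["subject"].to_numpy(),
        term_names=_clean_names(names))
    fit.notes.append(NO_CORRECTION_NOTE)
    return fit


# ---------------------------------------------------------------------------
# ordinal ratings CLMM

def fit_ratings_clmm(ratings: pd.DataFrame,
                     spec: Optional[ModelSpec] = None,
                     include_group: bool = False,
                     reference_group: str = "adolescent",
                     n_quad: int = 15) -> FitResult:
    """Cumulative-link mixed model of 1-5 fear ratings.

    Whole-sample model: rating ~ CS * phase with a subject random intercept;
    with ``include_group``, CS * phase * group.  References: CS- and the
    post-acquisition phase (and the chosen group).
    """
    df = ratings.dropna(subset=["rating"]).copy()
    if not df["rating"].between(1, 5).all():
        raise ValueError("ratings must lie in 1..5")
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    spec = spec if spec is not None else ModelSpec(
        outcome="rating",
        fixed_terms=["cs * phase * group"] if include_group else ["cs * phase"],
        reference_levels={"cs": "CS-", "phase": "post_acquisition",
                          "group": reference_group})
    X, names = _design(df, spec.formula(), spec)
    # thresholds absorb the intercept (location identifiability)
    keep = [i for i, n in enumerate(names) if n != "Intercept"]
    X = X[:, keep]
    names = [names[i] for i in keep]
    model = CumulativeLinkMixedModel(n_quad=n_quad)
    fit = model.fit(df["rating"].to_numpy(dtype=int), X,
                    df["subject"].to_numpy(),
                    term_names=_clean_names(names), n_categories=5)
    fit.notes.append(NO_CORRECTION_NOTE)
    return fit


# ---------------------------------------------------------------------------
# contingency awareness

def contingency_aware(cs_plus_screamed: Optional[str],
                      cs_minus_screamed: Optional[str]) -> Optional[bool]:
    """Aware iff the subject reports the CS+ screamed and the CS- did not.

    Answers are "yes"/"no"; a missing answer yields missing awareness (None).
    """
    def norm(x):
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return None
        s = str(x).strip().lower()
        if s in ("yes", "y", "true", "1"):
            return True
        if s in ("no", "n", "false", "0"):
            return False
        return None

    plus, minus = norm(cs_plus_screamed), norm(cs_minus_screamed)
    if plus is None or minus is None:
        return None
    return plus and not minus


def awareness_column(metadata: pd.DataFrame) -> pd.Series:
    """Vectorized awareness rule over a participants table."""
    return metadata.apply(
        lambda r: contingency_aware(r.get("cs_plus_screamed"),
                                    r.get("cs_minus_screamed")), axis=1)


# ---------------------------------------------------------------------------
# sensitivity analyses

def sensitivity_suite(trials: pd.DataFrame, ratings: pd.DataFrame,
                      metadata: pd.DataFrame,
                      phases: Sequence[str] = ("acquisition", "extinction", "retention"),
                      reml: bool = True,
                      fit_ratings: bool = False,
                      n_quad: int = 15) -> dict[str, dict[str, FitResult]]:
    """Covariate and awareness-subset sensitivity re-fits.

    Variants: base; + SES; + US sound level; retention + days between
    sessions; contingency-aware subset only.  Constant covariates are
    dropped with a note rather than breaking the design.  Returns
    {variant: {model_name: FitResult}} plus a "comparison" entry summarizing
    sign/significance stability of the CS term per phase.
    """
    meta = metadata.copy()
    meta["aware"] = awareness_column(meta)
    tdf = trials.merge(meta.drop(columns=[c for c in ("group",) if c in trials.columns]),
                       on="subject", how="left")

    def covariate_ok(name: str) -> bool:
        return name in tdf.columns and tdf[name].nunique(dropna=True) > 1

    variants: dict[str, dict] = {}

    def base_models(df: pd.DataFrame, covs: list[str]) -> dict[str, FitResult]:
        out = {}
        for phase in phases:
            spec = ModelSpec(covariates=covs)
            out[f"phase_{phase}"] = fit_phase_lmm(df, phase, spec, reml=reml)
        return out

    variants["base"] = base_models(tdf, [])
    for cov in ("ses", "us_sound_level"):
        if covariate_ok(cov):
            variants[f"with_{cov}"] = base_models(tdf, [cov])
        else:
            variants[f"with_{cov}"] = {"note": f"covariate {cov} constant or absent; dropped"}
    if covariate_ok("days_between_sessions") and "retention" in phases:
        spec = ModelSpec(covariates=["days_between_sessions"])
        variants["retention_with_days"] = {
            "phase_retention": fit_phase_lmm(tdf, "retention", spec, reml=reml)}
    aware_ids = set(meta.loc[meta["aware"] == True, "subject"])  # noqa: E712
    variants["aware_only"] = base_models(tdf[tdf["subject"].isin(aware_ids)], [])
    if fit_ratings:
        variants["ratings_base"] = {
            "ratings": fit_ratings_clmm(ratings, n_quad=n_quad)}
        variants["ratings_aware_only"] = {
            "ratings": fit_ratings_clmm(ratings[ratings["subject"].isin(aware_ids)],
                                        n_quad=n_quad)}

    rows = []
    for vname, models in variants.items():
        for mname, fit in models.items():
            if not isinstance(fit, FitResult):
                continue
            cs_rows = fit.table[fit.table["term"].str.startswith("cs:CS+")]
            if cs_rows.empty:
                continue
            r = cs_rows.iloc[0]
            rows.append({"variant": vname, "model": mname, "term": r["term"],
                         "estimate": r["estimate"], "p": r["p"],
                         "sign": int(np.sign(r["estimate"])),
                         "significant": bool(r["p"] < 0.05)})
    variants["comparison"] = pd.DataFrame(rows)
    return variants
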