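"""Synthetic cohorts for the differential fear-conditioning paradigm.

Generates, with known planted effects, everything the analysis stage consumes:

* continuous skin-conductance recordings — phasic responses (Bateman kernel)
  event-locked to a task schedule, riding on a tonic level with slow drift and
  measurement noise;
* trial amplitudes from a zero-inflated log-normal model whose log-mean
  carries the conditioning structure (differential learning during
  acquisition, decay during extinction, within-session habituation, an early
  return-of-fear boost at retention, group offsets, subject random
  intercepts);
* ordinal fear ratings (1-5) from a proportional-odds generative model with a
  subject random intercept;
* contingency-awareness reports with group-level awareness probabilities;
* six-column realignment parameters (random-walk head motion with occasional
  spikes, group-graded in magnitude).

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .physio import PhysioRecording, write_physio
from .task_design import (PhaseConfig, ScheduledEvent, TaskSchedule, PHASES,
                          default_protocol, make_schedule, write_events)

__all__ = [
    "SudomotorKernel", "AmplitudeModel", "RatingParams", "SubjectSpec",
    "CohortParams", "SubjectData",
    "bateman_kernel", "draw_amplitude", "simulate_recording",
    "simulate_ratings", "simulate_motion", "simulate_cohort", "write_cohort",
    "cumulative_logit_probs", "GROUPS",
]

GROUPS = ("child", "adolescent", "adult")

RATING_PHASES = ("pre_habituation", "post_acquisition", "post_extinction")


# ---------------------------------------------------------------------------
# Phasic response kernel

@dataclass(frozen=True)
class SudomotorKernel:
    """Bateman (difference-of-exponentials) phasic response shape.

    Defaults place the kernel peak ~2.6 s after stimulus onset, inside the
    1-5 s scoring window used downstream.
    """

    tau_rise_s: float = 0.75
    tau_decay_s: float = 2.0
    latency_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise_s < self.tau_decay_s:
            raise ValueError("require 0 < tau_rise_s < tau_decay_s")
        if self.latency_s < 0:
            raise ValueError("latency_s must be >= 0")

    @property
    def peak_time_s(self) -> float:
        """Closed-form argmax of the unshifted kernel, plus latency."""
        r, d = self.tau_rise_s, self.tau_decay_s
        return self.latency_s + np.log(d / r) * (r * d) / (d - r)


def bateman_kernel(kernel: SudomotorKernel, t: np.ndarray) -> np.ndarray:
    """Evaluate the unit-peak Bateman kernel on time grid ``t`` (seconds).

    Zero before the latency; scaled so the analytic maximum equals 1.
    """
    t = np.asarray(t, dtype=float)
    r, d = kernel.tau_rise_s, kernel.tau_decay_s
    ts = t - kernel.latency_s
    raw = np.where(ts >= 0, np.exp(-np.clip(ts, 0, None) / d) - np.exp(-np.clip(ts, 0, None) / r), 0.0)
    t_peak = kernel.peak_time_s - kernel.latency_s
    peak = np.exp(-t_peak / d) - np.exp(-t_peak / r)
    return raw / peak


# ---------------------------------------------------------------------------
# Trial amplitude model

def _default_intercepts() -> dict[tuple[str, str], float]:
    # log-microsiemens; exp() gives typical SCR magnitudes of 0.2-0.5 uS
    return {
        ("habituation", "CS+"): np.log(0.35),
        ("habituation", "CS-"): np.log(0.35),
        ("acquisition", "CS+"): np.log(0.25),
        ("acquisition", "CS-"): np.log(0.25),
        ("extinction", "CS+"): np.log(0.45),
        ("extinction", "CS-"): np.log(0.25),
        ("retention", "CS+"): np.log(0.30),
        ("retention", "CS-"): np.log(0.22),
    }


@dataclass
class AmplitudeModel:
    """Generative model for trial SCR amplitudes (log-normal, zero-inflated).

    The log-mean of a CS trial is::

        mu = intercept(phase, cs) + learning/decay terms + group offset

    with, per phase: acquisition CS+ gains ``learning_slope`` per trial
    (differential growth); during extinction the CS+ excess over CS- shrinks
    by ``extinction_decay`` per trial (floored at 0, convergence); all trials
    lose ``habituation_decay`` per trial (within-session habituation);
    retention CS+ trials 1-2 gain ``retention_boost`` (early return of fear).
    US amplitudes follow their own decaying series.  Realized amplitude is 0
    with probability ``nonresponse_p``, else ``exp(mu + b_subject + eps)``
    with ``eps ~ N(0, noise_sd)``.
    """

    intercepts: dict[tuple[str, str], float] = field(default_factory=_default_intercepts)
    learning_slope: float = 0.12
    extinction_decay: float = 0.08
    habituation_decay: float = 0.04
    retention_boost: float = 0.35
    group_offsets: dict[str, float] = field(
        default_factory=lambda: {g: 0.0 for g in GROUPS})
    subject_sd: float = 0.35
    noise_sd: float = 0.30
    nonresponse_p: float = 0.10
    us_intercept: float = float(np.log(0.9))
    us_decay: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.nonresponse_p <= 1:
            raise ValueError("nonresponse_p must be in [0, 1]")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("SDs must be >= 0")

    def log_mean(self, phase: str, trial_type: str, trial_index: int,
                 group: str = "adolescent") -> float:
        """Population log-amplitude for one event (no subject/noise terms)."""
        k = trial_index - 1  # trial 1 carries the intercept
        g = self.group_offsets.get(group, 0.0)
        if trial_type == "US":
            return self.us_intercept - self.us_decay * k + g
        mu = self.intercepts[(phase, trial_type)] - self.habituation_decay * k
        if phase == "acquisition" and trial_type == "CS+":
            mu += self.learning_slope * k
        if phase == "extinction" and trial_type == "CS+":
            diff0 = self.intercepts[(phase, "CS+")] - self.intercepts[(phase, "CS-")]
            mu = (self.intercepts[(phase, "CS-")] - self.habituation_decay * k
                  + max(0.0, diff0 - self.extinction_decay * k))
        if phase == "retention" and trial_type == "CS+" and trial_index <= 2:
            mu += self.retention_boost
        return mu + g


@dataclass
class SubjectSpec:
    """Per-subject generative parameters and covariates."""

    subject_id: str
    age_group: str
    random_intercept: float = 0.0     # log-amplitude deviation, shared by all trials
    tonic_level_uS: float = 5.0
    drift_rate_uS_per_s: float = 0.0
    noise_sd_uS: float = 0.01         # measurement noise on the continuous signal
    motion_level: float = 1.0
    ses: float = 7.0
    us_sound_level: float = 40.0
    days_between_sessions: float = 4.0
    rating_intercept: float = 0.0     # latent-scale deviation for ordinal ratings
    aware: bool = True

    def __post_init__(self) -> None:
        if self.age_group not in GROUPS:
            raise ValueError(f"age_group must be one of {GROUPS}")
        if self.tonic_level_uS <= 0:
            raise ValueError("tonic_level_uS must be positive")


def draw_amplitude(model: AmplitudeModel, subject: SubjectSpec,
                   event: ScheduledEvent, phase: str,
                   rng: np.random.Generator) -> float:
    """Draw one trial's SCR amplitude in microsiemens (0 for non-response)."""
    if event.trial_type not in ("CS+", "CS-", "US"):
        raise ValueError(f"not a CS/US event: {event.trial_type}")
    if rng.random() < model.nonresponse_p:
        return 0.0
    mu = model.log_mean(phase, event.trial_type, event.trial_index, subject.age_group)
    eps = rng.normal(0.0, model.noise_sd) if model.noise_sd else 0.0
    return float(np.exp(mu + subject.random_intercept + eps))


# ---------------------------------------------------------------------------
# Continuous recording

#: Seconds of signal kept after the final event offset (room for the last response).
TAIL_S = 15.0


def simulate_recording(schedule: TaskSchedule, subject: SubjectSpec,
                       model: AmplitudeModel | None = None,
                       kernel: SudomotorKernel | None = None,
                       rng: np.random.Generator | int | None = None,
                       sampling_rate_hz: float = 1000.0,
                       return_amplitudes: bool = False):
    """Synthesize a continuous skin-conductance recording for one phase.

    signal = tonic + drift + sum_events amplitude * kernel(t - onset) + noise.
    """
    if not schedule.events:
        raise ValueError("schedule has no events")
    if sampling_rate_hz < 20:
        raise ValueError("sampling_rate_hz must be >= 20 to resolve the kernel")
    model = model if model is not None else AmplitudeModel()
    kernel = kernel if kernel is not None else SudomotorKernel()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    n = int(np.ceil((schedule.end_s + TAIL_S) * sampling_rate_hz))
    t_kernel = np.arange(int(np.ceil(TAIL_S * sampling_rate_hz))) / sampling_rate_hz
    k = bateman_kernel(kernel, t_kernel)

    signal = np.full(n, float(subject.tonic_level_uS))
    if subject.drift_rate_uS_per_s:
        signal += subject.drift_rate_uS_per_s * np.arange(n) / sampling_rate_hz
    amplitudes: dict[tuple[str, int], float] = {}
    for event in schedule.events:
        a = draw_amplitude(model, subject, event, schedule.phase_name, rng)
        amplitudes[(event.trial_type, event.trial_index)] = a
        if a == 0.0:
            continue
        i0 = int(np.round(event.onset_s * sampling_rate_hz))
        stop = min(i0 + k.size, n)
        signal[i0:stop] += a * k[: stop - i0]
    if subject.noise_sd_uS:
        signal += rng.normal(0.0, subject.noise_sd_uS, size=n)

    rec = PhysioRecording(signal, sampling_rate_hz, 0.0,
                          subject_id=subject.subject_id,
                          phase_name=schedule.phase_name)
    return (rec, amplitudes) if return_amplitudes else rec


# ---------------------------------------------------------------------------
# Ordinal fear ratings

@dataclass
class RatingParams:
    """Proportional-odds generative model for 1-5 fear ratings.

    Latent scale: ``eta = beta_cs_by_phase[phase] * [cs is CS+] +
    phase_shift[phase] + group offset + b_subject``; then
    ``P(y <= k) = logistic(threshold_k - eta)``.  The CS+ effect grows after
    acquisition and partially persists after extinction (fear learning, then
    incomplete subjective extinction).
    """

    thresholds: tuple[float, ...] = (-1.0, 0.5, 2.0, 3.5)
    beta_cs_by_phase: dict[str, float] = field(default_factory=lambda: {
        "pre_habituation": 0.0, "post_acquisition": 2.5, "post_extinction": 1.0})
    phase_shift: dict[str, float] = field(default_factory=lambda: {
        "pre_habituation": 0.0, "post_acquisition": 0.5, "post_extinction": 0.0})
    group_offsets: dict[str, float] = field(default_factory=lambda: {g: 0.0 for g in GROUPS})
    subject_sd: float = 1.0

    def __post_init__(self) -> None:
        th = np.asarray(self.thresholds, dtype=float)
        if th.size < 1 or np.any(np.diff(th) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    def linear_predictor(self, phase: str, cs: str, group: str = "adolescent") -> float:
        eta = self.phase_shift[phase] + self.group_offsets.get(group, 0.0)
        if cs == "CS+":
            eta += self.beta_cs_by_phase[phase]
        return eta


def cumulative_logit_probs(eta: float, thresholds: Sequence[float]) -> np.ndarray:
    """Category probabilities of the cumulative-logit model, closed form."""
    th = np.asarray(thresholds, dtype=float)
    cdf = 1.0 / (1.0 + np.exp(-(th - eta)))
    cdf = np.concatenate([[0.0], cdf, [1.0]])
    return np.diff(cdf)


def simulate_ratings(subject: SubjectSpec, params: RatingParams,
                     rng: np.random.Generator) -> pd.DataFrame:
    """One rating per CS per rating phase (6 rows: subject, phase, cs, rating)."""
    rows = []
    b = subject.rating_intercept
    for phase in RATING_PHASES:
        for cs in ("CS+", "CS-"):
            eta = params.linear_predictor(phase, cs, subject.age_group) + b
            p = cumulative_logit_probs(eta, params.thresholds)
            rating = int(rng.choice(len(p), p=p)) + 1
            rows.append({"subject": subject.subject_id, "group": subject.age_group,
                         "phase": phase, "cs": cs, "rating": rating})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Head motion

def simulate_motion(n_volumes: int, subject: SubjectSpec,
                    rng: np.random.Generator,
                    step_sd_mm: float = 0.03,
                    spike_p: float = 0.02,
                    head_radius_mm: float = 50.0) -> np.ndarray:
    """Six-column realignment parameters (3 translations mm, 3 rotations rad).

    A random walk whose step SD scales with ``subject.motion_level``, plus
    occasional single-volume spikes (a transient displacement that reverts at
    the next volume), emulating age-graded in-scanner motion.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    level = subject.motion_level
    if level == 0:
        return np.zeros((n_volumes, 6))
    sd_t = step_sd_mm * level
    sd_r = sd_t / head_radius_mm
    steps = np.empty((n_volumes, 6))
    steps[0] = 0.0
    steps[1:, :3] = rng.normal(0.0, sd_t, size=(n_volumes - 1, 3))
    steps[1:, 3:] = rng.normal(0.0, sd_r, size=(n_volumes - 1, 3))
    params = np.cumsum(steps, axis=0)
    spikes = rng.random(n_volumes) < min(1.0, spike_p * level)
    spikes[0] = False
    for v in np.nonzero(spikes)[0]:
        axis = int(rng.integers(3))
        params[v, axis] += rng.uniform(0.6, 1.8) * np.sign(rng.standard_normal())
    return params


# ---------------------------------------------------------------------------
# Cohort assembly

#: Per-group covariate distributions (mean, SD): SES score 0-9, US sound level
#: (% of max), days between the two sessions -- children lowest sound level,
#: adults highest; motion highest in children.
GROUP_PROFILES = {
    "child": {"ses": (7.0, 1.7), "sound": (10.9, 3.8), "days": (4.1, 2.8),
              "motion_level": 3.0, "aware_p": 0.79},
    "adolescent": {"ses": (7.7, 1.1), "sound": (41.7, 10.2), "days": (3.8, 2.2),
                   "motion_level": 1.5, "aware_p": 0.85},
    "adult": {"ses": (7.1, 1.6), "sound": (49.6, 8.0), "days": (4.5, 4.5),
              "motion_level": 0.5, "aware_p": 0.95},
}

DEFAULT_GROUP_SIZES = {"child": 36, "adolescent": 40, "adult": 44}


@dataclass
class CohortParams:
    """Everything that defines a synthetic cohort apart from its seed."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    amplitude: AmplitudeModel = field(default_factory=AmplitudeModel)
    ratings: RatingParams = field(default_factory=RatingParams)
    kernel: SudomotorKernel = field(default_factory=SudomotorKernel)
    sampling_rate_hz: float = 1000.0
    tonic_mean_uS: float = 5.0
    tonic_sd_uS: float = 1.0
    drift_sd_uS_per_s: float = 0.002
    signal_noise_sd_uS: float = 0.01
    tr_s: float = 2.0     # repetition time used to size the motion trace
    protocol: dict[str, PhaseConfig] = field(default_factory=default_protocol)

    def __post_init__(self) -> None:
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if self.group_sizes[g] < 1:
                raise ValueError("group sizes must be >= 1")


#: Named parameter sets selectable from run configs.
def parameter_set(name: str) -> CohortParams:
    """Return a named cohort parameter set.

    ``default``       — planted conditioning effects, no group differences in
                        SCR level or retention (group-graded motion and
                        covariates only);
    ``developmental`` — adds group offsets (children > adults in overall SCR);
    ``null``          — no conditioning effects at all (for calibration runs).
    """
    if name == "default":
        return CohortParams()
    if name == "developmental":
        p = CohortParams()
        p.amplitude.group_offsets = {"child": 0.15, "adolescent": 0.0, "adult": -0.10}
        p.ratings.group_offsets = {"child": 0.3, "adolescent": 0.6, "adult": 0.0}
        return p
    if name == "null":
        p = CohortParams()
        flat = {(ph, cs): np.log(0.3) for ph in PHASES for cs in ("CS+", "CS-")}
        p.amplitude = AmplitudeModel(
            intercepts=flat, learning_slope=0.0, extinction_decay=0.0,
            habituation_decay=0.0, retention_boost=0.0)
        p.ratings = RatingParams(
            beta_cs_by_phase={ph: 0.0 for ph in RATING_PHASES},
            phase_shift={ph: 0.0 for ph in RATING_PHASES})
        return p
    raise ValueError(f"unknown parameter set {name!r}")


@dataclass
class SubjectData:
    """All simulated artifacts for one subject."""

    spec: SubjectSpec
    schedules: dict[str, TaskSchedule]
    recordings: dict[str, PhysioRecording]
    planted_amplitudes: dict[str, dict[tuple[str, int], float]]
    ratings: pd.DataFrame
    contingency_report: dict[str, str]   # {"cs_plus_screamed": "yes"/"no", ...}
    motion: np.ndarray                   # retention-phase realignment parameters


def _draw_subject(subject_id: str, group: str, params: CohortParams,
                  rng: np.random.Generator) -> SubjectSpec:
    prof = GROUP_PROFILES[group]
    ses = float(np.clip(rng.normal(*prof["ses"]), 0, 9))
    sound = float(np.clip(rng.normal(*prof["sound"]), 5, 80))
    days = float(max(1.0, rng.normal(*prof["days"])))
    return SubjectSpec(
        subject_id=subject_id, age_group=group,
        random_intercept=float(rng.normal(0.0, params.amplitude.subject_sd)),
        tonic_level_uS=float(max(0.5, rng.normal(params.tonic_mean_uS, params.tonic_sd_uS))),
        drift_rate_uS_per_s=float(rng.normal(0.0, params.drift_sd_uS_per_s)),
        noise_sd_uS=params.signal_noise_sd_uS,
        motion_level=prof["motion_level"],
        ses=ses, us_sound_level=sound, days_between_sessions=days,
        rating_intercept=float(rng.normal(0.0, params.ratings.subject_sd)),
        aware=bool(rng.random() < prof["aware_p"]),
    )


def simulate_subject(subject_id: str, group: str, params: CohortParams,
                     seed: np.random.SeedSequence) -> SubjectData:
    rng = np.random.default_rng(seed)
    spec = _draw_subject(subject_id, group, params, rng)
    schedules, recordings, planted = {}, {}, {}
    for phase in PHASES:
        sched = make_schedule(params.protocol[phase], rng)
        rec, amps = simulate_recording(
            sched, spec, params.amplitude, params.kernel, rng,
            params.sampling_rate_hz, return_amplitudes=True)
        schedules[phase], recordings[phase], planted[phase] = sched, rec, amps
    ratings = simulate_ratings(spec, params.ratings, rng)
    if spec.aware:
        report = {"cs_plus_screamed": "yes", "cs_minus_screamed": "no"}
    else:
        # any report other than (yes, no): misremembered or over-generalized
        plus, minus = [("yes", "yes"), ("no", "no"), ("no", "yes")][int(rng.integers(3))]
        report = {"cs_plus_screamed": plus, "cs_minus_screamed": minus}
    n_vol = int(np.ceil(recordings["retention"].duration_s / params.tr_s))
    motion = simulate_motion(n_vol, spec, rng)
    return SubjectData(spec, schedules, recordings, planted, ratings, report, motion)


def simulate_cohort(params: CohortParams | None = None,
                    master_seed: int = 0) -> list[SubjectData]:
    """Simulate the full cohort, deterministically in ``master_seed``.

    Per-subject seeds are spawned from a single SeedSequence, so any subject
    can be regenerated in isolation from (master_seed, subject position).
    """
    params = params if params is not None else CohortParams()
    n_total = sum(params.group_sizes.values())
    seeds = np.random.SeedSequence(master_seed).spawn(n_total)
    subjects, i = [], 0
    ids = set()
    for group in GROUPS:
        for _ in range(params.group_sizes.get(group, 0)):
            sid = f"sub-{i + 1:03d}"
            if sid in ids:
                raise ValueError(f"duplicate subject id {sid}")
            ids.add(sid)
            subjects.append(simulate_subject(sid, group, params, seeds[i]))
            i += 1
    return subjects


def subject_metadata(subjects: Sequence[SubjectData]) -> pd.DataFrame:
    """Covariate/metadata table: one row per subject."""
    return pd.DataFrame([{
        "subject": s.spec.subject_id, "group": s.spec.age_group,
        "ses": round(s.spec.ses, 3), "us_sound_level": round(s.spec.us_sound_level, 3),
        "days_between_sessions": round(s.spec.days_between_sessions, 3),
        "cs_plus_screamed": s.contingency_report["cs_plus_screamed"],
        "cs_minus_screamed": s.contingency_report["cs_minus_screamed"],
    } for s in subjects])


def write_cohort(subjects: Sequence[SubjectData], out_dir: str | Path,
                 master_seed: Optional[int] = None) -> Path:
    """Write the on-disk cohort layout.

    Per subject: ``sub-XXX/<phase>_physio.tsv.gz`` (+ JSON sidecar),
    ``<phase>_events.tsv``, ``rp_retention.txt``; cohort-level ``ratings.csv``,
    ``participants.csv`` and a ``manifest.json`` with seeds and counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        sdir = out / s.spec.subject_id
        sdir.mkdir(exist_ok=True)
        for phase in PHASES:
            write_physio(s.recordings[phase], sdir / phase)
            write_events(s.schedules[phase], sdir / f"{phase}_events.tsv")
        np.savetxt(sdir / "rp_retention.txt", s.motion, fmt="%12.6e")
    pd.concat([s.ratings for s in subjects], ignore_index=True).to_csv(
        out / "ratings.csv", index=False)
    subject_metadata(subjects).to_csv(out / "participants.csv", index=False)
    manifest = {
        "master_seed": master_seed,
        "n_subjects": len(subjects),
        "groups": {g: sum(s.spec.age_group == g for s in subjects) for g in GROUPS},
        "subjects": [s.spec.subject_id for s in subjects],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return out
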