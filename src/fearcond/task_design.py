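"""Four-phase differential fear-conditioning protocol: schedules and events files.

The protocol is the "screaming lady" differential cued-conditioning paradigm:
habituation (4 CS+ / 4 CS-, 7 s each), acquisition (10 CS+ / 10 CS-, CS+ 6 s
followed in 8 of 10 trials by a 1 s aversive US, CS- 7 s), extinction learning
and a retention test (10 CS+ / 10 CS-, 7 s, no US).  CS order is pseudorandom
with no more than two identical CS types in a row, and inter-trial intervals
are drawn from a truncated Gaussian (mean 12 s, SD 1 s).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PhaseConfig",
    "ScheduledEvent",
    "TaskSchedule",
    "ScheduleError",
    "EventsParseError",
    "PHASES",
    "default_protocol",
    "sample_iti",
    "make_schedule",
    "write_events",
    "read_events",
]

PHASES = ("habituation", "acquisition", "extinction", "retention")

#: Resampling attempts before declaring the run-length constraint infeasible.
MAX_SHUFFLE_ATTEMPTS = 10_000

#: ITI draws are truncated (by resampling) to mean +/- this many SDs.
ITI_TRUNCATION_SDS = 3.0


class ScheduleError(ValueError):
    """Invalid or infeasible schedule configuration."""


class EventsParseError(ValueError):
    """Malformed events file; message carries the 1-based line number."""


@dataclass(frozen=True)
class PhaseConfig:
    """Trial counts, durations and timing parameters for one phase."""

    phase_name: str
    n_cs_plus: int
    n_cs_minus: int
    cs_plus_duration_s: float
    cs_minus_duration_s: float
    us_duration_s: float = 0.0
    n_reinforced: int = 0
    iti_mean_s: float = 12.0
    iti_sd_s: float = 1.0
    max_run_length: int = 2

    def __post_init__(self) -> None:
        if self.phase_name not in PHASES:
            raise ScheduleError(f"unknown phase_name {self.phase_name!r}")
        if self.n_cs_plus < 0 or self.n_cs_minus < 0:
            raise ScheduleError("trial counts must be non-negative")
        if self.n_reinforced > self.n_cs_plus:
            raise ScheduleError("n_reinforced must not exceed n_cs_plus")
        if self.cs_plus_duration_s <= 0 or self.cs_minus_duration_s <= 0:
            raise ScheduleError("CS durations must be positive")
        if self.n_reinforced > 0 and self.us_duration_s <= 0:
            raise ScheduleError("us_duration_s must be positive when trials are reinforced")
        if self.max_run_length < 1:
            raise ScheduleError("max_run_length must be >= 1")
        if not (np.isfinite(self.iti_mean_s) and np.isfinite(self.iti_sd_s)):
            raise ScheduleError("ITI parameters must be finite")
        if self.iti_sd_s < 0:
            raise ScheduleError("iti_sd_s must be >= 0")


@dataclass(frozen=True)
class ScheduledEvent:
    """One timed stimulus presentation within a phase.

    ``trial_index`` is 1-based within its own trial type; a US shares the
    trial_index of the CS+ it follows.
    """

    onset_s: float
    duration_s: float
    trial_type: str  # "CS+", "CS-" or "US"
    trial_index: int
    reinforced: bool = False

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class TaskSchedule:
    phase_config: PhaseConfig
    events: tuple[ScheduledEvent, ...]
    seed: Optional[int] = None

    @property
    def phase_name(self) -> str:
        return self.phase_config.phase_name

    def cs_events(self) -> list[ScheduledEvent]:
        return [e for e in self.events if e.trial_type in ("CS+", "CS-")]

    def us_events(self) -> list[ScheduledEvent]:
        return [e for e in self.events if e.trial_type == "US"]

    @property
    def end_s(self) -> float:
        return max(e.offset_s for e in self.events) if self.events else 0.0


def default_protocol() -> dict[str, PhaseConfig]:
    """The published protocol constants, keyed by phase name.

    Habituation: 4+4 trials of 7 s.  Acquisition: 10+10 trials, CS+ 6 s with
    8 of 10 reinforced by a 1 s US (80% reinforcement), CS- 7 s.  Extinction
    and retention: 10+10 trials of 7 s.  All phases: ITI ~ N(12, 1) s,
    at most two identical CS types in a row.
    """
    return {
        "habituation": PhaseConfig(
            "habituation", n_cs_plus=4, n_cs_minus=4,
            cs_plus_duration_s=7.0, cs_minus_duration_s=7.0,
        ),
        "acquisition": PhaseConfig(
            "acquisition", n_cs_plus=10, n_cs_minus=10,
            cs_plus_duration_s=6.0, cs_minus_duration_s=7.0,
            us_duration_s=1.0, n_reinforced=8,
        ),
        "extinction": PhaseConfig(
            "extinction", n_cs_plus=10, n_cs_minus=10,
            cs_plus_duration_s=7.0, cs_minus_duration_s=7.0,
        ),
        "retention": PhaseConfig(
            "retention", n_cs_plus=10, n_cs_minus=10,
            cs_plus_duration_s=7.0, cs_minus_duration_s=7.0,
        ),
    }


def sample_iti(config: PhaseConfig, rng: np.random.Generator | int | None = None,
               size: Optional[int] = None) -> float | np.ndarray:
    """Draw inter-trial interval(s) from N(mean, sd) truncated to mean +/- 3 SD.

    Truncation is by resampling, so within the retained support the density is
    the untruncated Gaussian's.  Draws are guaranteed positive (an ITI mean
    closer than 3 SD to zero additionally rejects non-positive draws).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mean, sd = config.iti_mean_s, config.iti_sd_s
    n = 1 if size is None else int(size)
    if sd == 0:
        out = np.full(n, float(mean))
        return float(out[0]) if size is None else out
    lo, hi = mean - ITI_TRUNCATION_SDS * sd, mean + ITI_TRUNCATION_SDS * sd
    out = np.empty(n)
    filled = 0
    while filled < n:
        draws = rng.normal(mean, sd, size=max(n - filled, 16))
        ok = draws[(draws >= lo) & (draws <= hi) & (draws > 0)]
        take = min(ok.size, n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return float(out[0]) if size is None else out


def _max_run(types: Sequence[str]) -> int:
    best = run = 0
    prev = None
    for t in types:
        run = run + 1 if t == prev else 1
        prev = t
        best = max(best, run)
    return best


def _sample_order(config: PhaseConfig, rng: np.random.Generator) -> list[str]:
    """Uniform draw from CS+/CS- orderings obeying the run-length bound.

    Rejection sampling of uniform shuffles keeps the distribution uniform over
    the constraint-satisfying set; bounded attempts guard infeasible configs.
    """
    types = np.array(["CS+"] * config.n_cs_plus + ["CS-"] * config.n_cs_minus)
    if types.size == 0:
        raise ScheduleError("schedule has no CS trials")
    for _ in range(MAX_SHUFFLE_ATTEMPTS):
        order = rng.permutation(types)
        if _max_run(order) <= config.max_run_length:
            return list(order)
    raise ScheduleError(
        f"no ordering with max run {config.max_run_length} found for "
        f"{config.n_cs_plus} CS+ / {config.n_cs_minus} CS- in "
        f"{MAX_SHUFFLE_ATTEMPTS} attempts (infeasible constraint?)"
    )


def make_schedule(config: PhaseConfig,
                  rng_seed: np.random.Generator | int | None = None,
                  reinforced_positions: Optional[Sequence[int]] = None) -> TaskSchedule:
    """Build one phase's event schedule.

    CS order is a uniform draw over orderings with no run of identical types
    longer than ``config.max_run_length``.  In reinforced phases the
    ``config.n_reinforced`` reinforced CS+ trials are chosen uniformly at
    random unless ``reinforced_positions`` pins specific 1-based CS+ trial
    indices.  Each US starts exactly at its CS+ offset.  The first trial
    starts after one ITI draw.
    """
    seed = rng_seed if isinstance(rng_seed, (int, np.integer)) else None
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed

    order = _sample_order(config, rng)
    if reinforced_positions is not None:
        chosen = sorted(int(i) for i in reinforced_positions)
        if len(chosen) != config.n_reinforced or any(
                not 1 <= i <= config.n_cs_plus for i in chosen) or len(set(chosen)) != len(chosen):
            raise ScheduleError("reinforced_positions must be n_reinforced distinct CS+ indices")
    else:
        chosen = sorted(rng.choice(config.n_cs_plus, size=config.n_reinforced,
                                   replace=False) + 1) if config.n_reinforced else []
    reinforced_set = set(chosen)

    events: list[ScheduledEvent] = []
    t = float(sample_iti(config, rng))
    counts = {"CS+": 0, "CS-": 0}
    for trial_type in order:
        counts[trial_type] += 1
        idx = counts[trial_type]
        dur = config.cs_plus_duration_s if trial_type == "CS+" else config.cs_minus_duration_s
        reinforced = trial_type == "CS+" and idx in reinforced_set
        events.append(ScheduledEvent(round(t, 6), dur, trial_type, idx, reinforced))
        t += dur
        if reinforced:
            events.append(ScheduledEvent(round(t, 6), config.us_duration_s, "US", idx, True))
            t += config.us_duration_s
        t += float(sample_iti(config, rng))
    return TaskSchedule(config, tuple(events), seed=seed)


# ---------------------------------------------------------------------------
# Events file round-trip (tab-separated, BIDS-events-like)

_EVENTS_HEADER = ["onset", "duration", "trial_type", "trial_index", "reinforced"]


def write_events(schedule: TaskSchedule, path: str | Path) -> Path:
    """Write a schedule as a tab-separated events file (onsets to 3+ decimals)."""
    path = Path(path)
    lines = ["\t".join(_EVENTS_HEADER)]
    for e in schedule.events:
        lines.append("\t".join([
            f"{e.onset_s:.6f}", f"{e.duration_s:.6f}", e.trial_type,
            str(e.trial_index), str(int(e.reinforced)),
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_events(path: str | Path,
                phase_config: Optional[PhaseConfig] = None) -> TaskSchedule:
    """Parse an events file back into a TaskSchedule.

    Errors name the offending 1-based line.  If ``phase_config`` is omitted a
    minimal config is reconstructed from the events themselves (counts and
    durations; ITI parameters keep their defaults).
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != _EVENTS_HEADER:
        raise EventsParseError(f"{path}: line 1: expected header {'	'.join(_EVENTS_HEADER)!r}")
    events = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise EventsParseError(f"{path}: line {lineno}: expected 5 columns, got {len(parts)}")
        try:
            onset, dur = float(parts[0]), float(parts[1])
            trial_type = parts[2]
            idx = int(parts[3])
            reinforced = bool(int(parts[4]))
        except ValueError as exc:
            raise EventsParseError(f"{path}: line {lineno}: {exc}") from None
        if onset < 0:
            raise EventsParseError(f"{path}: line {lineno}: negative onset {onset}")
        if trial_type not in ("CS+", "CS-", "US"):
            raise EventsParseError(f"{path}: line {lineno}: unknown trial_type {trial_type!r}")
        events.append(ScheduledEvent(onset, dur, trial_type, idx, reinforced))
    if phase_config is None:
        phase_config = _infer_config(events)
    return TaskSchedule(phase_config, tuple(events))


def _infer_config(events: Sequence[ScheduledEvent]) -> PhaseConfig:
    plus = [e for e in events if e.trial_type == "CS+"]
    minus = [e for e in events if e.trial_type == "CS-"]
    us = [e for e in events if e.trial_type == "US"]
    return PhaseConfig(
        "acquisition" if us else "extinction",
        n_cs_plus=len(plus), n_cs_minus=len(minus),
        cs_plus_duration_s=plus[0].duration_s if plus else 7.0,
        cs_minus_duration_s=minus[0].duration_s if minus else 7.0,
        us_duration_s=us[0].duration_s if us else 0.0,
        n_reinforced=len(us),
    )


def validate_schedule(schedule: TaskSchedule) -> None:
    """Raise ScheduleError if the schedule violates the protocol invariants."""
    cfg = schedule.phase_config
    cs = schedule.cs_events()
    if sum(e.trial_type == "CS+" for e in cs) != cfg.n_cs_plus:
        raise ScheduleError("CS+ count mismatch")
    if sum(e.trial_type == "CS-" for e in cs) != cfg.n_cs_minus:
        raise ScheduleError("CS- count mismatch")
    if sum(e.reinforced for e in cs) != cfg.n_reinforced:
        raise ScheduleError("reinforced count mismatch")
    if _max_run([e.trial_type for e in cs]) > cfg.max_run_length:
        raise ScheduleError("run-length constraint violated")
    cs_by_key = {(e.trial_type, e.trial_index): e for e in cs}
    for u in schedule.us_events():
        parent = cs_by_key.get(("CS+", u.trial_index))
        if parent is None or abs(u.onset_s - parent.offset_s) > 1e-6:
            raise ScheduleError("US must start exactly at its CS+ offset")
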