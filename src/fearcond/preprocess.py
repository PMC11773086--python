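"""Skin-conductance preprocessing and trial scoring.

Pipeline, in fixed order: 10 ms median filter -> first-order Butterworth
band-pass 0.03-5 Hz (zero-phase) -> downsample to 100 Hz -> per-event
baseline-corrected peak (max over 1-5 s post onset minus mean over 0-1 s post
onset) -> amplitude rules (< 0.01 uS set to 0; > 5 uS set missing) -> square
root transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .physio import PhysioRecording
from .task_design import TaskSchedule

__all__ = [
    "PreprocessConfig", "TrialResponse",
    "median_filter", "bandpass", "downsample",
    "extract_peak", "apply_amplitude_rules", "sqrt_transform",
    "preprocess_recording", "score_phase", "qc_flags", "trials_to_frame",
]

MISSING_NONE = "none"
MISSING_CEILING = "ceiling"
MISSING_WINDOW = "window_out_of_range"


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering, windowing and amplitude-rule constants."""

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
    score_us_events: bool = False
    exclude_flagged: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("require 0 < band_low_hz < band_high_hz")
        if self.baseline_window_s[1] > self.peak_window_s[1]:
            raise ValueError("baseline window must precede the peak-window end")
        if not 0 <= self.floor_uS < self.ceiling_uS:
            raise ValueError("require 0 <= floor_uS < ceiling_uS")


@dataclass
class TrialResponse:
    """One scored trial.

    ``raw_peak_uS`` is the baseline-corrected window maximum before any rule
    (may be negative); ``scr_uS`` is the rule-applied amplitude (0, a value
    >= floor, or None when missing); ``scr_sqrt`` its square root.
    """

    subject_id: str
    phase: str
    trial_type: str
    trial_index: int
    raw_peak_uS: Optional[float]
    scr_uS: Optional[float]
    scr_sqrt: Optional[float]
    missing_reason: str = MISSING_NONE


# ---------------------------------------------------------------------------
# Signal stages

def median_filter(recording: PhysioRecording, window_s: float = 0.010) -> PhysioRecording:
    """Centered sliding median; window = round(window_s * rate) forced odd.

    Edges are handled by reflection.  A window that spans fewer than one
    sample leaves the signal unchanged.
    """
    if recording.n_samples == 0:
        raise ValueError("empty signal")
    w = int(round(window_s * recording.sampling_rate_hz))
    if w % 2 == 0:
        w += 1
    if w <= 1:
        return recording
    out = ndimage.median_filter(recording.samples, size=w, mode="reflect")
    return recording.with_samples(out)


def bandpass(recording: PhysioRecording, low_hz: float = 0.03, high_hz: float = 5.0,
             order: int = 1, zero_phase: bool = True) -> PhysioRecording:
    """Butterworth band-pass, applied forward-backward by default (zero phase).

    Zero-phase filtering keeps event-relative peak latencies in place; the
    effective magnitude response is then the squared single-pass response.
    """
    nyq = recording.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"band edges must satisfy 0 < {low_hz} < {high_hz} < Nyquist {nyq}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=recording.sampling_rate_hz, output="sos")
    if zero_phase:
        out = signal.sosfiltfilt(sos, recording.samples)
    else:
        out = signal.sosfilt(sos, recording.samples)
    return recording.with_samples(np.asarray(out))


def bandpass_gain(freq_hz: float, low_hz: float = 0.03, high_hz: float = 5.0,
                  order: int = 1, zero_phase: bool = True,
                  sampling_rate_hz: float = 1000.0) -> float:
    """Magnitude response of the band-pass stage at one frequency (for checks)."""
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=sampling_rate_hz, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=sampling_rate_hz)
    g = float(np.abs(h[0]))
    return g * g if zero_phase else g


def downsample(recording: PhysioRecording, target_rate_hz: float = 100.0) -> PhysioRecording:
    """Reduce the sampling rate.

    Integer rate ratios decimate by selection (every k-th sample, keeping the
    first); otherwise samples are linearly interpolated onto the target grid.
    Anti-aliasing is provided upstream by the 5 Hz band-pass edge.
    """
    rate = recording.sampling_rate_hz
    if target_rate_hz > rate:
        raise ValueError("upsampling requested")
    if target_rate_hz == rate:
        return recording
    ratio = rate / target_rate_hz
    if abs(ratio - round(ratio)) < 1e-9:
        out = recording.samples[:: int(round(ratio))]
    else:
        t_new = np.arange(int(np.floor(recording.duration_s * target_rate_hz))) / target_rate_hz
        t_old = np.arange(recording.n_samples) / rate
        out = np.interp(t_new, t_old, recording.samples)
    return recording.with_samples(out, rate=target_rate_hz)


# ---------------------------------------------------------------------------
# Trial scoring

def _window_indices(onset_s: float, window: tuple[float, float],
                    rate: float, start_time_s: float) -> tuple[int, int]:
    # onset mapped to the nearest sample at-or-after onset; closed-open window
    i_on = int(np.ceil((onset_s - start_time_s) * rate - 1e-9))
    return (i_on + int(round(window[0] * rate)), i_on + int(round(window[1] * rate)))


def extract_peak(recording: PhysioRecording, event_onset_s: float,
                 config: PreprocessConfig | None = None) -> Optional[float]:
    """Baseline-corrected peak: max over the peak window minus the mean over
    the baseline window, both measured from stimulus onset.

    Returns None when either window leaves the recording (missing,
    window_out_of_range).  The value may be negative; the amplitude rules
    handle that downstream.
    """
    config = config if config is not None else PreprocessConfig()
    rate = recording.sampling_rate_hz
    b0, b1 = _window_indices(event_onset_s, config.baseline_window_s, rate,
                             recording.start_time_s)
    p0, p1 = _window_indices(event_onset_s, config.peak_window_s, rate,
                             recording.start_time_s)
    n = recording.n_samples
    if b0 < 0 or p1 > n or b1 <= b0 or p1 <= p0:
        return None
    baseline = float(np.mean(recording.samples[b0:b1]))
    peak = float(np.max(recording.samples[p0:p1]))
    return peak - baseline


def apply_amplitude_rules(raw_peak_uS: Optional[float],
                          config: PreprocessConfig | None = None
                          ) -> tuple[Optional[float], str]:
    """Amplitude rules: < 0.01 uS (incl. negative) -> 0; > 5 uS -> missing.

    Returns (scr_uS or None, missing_reason).
    """
    config = config if config is not None else PreprocessConfig()
    if raw_peak_uS is None:
        return None, MISSING_WINDOW
    if not np.isfinite(raw_peak_uS):
        raise ValueError("raw peak must be finite or missing")
    if raw_peak_uS > config.ceiling_uS:
        return None, MISSING_CEILING
    if raw_peak_uS < config.floor_uS:
        return 0.0, MISSING_NONE
    return float(raw_peak_uS), MISSING_NONE


def sqrt_transform(scr_uS: Optional[float]) -> Optional[float]:
    """Square-root transform; 0 -> 0, missing propagates."""
    if scr_uS is None:
        return None
    if scr_uS < 0:
        raise ValueError("amplitude rules must run before the transform")
    return float(np.sqrt(scr_uS))


def preprocess_recording(recording: PhysioRecording,
                         config: PreprocessConfig | None = None) -> PhysioRecording:
    """Median filter -> band-pass -> downsample, in the pipeline's fixed order."""
    config = config if config is not None else PreprocessConfig()
    rec = median_filter(recording, config.median_window_s)
    rec = bandpass(rec, config.band_low_hz, config.band_high_hz,
                   config.filter_order, config.zero_phase)
    return downsample(rec, config.target_rate_hz)


def qc_flags(recording: PhysioRecording, flat_sd_uS: float = 1e-4,
             rail_fraction: float = 0.05) -> dict:
    """Automated stand-in for visual inspection of the raw recording.

    Flags flat-lining (near-zero variance), railing (a large fraction of
    samples pinned at the extremes) and gaps (long constant runs).
    """
    x = recording.samples
    sd = float(np.std(x))
    at_edge = float(np.mean((x == x.min()) | (x == x.max()))) if x.size else 0.0
    const = np.diff(x) == 0
    run, longest = 0, 0
    for c in const:
        run = run + 1 if c else 0
        longest = max(longest, run)
    gap_s = longest / recording.sampling_rate_hz
    flags = {
        "flatline": sd < flat_sd_uS,
        "railing": at_edge > rail_fraction,
        "gap": gap_s > 2.0,
    }
    return {"sd_uS": sd, "edge_fraction": at_edge, "longest_constant_run_s": gap_s,
            "flags": flags, "any": any(flags.values())}


def score_phase(recording: PhysioRecording, schedule: TaskSchedule,
                config: PreprocessConfig | None = None) -> list[TrialResponse]:
    """Run the full pipeline and score every CS event (plus US if configured).

    Events whose scoring window leaves the recording yield missing trials;
    the pipeline continues.  QC flags are computed on the raw recording; when
    ``config.exclude_flagged`` is set a flagged recording returns all-missing
    trials.
    """
    config = config if config is not None else PreprocessConfig()
    qc = qc_flags(recording)
    processed = preprocess_recording(recording, config)
    events = list(schedule.cs_events())
    if config.score_us_events:
        events += list(schedule.us_events())
    out = []
    for e in events:
        if config.exclude_flagged and qc["any"]:
            raw, scr, reason = None, None, MISSING_WINDOW
        else:
            raw = extract_peak(processed, e.onset_s, config)
            scr, reason = apply_amplitude_rules(raw, config)
        out.append(TrialResponse(
            subject_id=recording.subject_id, phase=schedule.phase_name,
            trial_type=e.trial_type, trial_index=e.trial_index,
            raw_peak_uS=raw, scr_uS=scr, scr_sqrt=sqrt_transform(scr),
            missing_reason=reason))
    return out


def trials_to_frame(trials: Sequence[TrialResponse],
                    metadata: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Long-format trial table; optionally merged with per-subject metadata
    (group label and covariates, constant within subject)."""
    df = pd.DataFrame([{
        "subject": t.subject_id, "phase": t.phase, "cs": t.trial_type,
        "trial": t.trial_index, "raw_peak_uS": t.raw_peak_uS,
        "scr_uS": t.scr_uS, "scr_sqrt": t.scr_sqrt,
        "missing_reason": t.missing_reason,
    } for t in trials])
    if metadata is not None:
        df = df.merge(metadata, on="subject", how="left", validate="many_to_one")
    return df
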