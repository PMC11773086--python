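"""Framewise displacement and motion censoring.

FD for volume t is the absolute sum of the six realignment-parameter
differences from volume t-1, with rotations (radians) converted to arc length
on a 50 mm sphere.  Volumes with FD strictly above 0.9 mm are censored, one
indicator regressor per censored volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MotionTrace", "CensorResult", "compute_fd", "censor",
           "read_realignment_params", "write_censor_outputs"]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.9


@dataclass(frozen=True)
class MotionTrace:
    """Six realignment parameters per volume: translations mm, rotations rad."""

    params: np.ndarray  # shape (n_volumes, 6)

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.params, dtype=float))
        object.__setattr__(self, "params", p)
        if p.shape[1] != 6:
            raise ValueError("expected 6 columns (3 translations, 3 rotations)")
        if p.shape[0] < 1:
            raise ValueError("need at least one volume")
        if not np.all(np.isfinite(p)):
            raise ValueError("realignment parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass(frozen=True)
class CensorResult:
    fd_mm: np.ndarray
    mask: np.ndarray          # True where censored
    threshold_mm: float

    @property
    def n_censored(self) -> int:
        return int(self.mask.sum())

    def regressors(self) -> np.ndarray:
        """One indicator column per censored volume (n_volumes x n_censored)."""
        idx = np.nonzero(self.mask)[0]
        out = np.zeros((self.mask.size, idx.size))
        out[idx, np.arange(idx.size)] = 1.0
        return out


def compute_fd(trace: MotionTrace | np.ndarray,
               head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement in mm; the first volume is defined as 0."""
    if not isinstance(trace, MotionTrace):
        trace = MotionTrace(trace)
    diffs = np.abs(np.diff(trace.params, axis=0))
    fd = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def censor(fd_mm: np.ndarray,
           threshold_mm: float = DEFAULT_FD_THRESHOLD_MM) -> CensorResult:
    """Censor volumes with FD strictly greater than the threshold."""
    fd = np.asarray(fd_mm, dtype=float)
    if np.any(fd < 0):
        raise ValueError("FD must be non-negative")
    return CensorResult(fd, fd > threshold_mm, threshold_mm)


def read_realignment_params(path: str | Path) -> MotionTrace:
    """Read a six-column whitespace-delimited realignment file (SPM rp_*.txt)."""
    return MotionTrace(np.loadtxt(path, ndmin=2))


def write_censor_outputs(result: CensorResult, out_prefix: str | Path) -> dict:
    """Write the censor mask TSV and a summary JSON; returns the summary."""
    prefix = Path(out_prefix)
    pd.DataFrame({
        "volume": np.arange(result.mask.size),
        "fd_mm": result.fd_mm,
        "censored": result.mask.astype(int),
    }).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6f")
    summary = {
        "n_volumes": int(result.mask.size),
        "n_censored": result.n_censored,
        "threshold_mm": result.threshold_mm,
        "mean_fd_mm": float(np.mean(result.fd_mm)),
        "max_fd_mm": float(np.max(result.fd_mm)),
    }
    prefix.with_suffix(".json").write_text(json.dumps(summary, indent=1) + "\n")
    return summary
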