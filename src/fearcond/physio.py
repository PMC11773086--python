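"""Uniformly sampled skin-conductance recordings and their on-disk format.

Recordings are stored the way BIDS stores peripheral physiology: a gzipped
tab-separated sample file (one column, microsiemens) next to a JSON sidecar
holding ``SamplingFrequency`` (Hz), ``StartTime`` (s) and ``Columns``.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = ["PhysioRecording", "write_physio", "read_physio"]


@dataclass(frozen=True)
class PhysioRecording:
    """Skin-conductance time series in microsiemens at a uniform rate."""

    samples: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0
    subject_id: str = ""
    phase_name: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray, rate: float | None = None) -> "PhysioRecording":
        return replace(self, samples=samples,
                       sampling_rate_hz=self.sampling_rate_hz if rate is None else rate)


def write_physio(recording: PhysioRecording, path: str | Path) -> Path:
    """Write ``<stem>_physio.tsv.gz`` plus ``<stem>_physio.json`` sidecar.

    ``path`` may be either of the pair or the bare stem.  mtime=0 in the gzip
    header keeps byte-identical output for identical input.
    """
    stem = _stem(path)
    tsv = stem.with_name(stem.name + "_physio.tsv.gz")
    body = "\n".join(f"{v:.9g}" for v in recording.samples) + "\n"
    with gzip.GzipFile(tsv, "wb", mtime=0) as fh:
        fh.write(body.encode())
    sidecar = {
        "SamplingFrequency": recording.sampling_rate_hz,
        "StartTime": recording.start_time_s,
        "Columns": ["skin_conductance"],
        "Units": "microsiemens",
    }
    stem.with_name(stem.name + "_physio.json").write_text(
        json.dumps(sidecar, indent=1) + "\n", encoding="utf-8")
    return tsv


def read_physio(path: str | Path, subject_id: str = "", phase_name: str = "") -> PhysioRecording:
    stem = _stem(path)
    tsv = stem.with_name(stem.name + "_physio.tsv.gz")
    meta = json.loads(stem.with_name(stem.name + "_physio.json").read_text(encoding="utf-8"))
    with gzip.open(tsv, "rt") as fh:
        samples = np.loadtxt(fh, ndmin=1)
    return PhysioRecording(samples, float(meta["SamplingFrequency"]),
                           float(meta.get("StartTime", 0.0)),
                           subject_id=subject_id, phase_name=phase_name)


def _stem(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in ("_physio.tsv.gz", "_physio.json"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)])
    return p
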