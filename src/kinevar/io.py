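"""Reading and writing kinematic trials, results tables and run configuration.

Trial files are plain CSV/TSV, one row per sample, with columns ``x,y,z``
(positions in cm: anteroposterior, mediolateral, vertical) and an optional
leading time column ``t`` in seconds from which the sampling rate is
inferred.  A column-mapping dictionary adapts files whose headers differ.
The reader validates and rejects; it never imputes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .metrics import MetricParams

__all__ = [
    "CONDITIONS",
    "STATIC_CONDITIONS",
    "DYNAMIC_CONDITIONS",
    "SITES",
    "KinematicTrial",
    "RunConfig",
    "TrialParseError",
    "SamplingRateError",
    "read_trial",
    "write_trial",
    "write_results_table",
]

CONDITIONS = ("HoS", "ARelax", "A90", "UpDown", "Circle")
STATIC_CONDITIONS = ("HoS", "ARelax", "A90")
DYNAMIC_CONDITIONS = ("UpDown", "Circle")
SITES = ("Hand", "Shoulder", "Hip")


class TrialParseError(ValueError):
    """A trial file could not be parsed (malformed or non-numeric rows)."""


class SamplingRateError(ValueError):
    """The time column is inconsistent or contradicts the declared rate."""


@dataclass(frozen=True)
class KinematicTrial:
    """One sensor's 3D position trace for a single trial.

    Coordinates are in cm: ``x`` anteroposterior, ``y`` mediolateral,
    ``z`` vertical.  ``fs`` is the sampling rate in Hz.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float
    participant_id: str = "P0"
    condition: str = "HoS"
    site: str = "Hand"
    trial_index: int = 1

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = self.x.size
        if n < 2 or self.y.size != n or self.z.size != n:
            raise ValueError(
                "coordinate streams must have equal length >= 2 "
                f"(got {self.x.size}, {self.y.size}, {self.z.size})"
            )
        for name in ("x", "y", "z"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"coordinate stream {name!r} contains non-finite values")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be a positive integer")

    @property
    def n_samples(self) -> int:
        return int(self.x.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def coordinates(self) -> np.ndarray:
        """(N, 3) array of positions."""
        return np.column_stack([self.x, self.y, self.z])

    def with_coordinates(self, coords: np.ndarray, fs: float | None = None) -> "KinematicTrial":
        return replace(
            self,
            x=coords[:, 0],
            y=coords[:, 1],
            z=coords[:, 2],
            fs=self.fs if fs is None else fs,
        )

    def provenance(self) -> dict:
        return {
            "participant": self.participant_id,
            "condition": self.condition,
            "site": self.site,
            "trial": self.trial_index,
        }


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration of the analysis pipeline.

    Defaults match the study protocol: 240 Hz acquisition down-sampled to
    100 Hz, a 1 Hz zero-phase high-pass, and a 2000-sample analysis window
    (20 s at 100 Hz).
    """

    source_fs: float = 240.0
    target_fs: float = 100.0
    highpass_cutoff: float = 1.0
    target_length: int = 2000
    metric_params: MetricParams = field(default_factory=MetricParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_fs > self.source_fs:
            raise ValueError(
                f"target_fs ({self.target_fs}) must not exceed source_fs ({self.source_fs})"
            )
        if self.target_length < 100:
            raise ValueError("target_length must be >= 100 (DFA needs N/10 >= 10)")
        if not 0 < self.highpass_cutoff < self.target_fs / 2:
            raise ValueError("highpass_cutoff must lie in (0, target Nyquist)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        mp = d.pop("metric_params", None)
        params = MetricParams(**mp) if isinstance(mp, Mapping) else (mp or MetricParams())
        return cls(metric_params=params, **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load configuration from YAML or JSON."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return {
            "source_fs": self.source_fs,
            "target_fs": self.target_fs,
            "highpass_cutoff": self.highpass_cutoff,
            "target_length": self.target_length,
            "metric_params": vars(self.metric_params).copy(),
            "seed": self.seed,
        }


def _separator_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_trial(
    path: str | Path,
    *,
    participant_id: str = "P0",
    condition: str = "HoS",
    site: str = "Hand",
    trial_index: int = 1,
    fs: float | None = None,
    column_map: Mapping[str, str] | None = None,
) -> KinematicTrial:
    """Read one trial from a CSV/TSV file with columns (t,)x,y,z.

    The sampling rate is taken from ``fs`` or inferred from the ``t``
    column as the reciprocal median inter-sample interval; when both are
    available they must agree within 1%.  Rows with non-numeric
    coordinates raise :class:`TrialParseError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _separator_for(path)
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    except Exception as err:  # malformed CSV structure
        raise TrialParseError(f"{path}: {err}") from err
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = {"x", "y", "z"} - set(frame.columns)
    if missing:
        raise TrialParseError(f"{path}: missing required columns {sorted(missing)}")

    cols = ["x", "y", "z"] + (["t"] if "t" in frame.columns else [])
    numeric = frame[cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | frame[cols].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise TrialParseError(f"{path}: non-numeric or missing value at line {line}")

    inferred_fs = None
    if "t" in numeric.columns:
        t = numeric["t"].to_numpy()
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise SamplingRateError(f"{path}: time column is not strictly increasing")
        median_dt = float(np.median(dt))
        if np.max(np.abs(dt - median_dt)) > 0.01 * median_dt:
            raise SamplingRateError(
                f"{path}: inter-sample intervals vary by more than 1% "
                f"(median dt={median_dt:.6g} s)"
            )
        inferred_fs = 1.0 / median_dt
    if fs is None:
        if inferred_fs is None:
            raise SamplingRateError(f"{path}: no time column and no sampling rate supplied")
        fs = inferred_fs
    elif inferred_fs is not None and abs(inferred_fs - fs) > 0.01 * fs:
        raise SamplingRateError(
            f"{path}: declared fs={fs} Hz disagrees with time column "
            f"({inferred_fs:.4g} Hz) by more than 1%"
        )

    return KinematicTrial(
        x=numeric["x"].to_numpy(),
        y=numeric["y"].to_numpy(),
        z=numeric["z"].to_numpy(),
        fs=float(fs),
        participant_id=participant_id,
        condition=condition,
        site=site,
        trial_index=trial_index,
    )


def write_trial(trial: KinematicTrial, path: str | Path) -> Path:
    """Write a trial as t,x,y,z CSV at full float precision (so staged
    and in-memory pipelines agree exactly)."""
    path = Path(path)
    t = np.arange(trial.n_samples) / trial.fs
    frame = pd.DataFrame({"t": t, "x": trial.x, "y": trial.y, "z": trial.z})
    frame.to_csv(path, index=False, float_format="%.17g", sep=_separator_for(path))
    return path


def write_results_table(summary: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-condition summary (mean and SD across participants).

    ``summary`` is tidy: one row per (condition, site, metric) with columns
    ``mean``, ``sd`` and ``n_participants``.
    """
    if summary is None or len(summary) == 0:
        raise ValueError("cannot write an empty results summary")
    required = {"condition", "site", "metric", "mean", "sd"}
    missing = required - set(summary.columns)
    if missing:
        raise ValueError(f"summary is missing columns {sorted(missing)}")
    path = Path(path)
    summary.to_csv(path, index=False, float_format="%.10g")
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
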