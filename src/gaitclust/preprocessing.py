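"""Raw stance-phase waveforms to the standardized cohort feature matrix.

Each participant contributes five joint-angle channels over stance phase.
Every raw series is time-normalized to 101 samples (0-100 % stance), step
repetitions are averaged pointwise, each channel mean pattern is
z-standardized (mean 0, SD 1; population SD convention), and the five
standardized channels are concatenated in the fixed channel order into a
505-feature participant vector. Vectors stack into the cohort matrix with
participants as rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNELS, N_SAMPLES, VECTOR_LENGTH, check_channel

__all__ = [
    "ParticipantWaveforms",
    "ParticipantVector",
    "FeatureMatrix",
    "ConstantChannelError",
    "time_normalize",
    "mean_pattern",
    "standardize_channel",
    "build_vector",
    "build_matrix",
    "participant_to_vector",
    "participants_to_matrix",
    "read_cohort_csv",
]


class ConstantChannelError(ValueError):
    """A channel with zero variance cannot be standardized."""


@dataclass
class ParticipantWaveforms:
    """Raw stance-phase angle series for one participant.

    ``steps`` maps each of the five channels to 1-5 raw series (degrees),
    each spanning heel strike to toe-off with at least 2 samples.
    """

    participant_id: str
    steps: dict[str, list[np.ndarray]]

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.steps]
        if missing:
            raise ValueError(
                f"participant {self.participant_id!r} missing channels {missing}"
            )
        for channel, series_list in self.steps.items():
            check_channel(channel)
            if not series_list:
                raise ValueError(
                    f"participant {self.participant_id!r} channel {channel!r} has no steps"
                )
            clean = []
            for s in series_list:
                a = np.asarray(s, dtype=float)
                if a.ndim != 1 or a.size < 2:
                    raise ValueError(
                        f"series in {channel!r} of {self.participant_id!r} needs >= 2 samples"
                    )
                if not np.all(np.isfinite(a)):
                    raise ValueError(
                        f"non-finite values in {channel!r} of {self.participant_id!r}"
                    )
                clean.append(a)
            self.steps[channel] = clean


@dataclass(frozen=True)
class ParticipantVector:
    """The standardized, concatenated 505-feature vector for one participant."""

    participant_id: str
    values: np.ndarray
    channel_order: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (VECTOR_LENGTH,):
            raise ValueError(f"participant vector must have {VECTOR_LENGTH} values")
        object.__setattr__(self, "values", v)

    def channel_block(self, channel: str) -> np.ndarray:
        i = self.channel_order.index(check_channel(channel))
        return self.values[i * N_SAMPLES:(i + 1) * N_SAMPLES]


@dataclass
class FeatureMatrix:
    """Cohort matrix: participants as rows, 505 standardized features."""

    values: np.ndarray
    participant_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != VECTOR_LENGTH:
            raise ValueError(f"feature matrix must have {VECTOR_LENGTH} columns")
        if v.shape[0] != len(self.participant_ids):
            raise ValueError("row count must match participant_ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite entries")
        self.values = v

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f{i:03d}" for i in range(VECTOR_LENGTH)]
        return pd.DataFrame(self.values, index=pd.Index(self.participant_ids,
                                                        name="participant_id"), columns=cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="participant_id")
        return cls(df.to_numpy(), [str(i) for i in df.index])


def time_normalize(series: Sequence[float] | np.ndarray, n_points: int = N_SAMPLES) -> np.ndarray:
    """Resample a stance-phase series onto a uniform grid of ``n_points``.

    Linear interpolation on a 0-100 % grid; the first and last samples are
    preserved exactly, so affine series are resampled without error.
    """
    a = np.asarray(series, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    old = np.linspace(0.0, 1.0, a.size)
    new = np.linspace(0.0, 1.0, n_points)
    return np.interp(new, old, a)


def mean_pattern(steps: Iterable[np.ndarray]) -> np.ndarray:
    """Pointwise mean across time-normalized step repetitions."""
    steps = [np.asarray(s, dtype=float) for s in steps]
    if not steps:
        raise ValueError("mean_pattern requires at least one step")
    if any(s.shape != (steps[0].size,) for s in steps):
        raise ValueError("all steps must share the same length")
    return np.mean(steps, axis=0)


def standardize_channel(series: np.ndarray, participant_id: str = "?",
                        channel: str = "?") -> np.ndarray:
    """z-standardize one channel mean pattern (population SD convention)."""
    a = np.asarray(series, dtype=float)
    sd = a.std()  # divide by N
    if sd == 0:
        raise ConstantChannelError(
            f"constant series (SD=0) for participant {participant_id!r}, channel {channel!r}"
        )
    return (a - a.mean()) / sd


def build_vector(standardized: Mapping[str, np.ndarray],
                 participant_id: str = "?") -> ParticipantVector:
    """Concatenate standardized channels in the fixed channel order."""
    missing = [c for c in CHANNELS if c not in standardized]
    if missing:
        raise ValueError(f"missing channels {missing} for participant {participant_id!r}")
    values = np.concatenate([np.asarray(standardized[c], dtype=float) for c in CHANNELS])
    return ParticipantVector(participant_id, values)


def build_matrix(vectors: Sequence[ParticipantVector]) -> FeatureMatrix:
    """Stack participant vectors into the cohort matrix, rows in input order."""
    ids = [v.participant_id for v in vectors]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate participant_ids {dupes}")
    return FeatureMatrix(np.vstack([v.values for v in vectors]), ids)


def participant_to_vector(p: ParticipantWaveforms) -> ParticipantVector:
    """Full per-participant pipeline: time-normalize, average steps,
    standardize, concatenate."""
    standardized = {}
    for channel in CHANNELS:
        normalized = [time_normalize(s) for s in p.steps[channel]]
        mean = mean_pattern(normalized)
        standardized[channel] = standardize_channel(mean, p.participant_id, channel)
    return build_vector(standardized, p.participant_id)


def participants_to_matrix(participants: Sequence[ParticipantWaveforms]) -> FeatureMatrix:
    return build_matrix([participant_to_vector(p) for p in participants])


def mean_patterns_deg(p: ParticipantWaveforms) -> dict[str, np.ndarray]:
    """Per-channel 101-sample mean patterns in degrees (no standardization);
    the degree-scale input for reference comparisons."""
    out = {}
    for channel in CHANNELS:
        normalized = [time_normalize(s) for s in p.steps[channel]]
        out[channel] = mean_pattern(normalized)
    return out


def read_cohort_csv(path: str | Path) -> list[ParticipantWaveforms]:
    """Read a long-format cohort CSV
    (participant_id,channel,sample_index,value_deg[,step])."""
    df = pd.read_csv(path)
    required = {"participant_id", "channel", "sample_index", "value_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns {sorted(missing)}")
    has_step = "step" in df.columns
    participants = []
    for pid, pdf in df.groupby("participant_id", sort=False):
        steps: dict[str, list[np.ndarray]] = {}
        for channel, cdf in pdf.groupby("channel", sort=False):
            check_channel(str(channel))
            if has_step:
                series = [
                    sdf.sort_values("sample_index")["value_deg"].to_numpy()
                    for _, sdf in cdf.groupby("step", sort=True)
                ]
            else:
                series = [cdf.sort_values("sample_index")["value_deg"].to_numpy()]
            steps[str(channel)] = series
        participants.append(ParticipantWaveforms(str(pid), steps))
    return participants
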