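"""Core containers: multichannel recordings and windowed segment series.

A :class:`Recording` holds a few seconds to minutes of prefrontal EEG
(typically Fp1/Fp2, optionally two periocular EOG reference channels) as a
dense ``(n_channels, n_samples)`` array in microvolts, with a sampling rate
and labeled, half-open artifact annotations in seconds.

A :class:`SegmentSeries` is the product of sliding-window segmentation: an
ordered stack of fixed-length windows plus a validity mask that downstream
feature extraction respects (artifact-contaminated windows are masked out,
never deleted, so segment indices stay aligned with time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

EEG = "EEG"
EOG = "EOG"


@dataclass
class Annotation:
    """A labeled half-open time interval ``[onset, end)`` in seconds."""

    onset: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset < self.end):
            raise ValueError(f"invalid annotation interval [{self.onset}, {self.end})")


@dataclass
class Recording:
    """Multichannel biosignal time series in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sample values in microvolts.
    rate : float
        Sampling rate in Hz, strictly positive.
    channels : list of str
        Channel labels, one per row of ``data`` (e.g. ``["Fp1", "Fp2"]``).
    roles : list of str
        ``"EEG"`` or ``"EOG"`` per channel.
    annotations : list of Annotation
        Labeled intervals (seconds), each within ``[0, duration)``.
    """

    data: np.ndarray
    rate: float
    channels: list[str]
    roles: list[str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for {self.data.shape[0]} data rows"
            )
        if len(self.roles) != len(self.channels):
            raise ValueError("one role per channel required")
        for role in self.roles:
            if role not in (EEG, EOG):
                raise ValueError(f"unknown channel role {role!r}")
        for ann in self.annotations:
            if ann.end > self.duration:
                raise ValueError(
                    f"annotation [{ann.onset}, {ann.end}) outside recording of "
                    f"duration {self.duration:.3f} s"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        """Return the sample vector of one channel by label."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: {self.channels}"
            ) from None
        return self.data[idx]

    def labels_with_role(self, role: str) -> list[str]:
        return [c for c, r in zip(self.channels, self.roles) if r == role]

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channels=list(self.channels),
            roles=list(self.roles),
            annotations=list(self.annotations),
        )


@dataclass
class SegmentSeries:
    """Ordered fixed-length windows over a recording, with a validity mask.

    ``segments[k]`` holds the samples of window ``k`` for every channel,
    shape ``(n_segments, n_channels, samples_per_segment)``; ``starts[k]``
    is its onset in seconds. Windows are half-open ``[start, start+window_s)``.
    """

    segments: np.ndarray
    starts: np.ndarray
    window_s: float
    overlap_frac: float
    rate: float
    channels: list[str]
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float64)
        self.starts = np.asarray(self.starts, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.segments.ndim != 3:
            raise ValueError("segments must be (n_segments, n_channels, n_samples)")
        if len(self.valid) != len(self.segments) or len(self.starts) != len(self.segments):
            raise ValueError("starts, valid and segments must have equal length")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_segments(self) -> np.ndarray:
        """Samples of the valid windows only, shape (n_valid, n_channels, n)."""
        return self.segments[self.valid]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: {self.channels}"
            ) from None


def write_recording_csv(rec: Recording, path) -> None:
    """Write a recording as a delimited table: time_s plus one column per channel.

    Channel roles are encoded in the header as ``label:role`` so the file
    round-trips without a sidecar.
    """
    cols = {"time_s": np.arange(rec.n_samples) / rec.rate}
    for label, role, row in zip(rec.channels, rec.roles, rec.data):
        cols[f"{label}:{role}"] = row
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(path) -> Recording:
    """Read a recording written by :func:`write_recording_csv`.

    Plain headers without a ``:role`` suffix are accepted; channels whose
    label starts with ``EOG`` are then treated as EOG references, everything
    else as EEG.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples to infer the rate")
    rate = (len(t) - 1) / float(t[-1] - t[0])
    if abs(rate - round(rate)) < 1e-3:  # undo time-column rounding for integer rates
        rate = float(round(rate))
    channels, roles, rows = [], [], []
    for col in df.columns:
        if col == "time_s":
            continue
        if ":" in col:
            label, role = col.rsplit(":", 1)
        else:
            label, role = col, (EOG if col.upper().startswith("EOG") else EEG)
        channels.append(label)
        roles.append(role)
        rows.append(df[col].to_numpy(dtype=np.float64))
    return Recording(np.vstack(rows), rate, channels, roles)
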