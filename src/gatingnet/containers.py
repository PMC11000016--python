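"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Switching x TrialType cells of the reference-back task, in canonical order.
CONDITIONS = (
    "switch-reference",
    "nonswitch-reference",
    "switch-comparison",
    "nonswitch-comparison",
)

#: Frequency bands (Hz, inclusive edges) used throughout the analysis.
BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (13.0, 30.0)}


@dataclass
class EpochArray:
    """Epoched multichannel time series.

    data has shape (n_trials, n_channels, n_times).  ``times_s`` is the common
    time axis relative to stimulus onset; ``onset_sample`` indexes t = 0.
    """

    data: np.ndarray
    times_s: np.ndarray
    sfreq_hz: float
    channel_names: list[str]
    condition_labels: np.ndarray | None = None  # one label per trial
    channel_positions: np.ndarray | None = None  # (n_channels, 3), optional

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if self.data.shape[2] != self.times_s.size:
            raise ValueError("time axis length mismatch")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel count mismatch")
        if self.condition_labels is not None:
            self.condition_labels = np.asarray(self.condition_labels)
            if self.condition_labels.size != self.data.shape[0]:
                raise ValueError("one condition label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def onset_sample(self) -> int:
        return int(np.argmin(np.abs(self.times_s)))

    def select(self, condition: str) -> "EpochArray":
        """Sub-array with only the trials of one condition."""
        if self.condition_labels is None:
            raise ValueError("no condition labels attached")
        mask = self.condition_labels == condition
        return EpochArray(
            self.data[mask],
            self.times_s,
            self.sfreq_hz,
            self.channel_names,
            self.condition_labels[mask],
            self.channel_positions,
        )


@dataclass
class Leadfield:
    """Forward model: unit activity at each voxel mapped to sensor amplitudes."""

    gain: np.ndarray  # (n_voxels, n_channels)
    voxel_positions: np.ndarray  # (n_voxels, 3)
    channel_names: list[str]
    channel_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.voxel_positions = np.asarray(self.voxel_positions, dtype=float)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("leadfield gain must be finite")
        if np.any(np.all(self.gain == 0.0, axis=1)):
            raise ValueError("leadfield contains an all-zero voxel row")
        if self.gain.shape[0] != self.voxel_positions.shape[0]:
            raise ValueError("voxel count mismatch")
        if self.gain.shape[1] != len(self.channel_names):
            raise ValueError("channel count mismatch")

    @property
    def n_voxels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[1]


@dataclass
class SourceSignal:
    """Per-trial, baseline-subtracted, cluster-averaged source time series."""

    data: np.ndarray  # (n_trials, n_times)
    times_s: np.ndarray
    cluster_id: int
    band: str | None = None
    process: str | None = None  # "opening" | "closing"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.shape[1] != self.times_s.size:
            raise ValueError("time axis length mismatch")
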