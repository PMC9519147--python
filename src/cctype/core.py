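"""Domain containers shared across the pipeline.

Conventions (fixed once, used everywhere):

* All event times are in seconds, float64, relative to recording start.
* Epoch windows are half-open ``[start, end)``.
* Voltages are in microvolts; firing rates in Hz; normalized responses in
  percent change (``100 * (x / baseline - 1)``).
* Task conditions appear in the fixed order :data:`CONDITIONS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Fixed condition order: two executive/attentional tasks, two episodic
#: (self-projection) tasks, and fixation rest.
CONDITIONS: tuple[str, ...] = ("search", "add", "past", "future", "rest")

TRIAL_COLUMNS = ("trial_id", "run_id", "condition", "cue_onset", "task_onset", "task_offset")


class InvalidConfigError(ValueError):
    """A structural/timing parameter is out of its valid range."""


class TrialTable:
    """Per-trial condition and event times; the temporal skeleton of a session.

    Wraps a :class:`pandas.DataFrame` with columns
    ``trial_id, run_id, condition, cue_onset, task_onset, task_offset``
    (times in seconds from recording start). Trials are sorted by cue onset
    and must not overlap.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidConfigError(f"trial table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.df
        if not df["cue_onset"].is_monotonic_increasing:
            raise InvalidConfigError("trials must be sorted by cue_onset")
        bad = set(df["condition"]) - set(CONDITIONS)
        if bad:
            raise InvalidConfigError(f"unknown conditions: {sorted(bad)}")
        if not ((df["task_onset"] > df["cue_onset"]) & (df["task_offset"] > df["task_onset"])).all():
            raise InvalidConfigError("require cue_onset < task_onset < task_offset")
        if (df["task_offset"].to_numpy()[:-1] > df["cue_onset"].to_numpy()[1:]).any():
            raise InvalidConfigError("overlapping trials")
        dur = (df["task_offset"] - df["task_onset"]).to_numpy()
        rest = (df["condition"] == "rest").to_numpy()
        if rest.any() and not np.allclose(dur[rest], 4.0, atol=1e-9):
            raise InvalidConfigError("rest trials must last exactly 4 s")
        if (~rest).any() and not ((dur[~rest] > 0) & (dur[~rest] <= 10.0 + 1e-9)).all():
            raise InvalidConfigError("non-rest trial durations must lie in (0, 10] s")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, TrialTable) and self.df.equals(other.df)

    @property
    def conditions(self) -> np.ndarray:
        return self.df["condition"].to_numpy()

    @property
    def cue_onsets(self) -> np.ndarray:
        return self.df["cue_onset"].to_numpy(float)

    @property
    def task_onsets(self) -> np.ndarray:
        return self.df["task_onset"].to_numpy(float)

    @property
    def task_offsets(self) -> np.ndarray:
        return self.df["task_offset"].to_numpy(float)

    def end_time(self, pad: float = 2.0) -> float:
        """Session duration implied by the table: last offset plus padding."""
        return float(self.df["task_offset"].iloc[-1]) + pad


@dataclass
class ContinuousRecording:
    """Multichannel sampled voltage with a probe map.

    ``data`` is channels x samples, in microvolts. ``probe_of_channel`` maps a
    channel id to its probe id; within a probe, contacts are ordered as their
    channel ids appear in ``channel_ids`` (tip to tail).
    """

    data: np.ndarray
    fs: float
    channel_ids: list
    probe_of_channel: dict
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.fs <= 0:
            raise InvalidConfigError("fs must be positive")
        if self.data.shape[0] != len(self.channel_ids):
            raise InvalidConfigError("channel_ids length must match data rows")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy_with(self, **kw) -> "ContinuousRecording":
        return replace(self, **kw)


@dataclass
class SpectralEnvelope:
    """Non-negative amplitude envelope, channels x freqs x times."""

    amplitude: np.ndarray
    freqs: np.ndarray
    fs: float
    channel_ids: list
    t0: float = 0.0
    #: per-frequency half-width (seconds) of the wavelet edge region at the
    #: recording boundaries, where circular-convolution artifacts can leak in
    edge_sec: Optional[np.ndarray] = None

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.amplitude.shape[-1]) / self.fs


@dataclass
class EpochedResponse:
    """Trials x times matrix aligned to cue onset; values in percent change."""

    data: np.ndarray                 # (n_trials, n_times)
    times: np.ndarray                # seconds relative to cue onset
    conditions: np.ndarray           # condition per trial
    trial_ids: np.ndarray
    label: object = None             # channel id or unit id
    valid: Optional[np.ndarray] = None   # per-trial validity (zero baseline etc.)
    baseline_hz: Optional[float] = None  # for rate responses: pooled pre-cue rate
    low_baseline: bool = False

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.ones(self.data.shape[0], dtype=bool)


@dataclass
class EpochedSpectra:
    """Per-frequency percent-change epochs: channels x trials x freqs x times."""

    data: np.ndarray
    freqs: np.ndarray
    times: np.ndarray                # relative to cue onset
    conditions: np.ndarray
    trial_ids: np.ndarray
    channel_ids: list
    valid: np.ndarray                # (n_channels, n_trials)


@dataclass
class SpikeTrain:
    """Sorted spike times for one unit."""

    unit_id: object
    spike_times: np.ndarray          # seconds, strictly ascending
    probe_id: object = None
    waveforms: Optional[np.ndarray] = None   # snippets x samples, microvolts
    isolation: str = "unknown"       # single | multi | unknown

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be ascending")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def mean_rate(self, duration: float) -> float:
        return self.n_spikes / duration


@dataclass
class RateTrace:
    """Gaussian-kernel instantaneous firing rate on a uniform grid."""

    unit_id: object
    times: np.ndarray
    rate: np.ndarray                 # Hz
    kernel_sd: float

    @property
    def fs(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])


@dataclass
class UnitProfile:
    """Condition-dependent modulation profile of one functional unit type.

    The firing rate is ``basal_rate * gain(condition, t)`` where the gain
    ramps exponentially (time constant ``ramp_tau``) from 1 toward the
    condition's multiplicative gain, starting ``onset_lag`` seconds after cue
    onset, and returns to 1 outside the trial.
    """

    unit_type: int
    condition_gain: Mapping[str, float]
    onset_lag: float = 0.0
    ramp_tau: float = 0.3
    basal_scale: float = 1.0
    basal_rate: Optional[float] = None

    def __post_init__(self):
        if any(g < 0 for g in self.condition_gain.values()):
            raise InvalidConfigError("condition gains must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually did, so recovery can be scored."""

    unit_types: dict = field(default_factory=dict)        # unit_id -> type label
    artifact_flags: dict = field(default_factory=dict)    # unit_id -> clean|outlier|duplicate-of:<id>
    channel_gains: dict = field(default_factory=dict)     # channel -> condition -> gain
    basal_rates: dict = field(default_factory=dict)       # unit_id -> calibrated basal rate (Hz)
    spike_times: dict = field(default_factory=dict)       # channel -> planted times (microwire render)


@dataclass
class ClusterResult:
    """Flat clusters from an agglomerative merge tree cut."""

    unit_ids: list
    labels: np.ndarray               # cluster id per unit, 1..n_clusters, ordered by size desc
    merges: np.ndarray               # scipy linkage matrix
    cut_height: float
    n_clusters: int

    def label_of(self, unit_id) -> int:
        return int(self.labels[self.unit_ids.index(unit_id)])

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


@dataclass
class StabilityResult:
    """Leave-one-out reclustering consistency."""

    n_iterations: int
    n_identical: int
    per_iteration: list              # list of (left_out_unit, identical: bool)

    @property
    def rate(self) -> float:
        return self.n_identical / self.n_iterations
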