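"""Pipeline configuration: nested dataclasses with strict JSON round-trip.

Unknown keys are rejected; every default is visible in the field
definitions.  ``config_hash`` fingerprints the canonical JSON form so
outputs from different configurations are never silently mixed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .core import InvalidConfigError


@dataclass
class TaskConfig:
    n_per_condition: int = 18
    cue_period: float = 1.0
    iti: float = 1.0
    mean_duration: float = 7.27
    duration_sd: float = 1.8
    max_duration: float = 10.0
    min_duration: float = 1.0
    rest_duration: float = 4.0
    response_period: float = 0.0
    start_pad: float = 2.0
    end_pad: float = 2.0


@dataclass
class LfpGenConfig:
    fs: float = 2000.0
    n_probes: int = 1
    contacts_per_probe: int = 4
    background_rms: float = 10.0
    band_rms: float = 40.0
    line_freq: float = 60.0
    line_amp_frac: float = 0.1
    condition_gains: dict = field(
        default_factory=lambda: {"search": 1.5, "add": 1.5, "past": 1.1, "future": 1.1, "rest": 1.0}
    )


@dataclass
class UnitsConfig:
    mix: dict = field(default_factory=lambda: {1: 13, 2: 34, 3: 26, 4: 18})
    rate_distribution_mean: float = 1.7
    basal_sigma: float = 0.4
    noise_cv: float = 1.0
    grid_fs: float = 1000.0
    n_probes: int = 6


@dataclass
class ArtifactConfig:
    n_outliers: int = 3
    n_duplicates: int = 1
    outlier_sd_above: float = 30.0
    duplicate_jitter: float = 2e-4


@dataclass
class LfpAnalysisConfig:
    notch_base: float = 60.0
    notch_harmonics: int = 3
    target_fs: float = 1000.0
    morlet_lo: float = 70.0   # pipeline decomposes only the analyzed band;
    morlet_hi: float = 150.0  # morlet_amplitude itself defaults to 2-200 Hz
    morlet_step: float = 1.0
    morlet_cycles: float = 7.0
    baseline: tuple = (-0.5, 0.0)
    epoch_span: tuple = (-0.5, 4.0)
    early_window: tuple = (0.0, 1.0)
    late_window: tuple = (2.0, 3.0)


@dataclass
class TypingConfig:
    kernel_sd: float = 0.010
    feature_fs: float = 1000.0
    baseline: tuple = (-0.5, 0.0)
    feature_span: tuple = (0.0, 3.0)
    baseline_floor: float = 0.1
    outlier_sd: float = 5.0
    duplicate_tolerance: float = 1e-3
    duplicate_fraction: float = 0.95
    cutoff_fraction: float = 0.9
    linkage: str = "average"


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "cctype_out"
    task: TaskConfig = field(default_factory=TaskConfig)
    lfp_gen: LfpGenConfig = field(default_factory=LfpGenConfig)
    units: UnitsConfig = field(default_factory=UnitsConfig)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    lfp: LfpAnalysisConfig = field(default_factory=LfpAnalysisConfig)
    typing: TypingConfig = field(default_factory=TypingConfig)

    def to_dict(self) -> dict:
        return _asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _from_dict(cls, d, "config")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def _from_dict(cls, d: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise InvalidConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, f in fields.items():
        if name not in d:
            continue
        val = d[name]
        if dataclasses.is_dataclass(f.type) or (isinstance(f.type, type) and dataclasses.is_dataclass(f.type)):
            kwargs[name] = _from_dict(f.type, val, f"{path}.{name}")
        elif name == "mix":
            kwargs[name] = {int(k): int(v) for k, v in val.items()}
        elif isinstance(val, list):
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    # nested dataclasses whose f.type is a string annotation: resolve by default value
    for name, f in fields.items():
        if name in kwargs and isinstance(kwargs[name], dict) and f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
            proto = f.default_factory()  # type: ignore[misc]
            if dataclasses.is_dataclass(proto):
                kwargs[name] = _from_dict(type(proto), kwargs[name], f"{path}.{name}")
    return cls(**kwargs)


def config_hash(config: PipelineConfig) -> str:
    """Fingerprint of the scientific configuration (output location excluded)."""
    d = config.to_dict()
    d.pop("out_dir", None)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
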