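"""Run configuration: every analysis threshold in one serializable place.

All defaults are the study's printed values (fixation radius 100 px, 250 ms
closure padding, 150 ms Hann smoothing, rejection at >50% missing / >=10%
samples beyond 3 SD, kernel time constant 150 ms, 100 ms minimum dilation,
lambda = 6 velocity threshold, 5–100 ms duration, <10 ms disparity, >50 ms
refractory, 1,000 bootstrap iterations at 95% consistency, 500 latency
iterations).  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synth import SynthParams


@dataclass
class PipelineConfig:
    eye_preference: str = "left"          # fall back to the other eye per block
    fixation_radius_px: float = 100.0
    closure_pad_ms: float = 250.0
    smooth_window_ms: float = 150.0
    missing_max_fraction: float = 0.5
    outlier_fraction: float = 0.10
    outlier_sd: float = 3.0
    outlier_before_normalization: bool = True
    alpha_ms: float = 150.0
    min_dilation_ms: float = 100.0
    # PDR change-locked baseline; shorter than the pupil's 0.5 s window
    pdr_baseline_s: tuple = (-0.15, 0.0)
    lam: float = 6.0
    ms_min_duration_ms: float = 5.0
    ms_max_duration_ms: float = 100.0
    ms_max_disparity_ms: float = 10.0
    ms_refractory_ms: float = 50.0

    def __post_init__(self):
        self.pdr_baseline_s = tuple(self.pdr_baseline_s)


@dataclass
class StatsConfig:
    n_boot: int = 1000
    consistency: float = 0.95
    n_latency_iter: int = 500
    noise_floor_iter: int = 100
    noise_floor_quantile: float = 0.95
    decimate: int = 10                   # stats run on every k-th sample
    corr_method: str = "pearson"


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 36
    n_blocks: int = 8
    trials_per_condition: int = 4
    decoys_per_condition: int = 1
    out_dir: str = "results/run"
    keep_traces: bool = False
    run_latency_analysis: bool = True
    synth: SynthParams = field(default_factory=SynthParams)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_to_plain(asdict(self)), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        obj = yaml.safe_load(text)
        return cls.from_dict(obj)

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        kwargs = dict(obj)
        kwargs["synth"] = SynthParams(**obj.get("synth", {}))
        kwargs["pipeline"] = PipelineConfig(**obj.get("pipeline", {}))
        kwargs["stats"] = StatsConfig(**obj.get("stats", {}))
        return cls(**kwargs)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj
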