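"""Study configuration: one object holding every tunable of the pipeline.

Serialisable to/from YAML with per-module sections; unknown keys are
rejected so typos in config files fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .emg import EMGOnsetParams
from .features import SlopeWindows
from .speller import CONDITIONS, TimingSpec
from .synth import MRCPTemplateParams, NoiseParams

__all__ = ["StudyConfig"]

PROCESSING_PATHS = ("cz", "laplacian")


@dataclass(frozen=True)
class StatsOptions:
    alpha: float = 0.05
    n_permutations: int = 1000
    repeated_measures: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass(frozen=True)
class FilterOptions:
    apply_notch: bool = True
    apply_bandpass: bool = True
    notch_band: tuple[float, float] = (48.0, 52.0)
    bandpass_band: tuple[float, float] = (0.05, 3.0)
    order: int = 2
    zero_phase: bool = True


@dataclass(frozen=True)
class StudyConfig:
    """Everything a full synthetic study run depends on (except the seed)."""

    n_subjects: int = 13
    conditions: tuple[str, ...] = CONDITIONS
    success_probs: dict[str, float] = field(
        default_factory=lambda: {"control": 0.67, "phrase": 0.67, "random": 0.63}
    )
    rate: float = 1200.0
    timing: TimingSpec = field(default_factory=TimingSpec)
    template: MRCPTemplateParams = field(default_factory=MRCPTemplateParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    filters: FilterOptions = field(default_factory=FilterOptions)
    emg: EMGOnsetParams = field(default_factory=EMGOnsetParams)
    slope_windows: SlopeWindows = field(default_factory=SlopeWindows)
    epoch_window: tuple[float, float] = (-4.0, 5.0)
    aligned_window: tuple[float, float] = (-2.0, 1.5)
    pn_search_halfwidth_s: float = 2.0
    alignment: str = "pn"
    processing: tuple[str, ...] = PROCESSING_PATHS
    stats: StatsOptions = field(default_factory=StatsOptions)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.alignment not in ("cue", "emg", "pn"):
            raise ValueError("alignment must be cue, emg or pn")
        for p in self.processing:
            if p not in PROCESSING_PATHS:
                raise ValueError(f"unknown processing path {p!r}")

    # -- noise-off variant used for ground-truth recovery runs -------------
    def noise_free(self) -> "StudyConfig":
        """All-signal variant: EEG noise and jitters off, unsmoothed
        template, every trial planted, filters bypassed (nothing to remove)."""
        return replace(
            self,
            noise=NoiseParams.noiseless(),
            template=replace(self.template, smoothing_s=0.0),
            success_probs={c: 1.0 for c in self.conditions},
            filters=replace(self.filters, apply_notch=False, apply_bandpass=False),
        )

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        known = {f.name: f for f in fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        nested = {
            "timing": TimingSpec,
            "template": MRCPTemplateParams,
            "noise": NoiseParams,
            "filters": FilterOptions,
            "emg": EMGOnsetParams,
            "slope_windows": SlopeWindows,
            "stats": StatsOptions,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested and isinstance(value, dict):
                value = nested[key](**{k: _tup(v) for k, v in value.items()})
            elif key in ("conditions", "processing"):
                value = tuple(value)
            elif key in ("epoch_window", "aligned_window"):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


def _tup(v):
    return tuple(v) if isinstance(v, list) else v


def _plain(obj):
    """Make asdict() output YAML-safe (tuples -> lists)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
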