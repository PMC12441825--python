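"""Pipeline configuration: every tunable in one serializable place.

Defaults follow the study protocol the pipeline implements: 256 Hz EEG
epochs over [-200, 500] ms band-limited to 0.1-45 Hz, pupil epochs over
[-500, 1500] ms down-sampled to 125 Hz, a 100 ms blink buffer, a 2.5 MAD
outlier threshold, 10-fold cross-validation, and 10,000 permutations at a
cluster-forming alpha of .05.

The pupil passband default (15.6-500 Hz) reproduces the protocol as printed
but is physiologically implausible for pupil dynamics (< 4 Hz) — using it
triggers a loud warning, and any cutoff at or above Nyquist is dropped.
Synthetic closed-loop analyses here use a 4 Hz low-pass instead.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "DEFAULT_ROI"]

#: All occipital + parietal labels of the 64-channel 10-20 montage.
DEFAULT_ROI = (
    "O1", "Oz", "O2", "PO7", "PO3", "POz", "PO4", "PO8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
)


@dataclass
class PipelineConfig:
    # EEG
    eeg_sampling_rate_hz: float = 256.0
    eeg_epoch_window_ms: tuple = (-200.0, 500.0)
    eeg_highpass_hz: float = 0.1
    eeg_lowpass_hz: float = 45.0
    eeg_filter_order: int = 4
    roi: tuple = DEFAULT_ROI
    # pupil
    pupil_sampling_rate_hz: float = 1000.0
    pupil_epoch_window_ms: tuple = (-500.0, 1500.0)
    pupil_downsample_hz: float = 125.0
    pupil_highpass_hz: float | None = 15.6
    pupil_lowpass_hz: float | None = 500.0
    pupil_filter_order: int = 1
    blink_buffer_ms: float = 100.0
    mad_threshold: float = 2.5
    max_missing_fraction: float = 1.0
    # analysis
    n_folds: int = 10
    n_permutations: int = 10_000
    cluster_alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
        }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})
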