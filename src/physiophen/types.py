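"""Shared container types for multichannel physiological waveforms.

A :class:`WaveformRecord` holds the raw or processed channels of one
patient's monitoring segment (ECG, PPG, respiratory impedance, plus any
derived channels such as VPG/APG/EDR).  A :class:`FiducialSet` holds the
landmark indices produced by delineation, and :class:`QualityReport`
summarises per-channel signal quality after preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Channel",
    "WaveformRecord",
    "QualityReport",
    "PulseFiducials",
    "FiducialSet",
]


@dataclass
class Channel:
    """One uniformly sampled signal with its sampling rate and quality mask."""

    samples: np.ndarray
    fs: float
    units: str = "a.u."
    quality_mask: Optional[np.ndarray] = None  # True = usable sample

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.quality_mask is None:
            self.quality_mask = np.ones(self.samples.shape, dtype=bool)
        else:
            self.quality_mask = np.asarray(self.quality_mask, dtype=bool)
            if self.quality_mask.shape != self.samples.shape:
                raise ValueError("quality mask length must match sample length")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class WaveformRecord:
    """Multichannel waveform segment for a single patient."""

    channels: dict[str, Channel]
    start_time: float = 0.0
    patient_id: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> Channel:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def copy(self) -> "WaveformRecord":
        return WaveformRecord(
            channels={
                k: Channel(c.samples.copy(), c.fs, c.units, c.quality_mask.copy())
                for k, c in self.channels.items()
            },
            start_time=self.start_time,
            patient_id=self.patient_id,
            meta=dict(self.meta),
        )


@dataclass
class ChannelQuality:
    flatline_fraction: float
    clipping_fraction: float
    outlier_fraction: float
    usable_fraction: float


@dataclass
class QualityReport:
    """Per-channel quality fractions produced by preprocessing."""

    channels: dict[str, ChannelQuality]
    low_quality: bool = False

    def usable_fraction(self, name: str) -> float:
        return self.channels[name].usable_fraction


@dataclass
class PulseFiducials:
    """Landmark indices of one PPG pulse (indices into the PPG channel)."""

    onset: int
    systolic: int
    offset: int
    notch: Optional[int] = None
    diastolic: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.onset < self.systolic < self.offset):
            raise ValueError("PPG fiducials must be ordered onset < systolic < offset")


@dataclass
class FiducialSet:
    """Landmarks detected across all channels of one record."""

    r_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    ppg_pulses: list[PulseFiducials] = field(default_factory=list)
    resp_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    resp_troughs: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    resp_transitions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
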