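"""Domain types shared by every pipeline stage.

The abdominal coordinate frame used throughout is right-handed, in cm:
x points from the maternal right to the maternal left, y from caudal to
cranial, z from posterior to anterior. All signal amplitudes are in µV;
dipole moments are in mV (an arbitrary but consistent source scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MATERNAL = "maternal"
FETUS_A = "fetusA"
FETUS_B = "fetusB"
SOURCE_LABELS = (MATERNAL, FETUS_A, FETUS_B)

HR_BOUNDS_BPM = (30.0, 300.0)


class TwinsNotSeparableError(RuntimeError):
    """Raised when the two fetal beat trains cannot be resolved.

    Carries a ``diagnostics`` dict describing why (e.g. collinear mixing
    vectors, a single rate cluster).
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class MaternalRhythmNotFoundError(RuntimeError):
    """Raised when no channel exhibits a plausible maternal rhythm."""


@dataclass
class Recording:
    """Uniformly sampled multichannel signal.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    sampling_rate : float
        Hz.
    channel_labels : list of str
    start_time : float
        Seconds; offset of sample 0.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def with_samples(self, samples: np.ndarray, channel_labels: list[str] | None = None) -> "Recording":
        """Copy carrying new samples but the same timing metadata."""
        return Recording(
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate,
            channel_labels=list(channel_labels) if channel_labels is not None else list(self.channel_labels),
            start_time=self.start_time,
        )


@dataclass
class BeatAnnotation:
    """Ordered R-peak sample indices for one source.

    Ground-truth and detected beats share this type; ``confidence`` is
    ``"low"`` when a detector could not establish a plausible rhythm.
    """

    label: str
    r_samples: np.ndarray
    confidence: str = "ok"

    def __post_init__(self):
        self.r_samples = np.asarray(self.r_samples, dtype=int)
        if self.r_samples.ndim != 1:
            raise ValueError("r_samples must be 1-D")
        if self.r_samples.size > 1 and np.any(np.diff(self.r_samples) <= 0):
            raise ValueError("r_samples must be strictly increasing")

    def __len__(self) -> int:
        return self.r_samples.size

    def times(self, sampling_rate: float) -> np.ndarray:
        return self.r_samples / sampling_rate


@dataclass
class ElectrodePatchGeometry:
    """Electrode positions plus the bipolar derivation matrix.

    ``derivation_matrix`` maps the vector of electrode potentials (one
    entry per physical electrode) to the derived bipolar channels. Each
    row sums to zero and the ground electrode contributes to no channel.
    """

    electrode_positions: np.ndarray  # (n_electrodes, 3) cm
    ground_index: int
    reference_index: int
    derivation_matrix: np.ndarray  # (n_channels, n_electrodes)

    def __post_init__(self):
        self.electrode_positions = np.asarray(self.electrode_positions, dtype=float)
        self.derivation_matrix = np.asarray(self.derivation_matrix, dtype=float)
        n_e = self.electrode_positions.shape[0]
        if self.electrode_positions.shape != (n_e, 3):
            raise ValueError("electrode_positions must be (n_electrodes, 3)")
        if self.derivation_matrix.shape[1] != n_e:
            raise ValueError("derivation_matrix columns must match electrode count")
        row_sums = self.derivation_matrix.sum(axis=1)
        if not np.allclose(row_sums, 0.0, atol=1e-9):
            raise ValueError("every derivation_matrix row must sum to zero (bipolar)")
        if not np.allclose(self.derivation_matrix[:, self.ground_index], 0.0):
            raise ValueError("ground electrode column must be all zero")

    @property
    def n_electrodes(self) -> int:
        return self.electrode_positions.shape[0]

    @property
    def n_channels(self) -> int:
        return self.derivation_matrix.shape[0]


@dataclass
class WaveParams:
    """One ECG wave (P, Q, R, S or T) of the Gaussian dipole model."""

    amplitude: np.ndarray  # (3,) mV per heart-frame axis
    center: float  # radians of cardiac phase, R at 0
    width: float  # radians

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != (3,):
            raise ValueError("amplitude must be a 3-vector")
        if self.width <= 0:
            raise ValueError(f"wave width must be positive, got {self.width}")


@dataclass
class DipoleSource:
    """A cardiac current-dipole source with its own beat train."""

    label: str
    position: np.ndarray  # (3,) cm
    orientation: np.ndarray  # (3, 3) rotation heart frame -> abdominal frame
    waveform_params: dict[str, WaveParams]
    mean_hr: float  # bpm
    sd_hr: float  # bpm

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be 3x3")
        if not np.allclose(self.orientation @ self.orientation.T, np.eye(3), atol=1e-8):
            raise ValueError("orientation must be orthonormal")
        if not np.isclose(np.linalg.det(self.orientation), 1.0, atol=1e-8):
            raise ValueError("orientation must be a proper rotation (det +1)")
        lo, hi = HR_BOUNDS_BPM
        if not lo < self.mean_hr < hi:
            raise ValueError(f"mean_hr must be in ({lo}, {hi}) bpm, got {self.mean_hr}")
        if self.sd_hr < 0:
            raise ValueError("sd_hr must be non-negative")


@dataclass
class NoiseParams:
    """Additive interference levels (standard deviations / amplitudes in µV)."""

    baseline_amplitude_uv: float = 30.0
    baseline_corner_hz: float = 0.7
    powerline_amplitude_uv: float = 20.0
    powerline_freq_hz: float = 50.0
    broadband_sd_uv: float = 5.0


@dataclass
class Scenario:
    """Full description of a simulated abdominal recording."""

    geometry: ElectrodePatchGeometry
    sources: Sequence[DipoleSource]
    duration: float  # s
    sampling_rate: float = 500.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.sampling_rate <= 2 * self.noise.powerline_freq_hz:
            raise ValueError("sampling_rate must exceed twice the powerline frequency")
        labels = [s.label for s in self.sources]
        if labels.count(MATERNAL) != 1:
            raise ValueError("scenario requires exactly one maternal source")
        n_fetal = sum(1 for l in labels if l in (FETUS_A, FETUS_B))
        if n_fetal > 2 or n_fetal + 1 != len(labels):
            raise ValueError("scenario allows 0-2 fetal sources and no other labels")

    def fetal_sources(self) -> list[DipoleSource]:
        return [s for s in self.sources if s.label != MATERNAL]

    def maternal_source(self) -> DipoleSource:
        return next(s for s in self.sources if s.label == MATERNAL)
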