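"""Synthetic abdominal recordings with known ground truth.

The generator mixes one maternal and up to two fetal cardiac
current-dipole sources into six bipolar abdominal channels through an
infinite-homogeneous-medium lead field, then adds baseline wander,
powerline interference and broadband noise. Every stochastic step is
seeded, and the clean per-source channel signals are returned alongside
the mixture so downstream stages can be scored against ground truth.

Model summary
-------------
Each source emits a rotating dipole moment m(θ) built as a sum of
Gaussians over cardiac phase θ (one Gaussian per P/Q/R/S/T wave and
dipole axis, R centred at θ = 0). Beat times follow a Gaussian
inter-beat-interval process. The potential of a dipole m at a point r
away is φ = k · (m · r̂) / |r|², so amplitude falls with squared
distance and a dipole pointing at an electrode deflects it positively.
Bipolar channels are formed by the patch's derivation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import (
    FETUS_A,
    FETUS_B,
    HR_BOUNDS_BPM,
    MATERNAL,
    BeatAnnotation,
    DipoleSource,
    ElectrodePatchGeometry,
    NoiseParams,
    Recording,
    Scenario,
    WaveParams,
)

# Lead-field gain: µV of electrode potential per (mV dipole) / cm².
# Chosen once so that the default maternal source (~25 cm from the
# patch) projects an abdominal QRS of a few hundred µV, matching
# routine abdominal recordings.
LEAD_FIELD_GAIN = 2.0e4

# Minimal admissible source-electrode separation (cm); closer is
# treated as singular geometry.
MIN_SOURCE_DISTANCE_CM = 1.0


# ---------------------------------------------------------------------------
# Electrode patch geometry
# ---------------------------------------------------------------------------

def default_geometry() -> ElectrodePatchGeometry:
    """Eight-electrode two-ring abdominal patch.

    Six measurement electrodes plus one reference (all channels are
    measured against it) and one ground. Electrodes 3/4/5 form the
    lower row right/midline/left so that a fetus lying on one side
    projects most strongly onto the channel above it. Coordinates are
    an approximation of a commercial patch; override with measured
    positions when available.
    """
    positions = np.array(
        [
            [-5.0, 12.0, 9.0],   # 1: upper right
            [5.0, 12.0, 9.0],    # 2: upper left
            [-8.0, 2.0, 8.0],    # 3: lower right
            [0.0, 0.0, 11.0],    # 4: lower midline
            [8.0, 2.0, 8.0],     # 5: lower left
            [0.0, 18.0, 8.0],    # 6: cranial midline
            [0.0, 7.0, 11.0],    # 7: reference (patch centre)
            [-10.0, 16.0, 6.0],  # 8: ground
        ]
    )
    reference_index = 6
    ground_index = 7
    derivation = np.zeros((6, 8))
    for ch in range(6):
        derivation[ch, ch] = 1.0
        derivation[ch, reference_index] = -1.0
    return ElectrodePatchGeometry(
        electrode_positions=positions,
        ground_index=ground_index,
        reference_index=reference_index,
        derivation_matrix=derivation,
    )


# ---------------------------------------------------------------------------
# Waveform and orientation defaults
# ---------------------------------------------------------------------------

def heart_waveform(scale: float = 1.0) -> dict[str, WaveParams]:
    """Canonical P-QRS-T Gaussian parameter set, in the heart frame.

    The heart frame's first axis is the electrical long axis (dominant
    R direction); the second and third axes carry the smaller loop
    components. ``scale`` multiplies every amplitude (mV).
    """
    # The QRS loop is dominated by the long axis; its third-axis
    # component is kept small so that flipping presentation (a 180°
    # rotation about the transverse axis) reverses the dominant QRS
    # axis almost exactly, as a normal heart axis implies.
    base = {
        "P": WaveParams(np.array([0.08, 0.02, 0.01]), -np.pi / 3, 0.25),
        "Q": WaveParams(np.array([-0.10, -0.02, 0.0]), -np.pi / 12, 0.10),
        "R": WaveParams(np.array([1.00, 0.12, 0.03]), 0.0, 0.10),
        "S": WaveParams(np.array([-0.25, -0.05, 0.0]), np.pi / 12, 0.10),
        "T": WaveParams(np.array([0.30, 0.05, 0.02]), np.pi / 2, 0.40),
    }
    return {
        name: WaveParams(w.amplitude * scale, w.center, w.width)
        for name, w in base.items()
    }


def _rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def fetal_orientation(presentation: str, axial_angle: float = 0.0) -> np.ndarray:
    """Rotation mapping the fetal heart frame into the abdominal frame.

    The heart's long axis points toward the apex, i.e. caudally within
    the fetal body. A cephalic (head-down) fetus therefore projects its
    long axis cranially in the maternal frame (+y); breech is the same
    fetus rotated 180° about the maternal transverse (x) axis, so the
    long axis points caudally (-y). ``axial_angle`` adds a rotation
    about the maternal y axis (the fetus facing left/right/front).
    """
    # Columns are the abdominal-frame images of the heart axes.
    cephalic = np.array(
        [
            [0.0, 0.0, 1.0],
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
        ]
    )
    if presentation == "cephalic":
        base = cephalic
    elif presentation == "breech":
        base = _rot_x(np.pi) @ cephalic
    else:
        raise ValueError(f"unknown presentation {presentation!r}")
    return _rot_y(axial_angle) @ base


def maternal_orientation() -> np.ndarray:
    """Maternal heart long axis points caudally and slightly left."""
    return _rot_x(np.pi) @ fetal_orientation("cephalic") @ _rot_x(0.0)


# ---------------------------------------------------------------------------
# RR-interval series
# ---------------------------------------------------------------------------

def generate_rr_series(
    mean_hr: float,
    sd_hr: float,
    duration: float,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Beat times (s) in [0, duration) with Gaussian inter-beat intervals.

    Intervals are drawn i.i.d. from N(60/mean_hr, sd_rr²) with
    sd_rr = sd_hr · 60 / mean_hr², then truncated to the physiological
    band (30–300 bpm). The first beat falls half an interval after the
    recording start, so no complex is clipped at the edge.
    """
    lo, hi = HR_BOUNDS_BPM
    if not lo < mean_hr < hi:
        raise ValueError(f"mean_hr must be in ({lo}, {hi}) bpm, got {mean_hr}")
    if sd_hr < 0:
        raise ValueError(f"sd_hr must be non-negative, got {sd_hr}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_rr = 60.0 / mean_hr
    sd_rr = sd_hr * 60.0 / mean_hr**2
    n_max = int(np.ceil(duration / max(mean_rr - 4 * sd_rr, 60.0 / hi))) + 2
    rr = rng.normal(mean_rr, sd_rr, size=n_max) if sd_rr > 0 else np.full(n_max, mean_rr)
    rr = np.clip(rr, 60.0 / hi, 60.0 / lo)
    beats = np.cumsum(rr) - rr[0] / 2.0
    return beats[beats < duration]


def cardiac_phase(beat_times: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Wrapped cardiac phase in [-π, π) with R peaks at phase 0.

    Phase advances by 2π per beat, linearly between consecutive beats;
    before the first and after the last beat the edge interval is
    extrapolated.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2:
        raise ValueError("need at least two beats to define a phase")
    idx = np.interp(t, beat_times, np.arange(beat_times.size))
    # linear extrapolation beyond the ends using the edge RR intervals
    rr0 = beat_times[1] - beat_times[0]
    rr1 = beat_times[-1] - beat_times[-2]
    left = t < beat_times[0]
    right = t > beat_times[-1]
    idx = np.where(left, (t - beat_times[0]) / rr0, idx)
    idx = np.where(right, beat_times.size - 1 + (t - beat_times[-1]) / rr1, idx)
    phase = 2 * np.pi * idx
    return np.mod(phase + np.pi, 2 * np.pi) - np.pi


def dipole_waveform(
    waveform_params: dict[str, WaveParams], phase: np.ndarray | float
) -> np.ndarray:
    """Dipole moment (mV) at the given cardiac phase(s).

    Sum over waves of amplitude · exp(-(Δφ)²/(2 width²)) per axis,
    where Δφ is the wrapped phase distance to the wave centre. Returns
    shape (3,) for scalar phase, else (len(phase), 3).
    """
    phase_arr = np.atleast_1d(np.asarray(phase, dtype=float))
    out = np.zeros((phase_arr.size, 3))
    for wave in waveform_params.values():
        if wave.width <= 0:
            raise ValueError("wave width must be positive")
        d = np.mod(phase_arr - wave.center + np.pi, 2 * np.pi) - np.pi
        out += np.exp(-(d**2) / (2 * wave.width**2))[:, None] * wave.amplitude
    return out[0] if np.isscalar(phase) or np.ndim(phase) == 0 else out


# ---------------------------------------------------------------------------
# Lead field
# ---------------------------------------------------------------------------

def lead_field(
    source_position: np.ndarray,
    orientation: np.ndarray,
    geometry: ElectrodePatchGeometry,
    gain: float = LEAD_FIELD_GAIN,
) -> np.ndarray:
    """Channels × 3 matrix mapping a heart-frame dipole moment to µV.

    Infinite-homogeneous-medium model: the potential at electrode e is
    gain · (m_world · r̂ₑ) / |rₑ|² with rₑ the source→electrode vector
    and m_world = orientation @ m_heart. Bipolar channels follow from
    the derivation matrix.
    """
    pos = np.asarray(source_position, dtype=float)
    r = geometry.electrode_positions - pos[None, :]  # (n_e, 3)
    dist = np.linalg.norm(r, axis=1)
    if np.any(dist < MIN_SOURCE_DISTANCE_CM):
        raise ValueError("source position coincides with an electrode (singular geometry)")
    electrode_rows = gain * r / dist[:, None] ** 3  # r̂ / r² per row
    return geometry.derivation_matrix @ electrode_rows @ np.asarray(orientation, dtype=float)


# ---------------------------------------------------------------------------
# Scenario assembly and simulation
# ---------------------------------------------------------------------------

def default_twin_scenario(
    duration: float = 600.0,
    sampling_rate: float = 500.0,
    seed: int = 0,
    noise: NoiseParams | None = None,
    fetal_scale: float = 0.15,
    maternal_scale: float = 10.0,
    fetus_a_orientation: np.ndarray | None = None,
    fetus_b_orientation: np.ndarray | None = None,
) -> Scenario:
    """Default study conditions: one maternal + two fetal sources.

    Fetus A lies on the maternal right in cephalic presentation at
    140 bpm; fetus B on the left in breech at 155 bpm (distinct rates
    keep the beat trains asynchronous). Amplitudes put the abdominal
    fetal QRS near one tenth of the maternal QRS.
    """
    geometry = default_geometry()
    sources = [
        DipoleSource(
            label=MATERNAL,
            position=np.array([-2.0, 30.0, 4.0]),
            orientation=maternal_orientation(),
            waveform_params=heart_waveform(maternal_scale),
            mean_hr=85.0,
            sd_hr=3.0,
        ),
        DipoleSource(
            label=FETUS_A,
            position=np.array([-5.0, 0.0, 5.0]),
            orientation=(
                fetus_a_orientation
                if fetus_a_orientation is not None
                else fetal_orientation("cephalic")
            ),
            waveform_params=heart_waveform(fetal_scale),
            mean_hr=140.0,
            sd_hr=4.0,
        ),
        DipoleSource(
            label=FETUS_B,
            position=np.array([5.0, 2.0, 5.0]),
            orientation=(
                fetus_b_orientation
                if fetus_b_orientation is not None
                else fetal_orientation("breech")
            ),
            waveform_params=heart_waveform(fetal_scale),
            mean_hr=155.0,
            sd_hr=4.0,
        ),
    ]
    return Scenario(
        geometry=geometry,
        sources=sources,
        duration=duration,
        sampling_rate=sampling_rate,
        noise=noise if noise is not None else NoiseParams(),
        seed=seed,
    )


def single_fetus_scenario(
    duration: float = 60.0,
    seed: int = 0,
    noise: NoiseParams | None = None,
    presentation: str = "cephalic",
    side: str = "right",
    fetal_scale: float = 0.15,
    orientation: np.ndarray | None = None,
) -> Scenario:
    """One maternal + one fetal source (fetus A)."""
    base = default_twin_scenario(duration=duration, seed=seed, noise=noise, fetal_scale=fetal_scale)
    x = -5.0 if side == "right" else 5.0
    fetus = DipoleSource(
        label=FETUS_A,
        position=np.array([x, 0.0, 5.0]),
        orientation=orientation if orientation is not None else fetal_orientation(presentation),
        waveform_params=heart_waveform(fetal_scale),
        mean_hr=140.0,
        sd_hr=4.0,
    )
    return Scenario(
        geometry=base.geometry,
        sources=[base.maternal_source(), fetus],
        duration=duration,
        sampling_rate=base.sampling_rate,
        noise=noise if noise is not None else NoiseParams(),
        seed=seed,
    )


@dataclass
class SimulationResult:
    """Mixed recording plus the ground truth that produced it."""

    recording: Recording
    annotations: list[BeatAnnotation]
    clean: dict[str, Recording]  # per-source noise-free channel signals
    noise: Recording  # summed noise terms (baseline + powerline + broadband)
    scenario: Scenario

    def annotation(self, label: str) -> BeatAnnotation:
        return next(a for a in self.annotations if a.label == label)


def _baseline_wander(
    rng: np.random.Generator, n_channels: int, n: int, fs: float, params: NoiseParams
) -> np.ndarray:
    if params.baseline_amplitude_uv <= 0:
        return np.zeros((n_channels, n))
    raw = rng.standard_normal((n_channels, n))
    corner = min(params.baseline_corner_hz, 0.45 * fs)
    sos = sps.butter(2, corner, btype="low", fs=fs, output="sos")
    wander = sps.sosfiltfilt(sos, raw, axis=1)
    std = wander.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return wander / std * params.baseline_amplitude_uv


def simulate_recording(scenario: Scenario) -> SimulationResult:
    """Render a scenario into a noisy 6-channel abdominal recording.

    Returns the mixture, per-source ground-truth beat annotations and
    the clean per-source channel signals; the mixture equals the sum of
    the clean components plus the returned noise, exactly.
    """
    fs = scenario.sampling_rate
    n = int(round(scenario.duration * fs))
    t = np.arange(n) / fs
    n_ch = scenario.geometry.n_channels

    ss = np.random.SeedSequence(scenario.seed)
    children = ss.spawn(len(scenario.sources) + 3)
    source_rngs = [np.random.default_rng(c) for c in children[: len(scenario.sources)]]
    rng_base, rng_pl, rng_wn = (np.random.default_rng(c) for c in children[-3:])

    clean: dict[str, Recording] = {}
    annotations: list[BeatAnnotation] = []
    mix = np.zeros((n_ch, n))
    for src, rng in zip(scenario.sources, source_rngs):
        beats = generate_rr_series(src.mean_hr, src.sd_hr, scenario.duration, rng)
        phase = cardiac_phase(beats, t)
        moment = dipole_waveform(src.waveform_params, phase)  # (n, 3) mV
        lf = lead_field(src.position, src.orientation, scenario.geometry)
        sig = lf @ moment.T  # (n_ch, n) µV
        mix += sig
        clean[src.label] = Recording(sig, fs)
        r_samples = np.round(beats * fs).astype(int)
        r_samples = r_samples[(r_samples >= 0) & (r_samples < n)]
        annotations.append(BeatAnnotation(label=src.label, r_samples=r_samples))

    noise = _baseline_wander(rng_base, n_ch, n, fs, scenario.noise)
    if scenario.noise.powerline_amplitude_uv > 0:
        phases = rng_pl.uniform(0, 2 * np.pi, size=n_ch)
        noise = noise + scenario.noise.powerline_amplitude_uv * np.sin(
            2 * np.pi * scenario.noise.powerline_freq_hz * t[None, :] + phases[:, None]
        )
    if scenario.noise.broadband_sd_uv > 0:
        noise = noise + rng_wn.normal(0, scenario.noise.broadband_sd_uv, size=(n_ch, n))

    recording = Recording(mix + noise, fs)
    return SimulationResult(
        recording=recording,
        annotations=annotations,
        clean=clean,
        noise=Recording(noise, fs),
        scenario=scenario,
    )
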