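"""Beat segmentation and ensemble averaging of fetal ECG complexes.

Aligning the six maternal-suppressed channels on one fetus's R peaks
and averaging pointwise suppresses everything asynchronous with that
fetus: broadband noise shrinks as 1/√N, and — because the co-twin's
rhythm runs at a different rate — the other fetus's complexes smear
out of the average as well. The result is one clean averaged P-QRS-T
complex per channel per fetus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BeatAnnotation, Recording

DEFAULT_ENSEMBLE_WINDOW_MS = (100.0, 300.0)  # pre-R, post-R
CORRELATION_REJECT_THRESHOLD = 0.5


@dataclass
class EnsembleComplex:
    """Per-channel averaged ECG complex for one fetus.

    ``channel_noise_uv`` is the standard error of the mean per channel
    (how much asynchronous interference survives the averaging); the
    vectorcardiogram stage uses it to weight channels.
    """

    fetus_label: str
    waveform: np.ndarray  # (channels, window_samples) µV
    window_ms: tuple[float, float]
    sampling_rate: float
    n_beats: int
    beat_rejection_count: int = 0
    channel_noise_uv: np.ndarray | None = None

    def __post_init__(self):
        self.waveform = np.atleast_2d(np.asarray(self.waveform, dtype=float))
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("ensemble waveform must be finite")

    @property
    def r_index(self) -> int:
        """Window index of the alignment R peak."""
        return int(round(self.window_ms[0] * self.sampling_rate / 1000.0))

    @property
    def time_ms(self) -> np.ndarray:
        w = self.waveform.shape[1]
        return (np.arange(w) - self.r_index) / self.sampling_rate * 1000.0


def segment_beats(
    recording: Recording,
    beats: BeatAnnotation,
    window_ms: tuple[float, float] = DEFAULT_ENSEMBLE_WINDOW_MS,
) -> tuple[np.ndarray, int]:
    """Stack beat-aligned segments: (n_beats, channels, window_samples).

    Beats whose window crosses a recording edge are dropped and
    counted; all retained segments have identical length. Raises when
    no beat can be retained.
    """
    fs = recording.sampling_rate
    pre = int(round(window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    segs = []
    dropped = 0
    for b in beats.r_samples:
        if b - pre < 0 or b + post > recording.n_samples:
            dropped += 1
            continue
        segs.append(recording.samples[:, b - pre:b + post])
    if not segs:
        raise ValueError("no beat fits inside the recording with this window")
    return np.stack(segs), dropped


def ensemble_average(
    stack: np.ndarray,
    rejection: str = "correlation",
    threshold: float = CORRELATION_REJECT_THRESHOLD,
    fetus_label: str = "fetus",
    window_ms: tuple[float, float] = DEFAULT_ENSEMBLE_WINDOW_MS,
    sampling_rate: float = 500.0,
) -> EnsembleComplex:
    """Pointwise mean over beats, optionally rejecting artifact beats.

    With ``rejection="correlation"`` each beat's (channel-concatenated)
    segment must correlate at least ``threshold`` with the pointwise
    median beat; rejected beats are counted and excluded. Raises when
    every beat is rejected.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be (n_beats, channels, window_samples) with >= 1 beat")
    n = stack.shape[0]
    if rejection == "none" or n == 1:
        keep = np.ones(n, dtype=bool)
    elif rejection == "correlation":
        # correlate in the QRS region of the channel where the median
        # beat is strongest: whole-window multi-channel correlation is
        # dominated by asynchronous interference, not beat morphology
        med = np.median(stack, axis=0)  # (ch, w)
        med = med - med.mean(axis=1, keepdims=True)
        r = int(round(window_ms[0] * sampling_rate / 1000.0))
        half = max(int(round(0.06 * sampling_rate)), 1)
        lo, hi = max(r - half, 0), min(r + half, stack.shape[2])
        ch = int(np.argmax(np.abs(med[:, lo:hi]).max(axis=1)))
        ref = med[ch, lo:hi] - med[ch, lo:hi].mean()
        ref_norm = np.linalg.norm(ref)
        corr = np.ones(n)
        for i in range(n):
            x = stack[i, ch, lo:hi]
            x = x - x.mean()
            nx = np.linalg.norm(x)
            if nx == 0 or ref_norm == 0:
                corr[i] = 1.0  # flat/identical content, nothing to reject on
            else:
                corr[i] = float(x @ ref) / (nx * ref_norm)
        keep = corr >= threshold
    else:
        raise ValueError(f"unknown rejection mode {rejection!r}")
    if not np.any(keep):
        raise ValueError(
            "all beats rejected by correlation gating; review the rejection threshold"
        )
    retained = stack[keep]
    mean = retained.mean(axis=0)
    n_keep = int(keep.sum())
    if n_keep > 1:
        noise = retained.std(axis=(0, 2), ddof=1) / np.sqrt(n_keep)
    else:
        noise = np.zeros(stack.shape[1])
    return EnsembleComplex(
        fetus_label=fetus_label,
        waveform=mean,
        window_ms=tuple(window_ms),
        sampling_rate=sampling_rate,
        n_beats=n_keep,
        beat_rejection_count=int(n - n_keep),
        channel_noise_uv=noise,
    )


def ensemble_for_fetus(
    residual: Recording,
    beats: BeatAnnotation,
    window_ms: tuple[float, float] = DEFAULT_ENSEMBLE_WINDOW_MS,
    rejection: str = "correlation",
) -> EnsembleComplex:
    """Segment and average in one step."""
    stack, dropped = segment_beats(residual, beats, window_ms)
    ens = ensemble_average(
        stack,
        rejection=rejection,
        fetus_label=beats.label,
        window_ms=window_ms,
        sampling_rate=residual.sampling_rate,
    )
    return ens
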