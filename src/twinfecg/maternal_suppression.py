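"""Maternal R-peak detection and dynamic template subtraction.

The maternal ECG is by far the strongest cardiac source on the abdomen,
so its R peaks are found on the channel with the most plausible
dominant rhythm. Suppression builds a running-average P-QRS-T template
per channel and subtracts it at every maternal beat after fitting a
per-beat least-squares amplitude scale — the "dynamic" part: the
subtracted waveform adapts to beat-to-beat amplitude changes (e.g.
respiration) while fetal complexes, asynchronous with the maternal
rhythm, average out of the template. Samples outside the maternal beat
windows are left untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import MATERNAL, BeatAnnotation, MaternalRhythmNotFoundError, Recording

logger = logging.getLogger(__name__)

MATERNAL_RATE_BAND_BPM = (40.0, 160.0)
MATERNAL_REFRACTORY_S = 0.25
DEFAULT_TEMPLATE_WINDOW_MS = (250.0, 350.0)  # pre-R, post-R
MIN_TEMPLATE_BEATS = 10


def _qrs_envelope(x: np.ndarray, fs: float, band=(8.0, 40.0), smooth_s: float = 0.10):
    """Rectified, smoothed QRS-band energy of one channel.

    Returns (envelope, band-passed signal)."""
    sos = sps.butter(3, band, btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    win = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(win) / win
    return np.convolve(np.abs(bp), kernel, mode="same"), bp


def _detect_channel_peaks(x: np.ndarray, fs: float, refractory_s: float,
                          band=(8.0, 40.0)) -> np.ndarray:
    env, bp = _qrs_envelope(x, fs, band=band)
    if not np.any(env > 0):
        return np.array([], dtype=int)
    thr = 0.4 * np.percentile(env, 99)
    peaks, _ = sps.find_peaks(env, height=thr, distance=max(int(refractory_s * fs), 1))
    if peaks.size == 0:
        return peaks
    # refine each peak to the extremum of the band-passed signal nearby
    half = int(round(0.05 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    keep = [refined[0]]
    for r in refined[1:]:
        if r - keep[-1] >= refractory_s * fs:
            keep.append(r)
    return np.asarray(keep, dtype=int)


def _rhythm_score(x: np.ndarray, peaks: np.ndarray, fs: float, rate_band) -> float:
    """Score a candidate maternal train: amplitude of a plausible rhythm.

    Plausibility (in-band rate, regular RR) gates; the score itself is
    the median QRS-band amplitude at the peaks, because the maternal
    ECG is the amplitude-dominant source on the abdomen — a regular
    *fetal* rhythm inside the band must never outrank it.
    """
    if peaks.size < 5:
        return -np.inf
    rr = np.diff(peaks) / fs
    rate = 60.0 / np.median(rr)
    if not rate_band[0] <= rate <= rate_band[1]:
        return -np.inf
    cv = np.std(rr) / np.mean(rr)
    if cv > 0.25:
        return -np.inf
    env, _ = _qrs_envelope(x, fs)
    return float(np.median(env[np.clip(peaks, 0, env.size - 1)]))


def detect_maternal_r_peaks(recording: Recording) -> BeatAnnotation:
    """Locate maternal R peaks on the amplitude-dominant channel.

    Scans every channel with a polarity-insensitive QRS-band detector
    (refractory 250 ms), scores the resulting trains for physiological
    plausibility (40-160 bpm, regular RR) and keeps the channel with
    the strongest plausible rhythm. Raises
    :class:`MaternalRhythmNotFoundError` when no channel qualifies.
    """
    fs = recording.sampling_rate
    best = None
    best_score = -np.inf
    for ch in range(recording.n_channels):
        peaks = _detect_channel_peaks(recording.samples[ch], fs, MATERNAL_REFRACTORY_S)
        score = _rhythm_score(recording.samples[ch], peaks, fs, MATERNAL_RATE_BAND_BPM)
        if score > best_score:
            best_score = score
            best = peaks
    if best is None or not np.isfinite(best_score):
        raise MaternalRhythmNotFoundError("maternal rhythm not found in any channel")
    return BeatAnnotation(label=MATERNAL, r_samples=best)


@dataclass
class TemplateModel:
    """Per-channel maternal template with per-beat amplitude scales.

    ``per_beat_scale`` holds the QRS-segment amplitude scale (one per
    channel per beat); ``segment_coeffs`` holds the full segment-wise
    fit (amplitude plus a template-derivative term per P/QRS/T segment)
    actually used for subtraction.
    """

    template: np.ndarray  # (channels, window_samples)
    per_beat_scale: np.ndarray  # (n_beats, channels), QRS amplitude scale
    r_samples: np.ndarray  # beats the scales belong to
    window_ms: tuple[float, float]
    forgetting: float
    segment_bounds: tuple[int, ...] = ()  # window indices delimiting P/QRS/T
    segment_coeffs: np.ndarray | None = None  # (n_beats, channels, n_seg, 2)

    def window_samples(self, fs: float) -> tuple[int, int]:
        pre = int(round(self.window_ms[0] * fs / 1000.0))
        post = int(round(self.window_ms[1] * fs / 1000.0))
        return pre, post


# Half-width of the QRS segment used for segment-wise scaling (s).
QRS_HALF_WIDTH_S = 0.06


def _segment_bounds(pre: int, post: int, fs: float) -> tuple[int, ...]:
    """Window indices delimiting the P, QRS and T scaling segments."""
    half = int(round(QRS_HALF_WIDTH_S * fs))
    qrs_lo = max(pre - half, 0)
    qrs_hi = min(pre + half, pre + post)
    bounds = [0, qrs_lo, qrs_hi, pre + post]
    return tuple(sorted(set(bounds)))


def _solve_ls(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    gram = X.T @ X
    if np.trace(gram) == 0 or np.linalg.cond(gram) > 1e10:
        denom = float(X[:, 0] @ X[:, 0])
        a = float(y @ X[:, 0]) / denom if denom > 0 else 0.0
        return np.array([a, 0.0])
    return np.linalg.solve(gram, X.T @ y)


def _fit_segment(seg: np.ndarray, tmpl: np.ndarray, dtmpl: np.ndarray) -> tuple[float, float]:
    """Least squares of seg ≈ a·tmpl + b·dtmpl (one channel, one segment).

    The derivative regressor absorbs sub-sample alignment error. A
    single robust reweighting pass masks outlier samples — typically a
    fetal QRS crossing the maternal window — so the fit does not absorb
    (and the subtraction does not attenuate) fetal complexes.
    """
    X = np.stack([tmpl, dtmpl], axis=1)
    coef = _solve_ls(X, seg)
    resid = seg - X @ coef
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = 1.4826 * mad
    if sigma > 0:
        keep = np.abs(resid) <= 3.0 * sigma
        if keep.sum() >= max(8, seg.size // 2) and keep.sum() < seg.size:
            coef = _solve_ls(X[keep], seg[keep])
    return float(coef[0]), float(coef[1])


def _fit_beat(segment: np.ndarray, template: np.ndarray, dtemplate: np.ndarray,
              bounds: tuple[int, ...]) -> np.ndarray:
    """Segment-wise fit for one beat; returns (channels, n_seg, 2)."""
    n_ch = template.shape[0]
    n_seg = len(bounds) - 1
    out = np.zeros((n_ch, n_seg, 2))
    for c in range(n_ch):
        for s in range(n_seg):
            lo, hi = bounds[s], bounds[s + 1]
            out[c, s] = _fit_segment(segment[c, lo:hi], template[c, lo:hi], dtemplate[c, lo:hi])
    return out


def build_dynamic_template(
    recording: Recording,
    maternal_beats: BeatAnnotation,
    window_ms: tuple[float, float] = DEFAULT_TEMPLATE_WINDOW_MS,
    forgetting: float = 0.9,
) -> TemplateModel:
    """Running-average maternal template plus per-beat scales.

    The template is an exponentially forgetting mean of beat-aligned
    segments (so slow morphology drift is tracked); each beat then
    receives a per-channel least-squares amplitude scale against the
    final template. Needs at least 10 in-bounds maternal beats and a
    window shorter than the minimum maternal RR interval.
    """
    fs = recording.sampling_rate
    pre = int(round(window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    if maternal_beats.r_samples.size >= 2:
        # Occasional short RRs are handled by midpoint truncation at
        # subtraction time; a window beyond the typical RR is misuse.
        median_rr = np.median(np.diff(maternal_beats.r_samples))
        if pre + post >= median_rr:
            raise ValueError(
                f"template window {window_ms} ms exceeds the median maternal RR "
                f"interval ({median_rr / fs * 1000:.0f} ms)"
            )
    r = maternal_beats.r_samples
    keep = (r - pre >= 0) & (r + post <= recording.n_samples)
    r = r[keep]
    if r.size < MIN_TEMPLATE_BEATS:
        raise ValueError(
            f"need at least {MIN_TEMPLATE_BEATS} maternal beats for a reliable template, got {r.size}"
        )
    segments = np.stack([recording.samples[:, b - pre:b + post] for b in r])  # (n, ch, w)
    template = segments[0].astype(float).copy()
    for seg in segments[1:]:
        template = forgetting * template + (1.0 - forgetting) * seg
    dtemplate = np.gradient(template, axis=1)
    bounds = _segment_bounds(pre, post, fs)
    coeffs = np.stack([_fit_beat(seg, template, dtemplate, bounds) for seg in segments])
    # the segment containing the R sample is the QRS segment
    qrs_seg = int(np.searchsorted(bounds, pre, side="right")) - 1
    qrs_seg = min(max(qrs_seg, 0), len(bounds) - 2)
    scales = coeffs[:, :, qrs_seg, 0]  # (n, ch)
    return TemplateModel(
        template=template,
        per_beat_scale=scales,
        r_samples=r,
        window_ms=tuple(window_ms),
        forgetting=forgetting,
        segment_bounds=bounds,
        segment_coeffs=coeffs,
    )


def subtract_maternal(
    recording: Recording,
    template_model: TemplateModel,
    maternal_beats: BeatAnnotation | None = None,
) -> Recording:
    """Subtract the scaled maternal template at every maternal beat.

    Windows overlapping a neighbouring beat are truncated at the RR
    midpoint; beats whose window would leave the recording are skipped
    with a logged warning. Samples outside all maternal windows are
    bit-identical to the input. An empty beat list returns the input
    unchanged.
    """
    fs = recording.sampling_rate
    pre, post = template_model.window_samples(fs)
    beats = maternal_beats.r_samples if maternal_beats is not None else template_model.r_samples
    out = recording.samples.copy()
    if beats.size == 0:
        return recording.with_samples(out)
    template = template_model.template
    dtemplate = np.gradient(template, axis=1)
    bounds = template_model.segment_bounds or _segment_bounds(pre, post, fs)
    coeff_by_beat = {}
    if template_model.segment_coeffs is not None:
        coeff_by_beat = {int(b): template_model.segment_coeffs[i]
                         for i, b in enumerate(template_model.r_samples)}
    n_ch = template.shape[0]
    for i, b in enumerate(beats):
        lo, hi = b - pre, b + post
        if lo < 0 or hi > recording.n_samples:
            logger.warning("maternal beat at sample %d skipped: window exceeds recording bounds", b)
            continue
        coeffs = coeff_by_beat.get(int(b))
        if coeffs is None:
            coeffs = _fit_beat(recording.samples[:, lo:hi], template, dtemplate, bounds)
        # reconstruct this beat's maternal estimate from the segment fits
        est = np.zeros_like(template)
        for s in range(len(bounds) - 1):
            s_lo, s_hi = bounds[s], bounds[s + 1]
            for c in range(n_ch):
                a, bb = coeffs[c, s]
                est[c, s_lo:s_hi] = a * template[c, s_lo:s_hi] + bb * dtemplate[c, s_lo:s_hi]
        # truncate at RR midpoints to avoid double subtraction on short RR
        t_lo, t_hi = lo, hi
        if i > 0:
            t_lo = max(t_lo, (int(beats[i - 1]) + int(b)) // 2 + 1)
        if i < beats.size - 1:
            t_hi = min(t_hi, (int(b) + int(beats[i + 1])) // 2 + 1)
        if t_hi <= t_lo:
            continue
        out[:, t_lo:t_hi] -= est[:, t_lo - lo:t_hi - lo]
    return recording.with_samples(out)


def suppress_maternal(
    recording: Recording,
    window_ms: tuple[float, float] = DEFAULT_TEMPLATE_WINDOW_MS,
    forgetting: float = 0.9,
) -> tuple[Recording, BeatAnnotation, TemplateModel]:
    """Detect maternal beats, build the template and subtract it."""
    beats = detect_maternal_r_peaks(recording)
    model = build_dynamic_template(recording, beats, window_ms=window_ms, forgetting=forgetting)
    residual = subtract_maternal(recording, model, beats)
    return residual, beats, model
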