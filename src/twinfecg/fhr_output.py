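"""Beat-to-beat fetal heart rate traces and detection metrics.

Every emitted rate maps to two detected beats: intervals implying a
rate outside 30-300 bpm are gap-masked (missed/extra beat guard), and
sudden jumps between adjacent intervals are flagged — a missed beat in
a 140 bpm rhythm yields a plausible-looking ≈70 bpm interval that only
the jump detector catches. Display resampling is sample-and-hold and
never interpolates across gaps: a monitor must not invent heart rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import HR_BOUNDS_BPM, BeatAnnotation

JUMP_THRESHOLD_BPM = 25.0
DISPLAY_RATE_HZ = 4.0


@dataclass
class FHRTrace:
    """Beat-to-beat heart-rate trace for one source."""

    fetus_label: str
    beat_times: np.ndarray  # s, length n
    fhr_bpm: np.ndarray  # length n-1, rate of each successive interval
    gap_mask: np.ndarray  # bool, length n-1; True = excluded interval
    jump_flags: np.ndarray  # bool, length n-1; suspected missed/extra beat
    resampled: tuple[np.ndarray, np.ndarray] | None = None  # (times, values)

    def valid_values(self) -> np.ndarray:
        return self.fhr_bpm[~self.gap_mask]


def compute_fhr(
    beats: BeatAnnotation,
    sampling_rate: float,
    jump_threshold_bpm: float = JUMP_THRESHOLD_BPM,
) -> FHRTrace:
    """60/RR for each successive beat pair, with gap and jump guards."""
    if len(beats) < 2:
        raise ValueError("need at least 2 beats to compute a heart rate")
    t = beats.r_samples / sampling_rate
    rr = np.diff(t)
    fhr = 60.0 / rr
    lo, hi = HR_BOUNDS_BPM
    gap = (fhr <= lo) | (fhr >= hi)
    jump = np.zeros_like(gap)
    valid_idx = np.flatnonzero(~gap)
    for prev, cur in zip(valid_idx[:-1], valid_idx[1:]):
        if abs(fhr[cur] - fhr[prev]) > jump_threshold_bpm:
            jump[cur] = True
    return FHRTrace(
        fetus_label=beats.label,
        beat_times=t,
        fhr_bpm=fhr,
        gap_mask=gap,
        jump_flags=jump,
    )


def resample_trace(trace: FHRTrace, rate: float = DISPLAY_RATE_HZ) -> FHRTrace:
    """Uniform sample-and-hold display trace.

    Grid spans the trace's beat interval at ``rate`` Hz; each grid
    point holds the rate of the interval it falls in, NaN inside
    gap-masked intervals and before the first interval. No
    interpolation across gaps.
    """
    if rate <= 0:
        raise ValueError(f"resampling rate must be positive, got {rate}")
    if trace.beat_times.size < 2:
        raise ValueError("trace is empty")
    t0, t1 = trace.beat_times[0], trace.beat_times[-1]
    grid = np.arange(t0, t1, 1.0 / rate)
    # interval i covers [beat_times[i], beat_times[i+1])
    idx = np.searchsorted(trace.beat_times, grid, side="right") - 1
    idx = np.clip(idx, 0, trace.fhr_bpm.size - 1)
    values = trace.fhr_bpm[idx].astype(float)
    values[trace.gap_mask[idx]] = np.nan
    return FHRTrace(
        fetus_label=trace.fetus_label,
        beat_times=trace.beat_times,
        fhr_bpm=trace.fhr_bpm,
        gap_mask=trace.gap_mask,
        jump_flags=trace.jump_flags,
        resampled=(grid, values),
    )


@dataclass
class DetectionMetrics:
    """Beat-detection quality against simulator ground truth."""

    sensitivity: float
    ppv: float
    fhr_rmse_bpm: float
    n_truth: int
    n_detected: int
    n_matched: int
    tolerance_ms: float


def match_beats(
    detected: np.ndarray, truth: np.ndarray, sampling_rate: float, tolerance_ms: float = 50.0
) -> list[tuple[int, int]]:
    """One-to-one nearest matching of detected to truth beats."""
    tol = tolerance_ms * 1e-3 * sampling_rate
    pairs = []
    used = set()
    for i, tb in enumerate(truth):
        if detected.size == 0:
            break
        j = int(np.argmin(np.abs(detected - tb)))
        if abs(int(detected[j]) - int(tb)) <= tol and j not in used:
            pairs.append((j, i))
            used.add(j)
    return pairs


def evaluate_against_truth(
    detected: BeatAnnotation,
    truth: BeatAnnotation,
    sampling_rate: float,
    tolerance_ms: float = 50.0,
) -> DetectionMetrics:
    """Sensitivity, PPV and FHR RMSE of a detected train vs ground truth.

    FHR RMSE is computed over truth intervals whose both endpoints were
    matched (the overlapping valid region), comparing 60/RR of the
    matched detections with 60/RR of the truth.
    """
    pairs = match_beats(detected.r_samples, truth.r_samples, sampling_rate, tolerance_ms)
    n_matched = len(pairs)
    sens = n_matched / max(len(truth), 1)
    ppv = n_matched / max(len(detected), 1)
    truth_to_det = {ti: di for di, ti in pairs}
    errs = []
    for i in range(len(truth) - 1):
        if i in truth_to_det and (i + 1) in truth_to_det:
            rr_t = (truth.r_samples[i + 1] - truth.r_samples[i]) / sampling_rate
            d0 = detected.r_samples[truth_to_det[i]]
            d1 = detected.r_samples[truth_to_det[i + 1]]
            rr_d = (d1 - d0) / sampling_rate
            if rr_d > 0:
                errs.append(60.0 / rr_d - 60.0 / rr_t)
    rmse = float(np.sqrt(np.mean(np.square(errs)))) if errs else float("nan")
    return DetectionMetrics(
        sensitivity=float(sens),
        ppv=float(ppv),
        fhr_rmse_bpm=rmse,
        n_truth=len(truth),
        n_detected=len(detected),
        n_matched=n_matched,
        tolerance_ms=tolerance_ms,
    )


def plot_traces(traces, path, title: str = "Twin beat-to-beat FHR"):  # pragma: no cover
    """CTG-style dual-fetus tracing to a PNG file (optional matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for tr in traces:
        rt = tr.resampled or resample_trace(tr).resampled
        ax.plot(rt[0], rt[1], label=tr.fetus_label, lw=1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("FHR (bpm)")
    ax.set_ylim(60, 220)
    ax.legend()
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
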