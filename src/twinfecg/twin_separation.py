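"""Separation of the two fetal ECGs by linear channel combination.

After maternal suppression, each abdominal channel carries a mixture of
both fetal ECGs. Because each fetal heart projects onto the six
channels through its own (approximately rank-one, QRS-dominated)
mixing vector, a weighted sum of channels can enhance one fetus while
nulling the other. This module bootstraps candidate fetal beats per
channel, groups them into (at most) two rate-consistent trains, derives
the two combination weight vectors — own-fetus ensemble-QRS energy
maximization under a null constraint on the other fetus's ensemble QRS
— detects each fetus's QRS train on its enhanced signal, and checks
that the two trains are genuinely distinct heart beats rather than one
fetus tracked twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import BeatAnnotation, Recording, TwinsNotSeparableError
from .maternal_suppression import _detect_channel_peaks, _qrs_envelope

FETAL_RATE_BAND_BPM = (100.0, 200.0)
FETAL_REFRACTORY_S = 0.2
QRS_WINDOW_S = 0.06  # half-width used for ensemble-QRS matrices
COINCIDENCE_TOL_MS = 30.0


# ---------------------------------------------------------------------------
# Candidate beats
# ---------------------------------------------------------------------------

def detect_candidate_beats(residual: Recording,
                           rate_band: tuple[float, float] = FETAL_RATE_BAND_BPM,
                           ) -> list[BeatAnnotation]:
    """Per-channel fetal QRS candidate trains on the maternal residual.

    Polarity-insensitive band-energy detection per channel; trains whose
    implied rate falls outside ``rate_band`` or that are too sparse are
    returned with ``confidence="low"`` rather than dropped.
    """
    fs = residual.sampling_rate
    out = []
    for ch in range(residual.n_channels):
        peaks = _detect_channel_peaks(residual.samples[ch], fs, FETAL_REFRACTORY_S,
                                      band=(10.0, 45.0))
        confidence = _train_confidence(residual.samples[ch], peaks, fs, rate_band)
        out.append(BeatAnnotation(label=f"ch{ch + 1}", r_samples=peaks, confidence=confidence))
    return out


def _train_confidence(x: np.ndarray, peaks: np.ndarray, fs: float, rate_band) -> str:
    """"ok" only for a prominent, regular, in-band beat train."""
    if peaks.size < 5:
        return "low"
    rr = np.diff(peaks) / fs
    rate = 60.0 / np.median(rr)
    if not rate_band[0] <= rate <= rate_band[1] or np.std(rr) / np.mean(rr) > 0.3:
        return "low"
    env, _ = _qrs_envelope(x, fs, band=(10.0, 45.0))
    background = np.median(env)
    prominence = np.median(env[np.clip(peaks, 0, env.size - 1)])
    if background <= 0 or prominence < 3.0 * background:
        return "low"  # peaks barely rise above the noise floor
    return "ok"


def _coincidence_fraction(a: np.ndarray, b: np.ndarray, tol_samples: float) -> float:
    """Fraction of beats in ``a`` with a beat of ``b`` within tolerance."""
    if a.size == 0 or b.size == 0:
        return 0.0
    idx = np.searchsorted(b, a)
    left = b[np.clip(idx - 1, 0, b.size - 1)]
    right = b[np.clip(idx, 0, b.size - 1)]
    near = np.minimum(np.abs(a - left), np.abs(a - right))
    return float(np.mean(near <= tol_samples))


def _train_regularity(peaks: np.ndarray, fs: float, rate_band,
                      max_cv: float = 0.3) -> float:
    """Score: higher for long, regular, in-band trains; -inf if implausible.

    A channel seeing a mixture of both fetuses yields an irregular RR
    series (coefficient of variation above ``max_cv``) and scores -inf.
    """
    if peaks.size < 10:
        return -np.inf
    rr = np.diff(peaks) / fs
    rate = 60.0 / np.median(rr)
    if not rate_band[0] <= rate <= rate_band[1]:
        return -np.inf
    cv = np.std(rr) / np.mean(rr)
    if cv > max_cv:
        return -np.inf
    return peaks.size * (1.0 - 2.0 * cv)


def cluster_candidate_trains(
    candidates: list[BeatAnnotation],
    sampling_rate: float,
    rate_band: tuple[float, float] = FETAL_RATE_BAND_BPM,
) -> list[BeatAnnotation]:
    """Select up to two mutually distinct representative beat trains.

    The most regular plausible per-channel train seeds the first
    cluster; the second is the most regular train sharing fewer than
    30% of its beats with the first. Channels carrying a mixture of
    both fetuses, or detections that barely rise above the noise
    floor, have irregular RR series or a low-confidence flag and are
    never selected.
    """
    tol = COINCIDENCE_TOL_MS * 1e-3 * sampling_rate
    scored = sorted(
        (c for c in candidates),
        key=lambda c: _train_regularity(c.r_samples, sampling_rate, rate_band),
        reverse=True,
    )
    plausible = [
        c for c in scored
        if np.isfinite(_train_regularity(c.r_samples, sampling_rate, rate_band))
    ]
    if not plausible:
        return []
    first = plausible[0]
    for c in plausible[1:]:
        coinc = max(_coincidence_fraction(c.r_samples, first.r_samples, tol),
                    _coincidence_fraction(first.r_samples, c.r_samples, tol))
        if coinc < 0.3:
            return [first, c]
    return [first]


# ---------------------------------------------------------------------------
# Combination weights
# ---------------------------------------------------------------------------

@dataclass
class CombinationWeights:
    """Channel weights enhancing one fetus each.

    ``quality`` maps each weight's name to the achieved own-vs-other
    ensemble-QRS energy ratio in dB (``inf`` when only one fetus is
    present).
    """

    w_A: np.ndarray
    w_B: np.ndarray | None
    method: str = "auto"
    quality: dict = field(default_factory=dict)

    def __post_init__(self):
        self.w_A = np.asarray(self.w_A, dtype=float)
        n = np.linalg.norm(self.w_A)
        if n == 0:
            raise ValueError("w_A must be nonzero")
        self.w_A = self.w_A / n
        if self.w_B is not None:
            self.w_B = np.asarray(self.w_B, dtype=float)
            n = np.linalg.norm(self.w_B)
            if n == 0:
                raise ValueError("w_B must be nonzero")
            self.w_B = self.w_B / n
            cosang = abs(float(self.w_A @ self.w_B))
            if cosang > np.cos(np.deg2rad(10.0)):
                raise ValueError("w_A and w_B are nearly collinear (angle < 10 degrees)")


def _ensemble_qrs_matrix(residual: Recording, beats: np.ndarray, half_s: float = QRS_WINDOW_S) -> np.ndarray:
    """Channels × window mean QRS complex around the given beats."""
    fs = residual.sampling_rate
    w = int(round(half_s * fs))
    segs = [residual.samples[:, b - w:b + w]
            for b in beats if b - w >= 0 and b + w <= residual.n_samples]
    if not segs:
        raise ValueError("no in-bounds beats to build an ensemble QRS")
    m = np.mean(segs, axis=0)
    return m - m.mean(axis=1, keepdims=True)


def _dominant_direction(M: np.ndarray) -> np.ndarray:
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    return u[:, 0]


def _beat_locked_reconstruction(
    samples: np.ndarray, beats: np.ndarray, fs: float,
    window_s: tuple[float, float] = (0.10, 0.30),
) -> np.ndarray:
    """Beat-locked average complex re-inserted at every beat.

    The returned signal is the part of ``samples`` that is synchronous
    with ``beats`` (that source's mean contribution); subtracting it
    deflates the source from the mixture.
    """
    pre = int(round(window_s[0] * fs))
    post = int(round(window_s[1] * fs))
    n = samples.shape[1]
    segs = [samples[:, b - pre:b + post] for b in beats if b - pre >= 0 and b + post <= n]
    out = np.zeros_like(samples)
    if not segs:
        return out
    template = np.mean(segs, axis=0)
    template = template - template.mean(axis=1, keepdims=True)
    for b in beats:
        lo, hi = b - pre, b + post
        s_lo = max(lo, 0)
        s_hi = min(hi, n)
        if s_hi <= s_lo:
            continue
        out[:, s_lo:s_hi] += template[:, s_lo - lo:s_hi - lo]
    return out


def _null_rank(s: np.ndarray, max_rank: int = 3) -> int:
    """How many directions of the other twin's QRS matrix to null.

    A dipole source spans at most three directions, so a noise-free
    ensemble-QRS matrix is numerically rank ≤ 3 and all of it should
    be nulled. Under noise only directions that stand well above the
    trailing (noise-floor) singular values are estimated reliably —
    nulling a noisy direction costs own-fetus energy without removing
    real co-twin signal, so poorly estimated directions are left to
    the averaging stages instead.
    """
    if s.size == 0 or s[0] == 0:
        return 1
    floor = np.median(s[max_rank:]) if s.size > max_rank else 0.0
    thr = max(0.01 * s[0], 10.0 * floor)
    return int(min(max(np.sum(s > thr), 1), max_rank))


def _max_snr_weight(S: np.ndarray, C: np.ndarray, null_basis: np.ndarray | None) -> np.ndarray:
    """Maximize wᵀS w / wᵀC w over the orthogonal complement of null_basis."""
    from scipy.linalg import eigh, null_space

    n = S.shape[0]
    N = np.eye(n) if null_basis is None or null_basis.shape[1] == 0 else null_space(null_basis.T)
    _, vecs = eigh(N.T @ S @ N, N.T @ C @ N)
    w = N @ vecs[:, -1]
    return w / np.linalg.norm(w)


# Ridge on the interference covariance, as a fraction of mean own-QRS
# power: when interference is far below the fetal signal the weight
# tends to the matched filter; when interference dominates, whitening
# stays fully active.
BEAMFORMER_RIDGE_FRACTION = 0.1


def derive_combination_weights(
    residual: Recording,
    candidates: list[BeatAnnotation] | None = None,
    trains: list[BeatAnnotation] | None = None,
    rate_band: tuple[float, float] = FETAL_RATE_BAND_BPM,
) -> tuple[CombinationWeights, list[BeatAnnotation]]:
    """Weights enhancing each fetus while nulling the other.

    Each train's beat-locked average complex is first deflated from
    the mixture so the two ensemble-averaged QRS matrices M (channels
    × window) are free of cross-contamination. The weight for a fetus
    then (a) lies in the orthogonal complement of the other fetus's
    reliably estimated ensemble-QRS directions (hard null constraint;
    exact in the noise-free case, where M is numerically rank ≤ 3),
    and (b) within that complement maximizes own ensemble-QRS energy
    against the covariance of the non-beat-locked background (maternal
    subtraction leftover and noise), so interference-heavy channels
    are down-weighted instead of amplified. Raises
    :class:`TwinsNotSeparableError` when the null constraint removes
    nearly all own-QRS energy (collinear mixing vectors) — rather than
    emitting two copies of the same fetus.

    Returns the weights and the representative trains used.
    """
    if trains is None:
        if candidates is None:
            candidates = detect_candidate_beats(residual, rate_band)
        trains = cluster_candidate_trains(candidates, residual.sampling_rate, rate_band)
    if not trains:
        raise TwinsNotSeparableError(
            "no plausible fetal beat train found", {"n_trains": 0}
        )
    fs = residual.sampling_rate
    n_ch = residual.n_channels
    # deflation: remove each train's beat-locked average before forming
    # the other train's ensemble, so cross-contamination of the QRS
    # matrices does not cap the achievable suppression
    recon = [
        _beat_locked_reconstruction(residual.samples, t.r_samples, fs) for t in trains
    ]
    background = residual.samples - sum(recon)
    background = background - background.mean(axis=1, keepdims=True)
    C0 = background @ background.T / background.shape[1]
    M = []
    for i, t in enumerate(trains):
        others = sum((recon[j] for j in range(len(trains)) if j != i),
                     np.zeros_like(residual.samples))
        M.append(_ensemble_qrs_matrix(residual.with_samples(residual.samples - others),
                                      t.r_samples))

    def interference_cov(S: np.ndarray, width: int) -> np.ndarray:
        lam = BEAMFORMER_RIDGE_FRACTION * np.trace(S) / (n_ch * width)
        return C0 + lam * np.eye(n_ch)

    if len(trains) == 1:
        S = M[0] @ M[0].T
        w_A = _max_snr_weight(S, interference_cov(S, M[0].shape[1]), None)
        w_A *= np.sign(w_A @ M[0][:, M[0].shape[1] // 2] + 1e-300)
        return (
            CombinationWeights(w_A=w_A, w_B=None, method="auto",
                               quality={"fetusA_db": np.inf}),
            trains,
        )

    weights = []
    quality = {}
    for own, other, name in ((0, 1, "fetusA"), (1, 0, "fetusB")):
        u, s, _ = np.linalg.svd(M[other], full_matrices=False)
        rank = min(_null_rank(s), n_ch - 1)
        U = u[:, :rank]
        P = np.eye(n_ch) - U @ U.T
        own_before = np.linalg.norm(M[own])
        own_after = np.linalg.norm(P @ M[own])
        if own_after < 0.15 * own_before:
            raise TwinsNotSeparableError(
                "twins not separable: mixing vectors are too collinear",
                {
                    "retained_energy_fraction": float(own_after / own_before),
                    "fetus": name,
                },
            )
        S = M[own] @ M[own].T
        w = _max_snr_weight(S, interference_cov(S, M[own].shape[1]), U)
        # sign: upright own-fetus R peak in the enhanced signal
        center = M[own].shape[1] // 2
        w *= np.sign(w @ M[own][:, center] + 1e-300)
        own_rms = np.linalg.norm(w @ M[own])
        other_rms = np.linalg.norm(w @ M[other])
        quality[f"{name}_db"] = float(
            20 * np.log10(own_rms / other_rms) if other_rms > 0 else np.inf
        )
        weights.append(w)
    cw = CombinationWeights(w_A=weights[0], w_B=weights[1], method="auto", quality=quality)
    return cw, trains


def enhance_fetus(residual: Recording, weights: np.ndarray) -> Recording:
    """Weighted sum of channels; linear and deterministic."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (residual.n_channels,):
        raise ValueError(
            f"weight length {w.shape} does not match channel count {residual.n_channels}"
        )
    return Recording(
        samples=(w @ residual.samples)[None, :],
        sampling_rate=residual.sampling_rate,
        channel_labels=["enhanced"],
        start_time=residual.start_time,
    )


def detect_fetal_qrs(
    enhanced: Recording,
    rate_band: tuple[float, float] = FETAL_RATE_BAND_BPM,
    label: str = "fetus",
) -> BeatAnnotation:
    """Fetal QRS train on a single enhanced channel.

    Polarity-insensitive (the QRS may deflect downward depending on the
    fetus-electrode geometry); refractory period 200 ms. An empty or
    implausible train is returned flagged ``confidence="low"``.
    """
    if enhanced.n_channels != 1:
        raise ValueError("detect_fetal_qrs expects the single-channel enhanced signal")
    fs = enhanced.sampling_rate
    peaks = _detect_channel_peaks(enhanced.samples[0], fs, FETAL_REFRACTORY_S,
                                  band=(10.0, 45.0))
    confidence = _train_confidence(enhanced.samples[0], peaks, fs, rate_band)
    return BeatAnnotation(label=label, r_samples=peaks, confidence=confidence)


# ---------------------------------------------------------------------------
# Distinctness
# ---------------------------------------------------------------------------

@dataclass
class DistinctnessReport:
    """Evidence that the two trains are two hearts, not one tracked twice."""

    coincidence_fraction: float
    window_times_s: np.ndarray
    window_coincidence: np.ndarray
    flagged: bool
    tolerance_ms: float
    warning: str = ""


def check_twin_distinctness(
    beats_A: BeatAnnotation,
    beats_B: BeatAnnotation,
    sampling_rate: float,
    tolerance_ms: float = COINCIDENCE_TOL_MS,
    window_s: float = 60.0,
) -> DistinctnessReport:
    """Coincidence analysis of two beat trains.

    Computes the fraction of A-beats with a B-beat within tolerance,
    overall and over sliding windows; any window above 0.5 flags
    "possible same-source duplication". Two independent fetal rhythms
    coincide only at the chance rate ≈ 2·tol·rate, far below 0.5.
    """
    tol = tolerance_ms * 1e-3 * sampling_rate
    a, b = beats_A.r_samples, beats_B.r_samples
    warning = ""
    if a.size == 0 or b.size == 0:
        warning = "at least one beat train is empty; distinctness not assessable"
        return DistinctnessReport(
            coincidence_fraction=0.0,
            window_times_s=np.array([]),
            window_coincidence=np.array([]),
            flagged=False,
            tolerance_ms=tolerance_ms,
            warning=warning,
        )
    overall = _coincidence_fraction(a, b, tol)
    t_end = max(a[-1], b[-1]) / sampling_rate
    starts = np.arange(0.0, max(t_end - window_s, 0.0) + 1e-9, window_s / 2.0)
    if starts.size == 0:
        starts = np.array([0.0])
    win_frac = []
    for s in starts:
        lo, hi = s * sampling_rate, (s + window_s) * sampling_rate
        a_w = a[(a >= lo) & (a < hi)]
        win_frac.append(_coincidence_fraction(a_w, b, tol) if a_w.size else 0.0)
    win_frac = np.asarray(win_frac)
    flagged = bool(np.any(win_frac > 0.5)) and a.size > 5
    return DistinctnessReport(
        coincidence_fraction=overall,
        window_times_s=starts,
        window_coincidence=win_frac,
        flagged=flagged,
        tolerance_ms=tolerance_ms,
        warning=warning,
    )
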