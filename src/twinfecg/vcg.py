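"""Fetal vectorcardiogram reconstruction and presentation estimation.

Knowing the electrode positions, the six ensemble-averaged channels at
each time sample are the projections of a single 3-D cardiac dipole
through the lead field at the fetal heart's location. Solving the
(6-equation, 3-unknown) least-squares inverse per sample reconstructs
the dipole loop over the cardiac cycle — the vectorcardiogram.

Under the assumption of a normal fetal heart (electrical axis toward
the apex, i.e. caudal within the fetal body), the craniocaudal sign of
the dominant QRS axis in the maternal frame encodes presentation: a
cephalic fetus projects the axis cranially, a breech fetus — the same
heart rotated 180° about the maternal transverse axis — caudally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ElectrodePatchGeometry
from .ensemble import EnsembleComplex
from .synthetic_data import lead_field

# |y| of the dominant axis below which presentation is not called.
PRESENTATION_Y_THRESHOLD = 0.1
QRS_HALF_WIDTH_S = 0.06


class GeometryRankError(RuntimeError):
    """Electrode geometry cannot resolve a 3-D dipole at this position."""


@dataclass
class Vectorcardiogram:
    """Reconstructed 3-D cardiac loop for one fetus."""

    fetus_label: str
    loop: np.ndarray  # (window_samples, 3), heart-dipole scale (mV-equivalent)
    time_ms: np.ndarray
    dominant_axis: np.ndarray  # unit 3-vector at maximal QRS excursion
    presentation: str  # cephalic | breech | indeterminate
    side: str  # left | right
    condition_number: float
    source_position: np.ndarray  # cm, abdominal frame

    def __post_init__(self):
        self.loop = np.asarray(self.loop, dtype=float)
        if not np.all(np.isfinite(self.loop)):
            raise ValueError("VCG loop must be finite")
        self.dominant_axis = np.asarray(self.dominant_axis, dtype=float)
        if not np.isclose(np.linalg.norm(self.dominant_axis), 1.0, atol=1e-6):
            raise ValueError("dominant_axis must be unit norm")
        if self.condition_number < 1.0:
            raise ValueError("condition_number must be >= 1")


def _qrs_matrix(ensemble: EnsembleComplex) -> np.ndarray:
    """Baseline-corrected channels × samples QRS portion of the ensemble."""
    waveform = ensemble.waveform - ensemble.waveform.mean(axis=1, keepdims=True)
    r = ensemble.r_index
    half = int(round(QRS_HALF_WIDTH_S * ensemble.sampling_rate))
    lo, hi = max(r - half, 0), min(r + half, waveform.shape[1])
    return waveform[:, lo:hi]


def _channel_weights(ensemble: EnsembleComplex) -> np.ndarray:
    """Inverse-noise channel weights for the dipole fits.

    Channels where more asynchronous interference survived the
    ensemble averaging carry less weight; equal weights when no noise
    estimate is available.
    """
    sigma = ensemble.channel_noise_uv
    n_ch = ensemble.waveform.shape[0]
    if sigma is None or not np.all(np.isfinite(sigma)) or np.all(sigma <= 0):
        return np.ones(n_ch)
    floor = 0.1 * np.median(sigma[sigma > 0])
    w = 1.0 / np.maximum(sigma, floor)
    return w / w.max()


def _dipole_fit_residual(pos: np.ndarray, Y: np.ndarray, geometry: ElectrodePatchGeometry,
                         weights: np.ndarray | None = None) -> float:
    """Relative (weighted) misfit of a single-dipole model at a position."""
    try:
        L = lead_field(pos, np.eye(3), geometry)
    except ValueError:
        return np.inf
    if weights is not None:
        L = L * weights[:, None]
        Y = Y * weights[:, None]
    D, *_ = np.linalg.lstsq(L, Y, rcond=None)
    return float(np.linalg.norm(Y - L @ D) / np.linalg.norm(Y))


def estimate_source_position(
    ensemble: EnsembleComplex,
    geometry: ElectrodePatchGeometry,
    grid_step_cm: float = 2.0,
) -> np.ndarray:
    """Single-dipole localization of the fetal heart.

    Scans a coarse interior grid beneath the electrode patch for the
    position whose lead field best explains the ensemble QRS in the
    least-squares sense, then polishes with a local simplex search.
    Override with ultrasound-derived coordinates when known.
    """
    from scipy.optimize import minimize

    Y = _qrs_matrix(ensemble)
    if np.linalg.norm(Y) == 0:
        raise ValueError("ensemble has no QRS energy to locate the source")
    weights = _channel_weights(ensemble)
    # search box: beneath the measurement electrodes (the uterus), not
    # outside the patch where a contaminated ensemble can fit spuriously.
    # Cranially the box stops at the median electrode height: the patch
    # is laid out with its lower electrodes over the uterus, and letting
    # the search run to the fundus lets maternal leftover hijack the fit
    meas = np.ones(geometry.n_electrodes, dtype=bool)
    meas[[geometry.ground_index, geometry.reference_index]] = False
    elec = geometry.electrode_positions[meas]
    y_hi = float(np.median(elec[:, 1])) + 4.0
    lo = np.array([elec[:, 0].min(), elec[:, 1].min() - 4.0, elec[:, 2].min() - 8.0])
    hi = np.array([elec[:, 0].max(), y_hi, elec[:, 2].min() - 1.0])
    grids = [np.arange(lo[i], hi[i] + 1e-9, grid_step_cm) for i in range(3)]
    best, best_pos = np.inf, None
    for x in grids[0]:
        for y in grids[1]:
            for z in grids[2]:
                pos = np.array([x, y, z])
                r = _dipole_fit_residual(pos, Y, geometry, weights)
                if r < best:
                    best, best_pos = r, pos
    if best_pos is None:
        raise ValueError("no admissible source position found")
    out = minimize(
        lambda p: _dipole_fit_residual(np.clip(p, lo, hi), Y, geometry, weights),
        best_pos,
        method="Nelder-Mead",
        options={"xatol": 0.1, "fatol": 1e-5, "maxiter": 200},
    )
    return np.clip(out.x, lo, hi) if out.fun <= best else best_pos


def compute_vcg(
    ensemble: EnsembleComplex,
    geometry: ElectrodePatchGeometry,
    source_position: np.ndarray | None = None,
) -> Vectorcardiogram:
    """Least-squares dipole inverse of the ensemble complex.

    Solves lead_field(source_position) · d(t) = y(t) for the dipole
    moment d at every window sample (identity source orientation, so
    the loop lives in the abdominal frame). Reports the lead-field
    condition number; raises :class:`GeometryRankError` when the
    geometry cannot resolve all three dipole components.
    """
    if ensemble.waveform.shape[0] != geometry.n_channels:
        raise ValueError("ensemble channel count does not match geometry")
    if source_position is None:
        source_position = estimate_source_position(ensemble, geometry)
    source_position = np.asarray(source_position, dtype=float)
    weights = _channel_weights(ensemble)
    L = weights[:, None] * lead_field(source_position, np.eye(3), geometry)
    u, s, vt = np.linalg.svd(L, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        raise GeometryRankError(
            "geometry cannot resolve a 3-D dipole at this source position (rank < 3)"
        )
    cond = float(s[0] / s[-1])
    y = ensemble.waveform - ensemble.waveform.mean(axis=1, keepdims=True)
    y = weights[:, None] * y
    loop = (vt.T @ np.diag(1.0 / s) @ u.T @ y).T  # (w, 3)

    r = ensemble.r_index
    half = int(round(QRS_HALF_WIDTH_S * ensemble.sampling_rate))
    lo, hi = max(r - half, 0), min(r + half, loop.shape[0])
    qrs = loop[lo:hi]
    norms = np.linalg.norm(qrs, axis=1)
    if norms.max() == 0:
        raise ValueError("QRS excursion is zero; dominant axis undefined")
    # principal direction of the QRS loop segment, signed by the point
    # of maximal excursion: robust to pointwise contamination of the
    # ensemble, unlike the single max-norm sample
    _, _, vt = np.linalg.svd(qrs, full_matrices=False)
    axis = vt[0]
    peak = qrs[int(np.argmax(norms))]
    axis = axis * np.sign(axis @ peak + 1e-300)

    presentation, side = _orientation_from_axis(axis, source_position)
    return Vectorcardiogram(
        fetus_label=ensemble.fetus_label,
        loop=loop,
        time_ms=ensemble.time_ms,
        dominant_axis=axis,
        presentation=presentation,
        side=side,
        condition_number=cond,
        source_position=source_position,
    )


def _orientation_from_axis(axis: np.ndarray, source_position: np.ndarray) -> tuple[str, str]:
    if axis[1] > PRESENTATION_Y_THRESHOLD:
        presentation = "cephalic"
    elif axis[1] < -PRESENTATION_Y_THRESHOLD:
        presentation = "breech"
    else:
        presentation = "indeterminate"
    side = "left" if source_position[0] > 0 else "right"
    return presentation, side


def estimate_orientation(vcg: Vectorcardiogram) -> tuple[str, str]:
    """Presentation and side from the dominant QRS axis.

    Deterministic: presentation from the sign of the craniocaudal (y)
    component of the dominant axis under the normal-heart-axis
    assumption; ``indeterminate`` when |y| < 0.1 (near-transverse
    axis) rather than a guess. Side from the source-position x sign.
    """
    if np.linalg.norm(vcg.dominant_axis) == 0:
        raise ValueError("dominant axis undefined")
    return _orientation_from_axis(vcg.dominant_axis, vcg.source_position)


def vcg_axis_angle(vcg1: Vectorcardiogram | np.ndarray, vcg2: Vectorcardiogram | np.ndarray) -> float:
    """Angle in degrees between two dominant QRS axes, on [0°, 180°].

    Sign-aware: an axis and its negation are 180° apart (the
    cephalic-vs-breech signature), not 0°.
    """
    a = vcg1.dominant_axis if isinstance(vcg1, Vectorcardiogram) else np.asarray(vcg1, float)
    b = vcg2.dominant_axis if isinstance(vcg2, Vectorcardiogram) else np.asarray(vcg2, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm axis")
    cosang = float(a @ b) / (na * nb)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
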