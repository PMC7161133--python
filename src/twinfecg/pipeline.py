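"""End-to-end twin NI-fECG pipeline.

Chains preprocessing, maternal suppression, twin separation, per-fetus
QRS detection, distinctness checking, FHR traces, ensemble averaging
and vectorcardiogram reconstruction, and gathers a machine-readable
run report. The fetus with the lower mean heart rate is labelled
fetus A (deterministic labelling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FETUS_A, FETUS_B, BeatAnnotation, Recording, TwinsNotSeparableError
from .ensemble import DEFAULT_ENSEMBLE_WINDOW_MS, EnsembleComplex, ensemble_for_fetus
from .fhr_output import FHRTrace, compute_fhr, resample_trace
from .maternal_suppression import TemplateModel, suppress_maternal
from .preprocess import PreprocessConfig, preprocess_recording
from .twin_separation import (
    CombinationWeights,
    check_twin_distinctness,
    derive_combination_weights,
    detect_candidate_beats,
    detect_fetal_qrs,
    DistinctnessReport,
)
from .vcg import Vectorcardiogram, compute_vcg


@dataclass
class PipelineResult:
    preprocessed: Recording
    residual: Recording
    maternal_beats: BeatAnnotation
    template_model: TemplateModel
    weights: CombinationWeights
    fetal_beats: dict[str, BeatAnnotation]
    traces: dict[str, FHRTrace]
    ensembles: dict[str, EnsembleComplex]
    vcgs: dict[str, Vectorcardiogram]
    distinctness: DistinctnessReport | None
    report: dict = field(default_factory=dict)


def run_pipeline(
    recording: Recording,
    geometry=None,
    preprocess_config: PreprocessConfig | None = None,
    ensemble_window_ms: tuple[float, float] = DEFAULT_ENSEMBLE_WINDOW_MS,
    manual_weights: CombinationWeights | None = None,
    source_positions: dict[str, np.ndarray] | None = None,
    expect_twins: bool = True,
) -> PipelineResult:
    """Run the full analysis on a six-channel abdominal recording.

    ``manual_weights`` bypasses automatic weight derivation (fidelity
    mode mirroring manually chosen combinations). ``source_positions``
    optionally supplies ultrasound-derived fetal heart coordinates per
    fetus label for the VCG inverse. When ``expect_twins`` and only one
    separable fetal rhythm is found, a
    :class:`~twinfecg.core.TwinsNotSeparableError` propagates.
    """
    pre = preprocess_recording(recording, preprocess_config)
    residual, maternal_beats, model = suppress_maternal(pre)

    if manual_weights is not None:
        weights = manual_weights
        trains = None
    else:
        candidates = detect_candidate_beats(residual)
        try:
            weights, trains = derive_combination_weights(residual, candidates)
        except TwinsNotSeparableError:
            if expect_twins:
                raise
            # single-fetus analysis: fall back to the strongest train
            from .twin_separation import cluster_candidate_trains

            trains = cluster_candidate_trains(candidates, residual.sampling_rate)
            if not trains:
                raise
            weights, trains = derive_combination_weights(residual, trains=trains[:1])
    if expect_twins and weights.w_B is None:
        raise TwinsNotSeparableError(
            "twins not separable: only one fetal rhythm could be isolated",
            {"quality": weights.quality},
        )

    fetal_beats: dict[str, BeatAnnotation] = {}
    per_w = {"first": weights.w_A}
    if weights.w_B is not None:
        per_w["second"] = weights.w_B
    detected = {}
    for name, w in per_w.items():
        enhanced = Recording(
            (np.asarray(w) @ residual.samples)[None, :], residual.sampling_rate
        )
        detected[name] = detect_fetal_qrs(enhanced, label=name)

    # deterministic labelling: lower mean rate -> fetus A
    def mean_rate(ann: BeatAnnotation) -> float:
        if len(ann) < 2:
            return np.inf
        return 60.0 * residual.sampling_rate / np.mean(np.diff(ann.r_samples))

    if len(detected) == 2:
        names = sorted(detected, key=lambda k: mean_rate(detected[k]))
        mapping = {names[0]: FETUS_A, names[1]: FETUS_B}
        if mapping["first"] == FETUS_B:
            weights = CombinationWeights(
                w_A=weights.w_B, w_B=weights.w_A, method=weights.method,
                quality={
                    "fetusA_db": weights.quality.get("fetusB_db", np.nan),
                    "fetusB_db": weights.quality.get("fetusA_db", np.nan),
                },
            )
    else:
        mapping = {"first": FETUS_A}
    for name, ann in detected.items():
        label = mapping[name]
        fetal_beats[label] = BeatAnnotation(
            label=label, r_samples=ann.r_samples, confidence=ann.confidence
        )

    distinctness = None
    if len(fetal_beats) == 2:
        distinctness = check_twin_distinctness(
            fetal_beats[FETUS_A], fetal_beats[FETUS_B], residual.sampling_rate
        )

    traces = {}
    for label, ann in fetal_beats.items():
        if len(ann) >= 2:
            traces[label] = resample_trace(compute_fhr(ann, residual.sampling_rate))
    if len(maternal_beats) >= 2:
        traces["maternal"] = resample_trace(
            compute_fhr(maternal_beats, residual.sampling_rate)
        )

    ensembles = {}
    vcgs = {}
    for label, ann in fetal_beats.items():
        if len(ann) < 1:
            continue
        try:
            ens = ensemble_for_fetus(residual, ann, window_ms=ensemble_window_ms)
        except ValueError:
            # correlation gating rejected every beat (weak fetal signal);
            # fall back to the plain mean rather than aborting the run
            ens = ensemble_for_fetus(residual, ann, window_ms=ensemble_window_ms,
                                     rejection="none")
        ensembles[label] = ens
        if geometry is not None:
            pos = (source_positions or {}).get(label)
            vcgs[label] = compute_vcg(ens, geometry, source_position=pos)

    report = {
        "n_maternal_beats": len(maternal_beats),
        "weights_quality_db": weights.quality,
        "fetal_beat_counts": {k: len(v) for k, v in fetal_beats.items()},
        "mean_fhr_bpm": {
            k: float(np.mean(tr.valid_values())) if tr.valid_values().size else None
            for k, tr in traces.items()
        },
        "distinctness": {
            "coincidence_fraction": distinctness.coincidence_fraction,
            "flagged": distinctness.flagged,
        }
        if distinctness is not None
        else None,
        "presentations": {
            k: {"presentation": v.presentation, "side": v.side,
                "condition_number": v.condition_number}
            for k, v in vcgs.items()
        },
    }
    return PipelineResult(
        preprocessed=pre,
        residual=residual,
        maternal_beats=maternal_beats,
        template_model=model,
        weights=weights,
        fetal_beats=fetal_beats,
        traces=traces,
        ensembles=ensembles,
        vcgs=vcgs,
        distinctness=distinctness,
        report=report,
    )
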