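"""Plain-text persistence for recordings, beat annotations and FHR traces.

Native on-disk layout for a record named ``rec``:

* ``rec.csv``  — samples, one column per channel, in µV.
* ``rec.json`` — header: sampling rate, channel labels, start time, units,
  free-text provenance, optional electrode geometry.
* ``rec.beats.csv`` — optional annotations, columns ``label,sample``.

FHR traces export as RFC-4180 CSV with one row per heartbeat interval;
missing values are left as empty cells, never interpolated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BeatAnnotation, ElectrodePatchGeometry, Recording

_QUANT_BITS = 16


@dataclass
class DatasetBundle:
    recording: Recording
    annotations: list[BeatAnnotation] = field(default_factory=list)
    geometry: ElectrodePatchGeometry | None = None
    provenance: str = ""

    def __post_init__(self):
        n = self.recording.n_samples
        for ann in self.annotations:
            if ann.r_samples.size and (ann.r_samples[0] < 0 or ann.r_samples[-1] >= n):
                raise ValueError(f"annotation {ann.label!r} indices exceed recording length")


def _geometry_to_dict(g: ElectrodePatchGeometry) -> dict:
    return {
        "electrode_positions": g.electrode_positions.tolist(),
        "ground_index": int(g.ground_index),
        "reference_index": int(g.reference_index),
        "derivation_matrix": g.derivation_matrix.tolist(),
    }


def _geometry_from_dict(d: dict) -> ElectrodePatchGeometry:
    return ElectrodePatchGeometry(
        electrode_positions=np.asarray(d["electrode_positions"], dtype=float),
        ground_index=int(d["ground_index"]),
        reference_index=int(d["reference_index"]),
        derivation_matrix=np.asarray(d["derivation_matrix"], dtype=float),
    )


def write_recording(bundle: DatasetBundle | Recording, path_prefix: str | Path,
                    quantize: bool = False) -> Path:
    """Write a record as ``<prefix>.csv`` + ``<prefix>.json`` (+ beats CSV).

    With ``quantize`` the samples are stored as 16-bit integers over the
    observed range (gain/offset recorded in the header), emulating the
    resolution of digitizing front-ends.
    """
    if isinstance(bundle, Recording):
        bundle = DatasetBundle(recording=bundle)
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rec = bundle.recording

    header = {
        "sampling_rate": rec.sampling_rate,
        "channel_labels": rec.channel_labels,
        "start_time": rec.start_time,
        "units": "uV",
        "provenance": bundle.provenance,
    }
    data = rec.samples.T
    if quantize:
        lo = float(data.min())
        hi = float(data.max())
        span = (hi - lo) or 1.0
        gain = span / (2**_QUANT_BITS - 1)
        q = np.round((data - lo) / gain).astype(np.int32)
        header["quantization"] = {"gain": gain, "offset": lo, "bits": _QUANT_BITS}
        df = pd.DataFrame(q, columns=rec.channel_labels)
    else:
        df = pd.DataFrame(data, columns=rec.channel_labels)
    if bundle.geometry is not None:
        header["geometry"] = _geometry_to_dict(bundle.geometry)
    df.to_csv(prefix.with_suffix(".csv"), index=False,
              float_format=None if quantize else "%.6f")
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))
    if bundle.annotations:
        rows = [
            {"label": ann.label, "sample": int(s)}
            for ann in bundle.annotations
            for s in ann.r_samples
        ]
        pd.DataFrame(rows).to_csv(prefix.with_suffix(".beats.csv"), index=False)
    return prefix


def read_recording(path_prefix: str | Path, format: str = "csv") -> DatasetBundle:
    """Read a record written by :func:`write_recording`.

    Samples are returned in µV with any stored quantization gain/offset
    applied. Raises ``FileNotFoundError`` naming the path when the record
    does not exist. A channel count other than six only warns downstream
    (stages that require the 6-channel patch validate it themselves).
    """
    if format != "csv":
        raise ValueError(
            f"unsupported format {format!r}: this build persists records as CSV+JSON text"
        )
    prefix = Path(path_prefix)
    header_path = prefix.with_suffix(".json")
    csv_path = prefix.with_suffix(".csv")
    for p in (header_path, csv_path):
        if not p.exists():
            raise FileNotFoundError(f"record file not found: {p}")
    header = json.loads(header_path.read_text())
    df = pd.read_csv(csv_path)
    data = df.to_numpy(dtype=float).T
    quant = header.get("quantization")
    if quant:
        data = data * quant["gain"] + quant["offset"]
    rec = Recording(
        samples=data,
        sampling_rate=header["sampling_rate"],
        channel_labels=list(header["channel_labels"]),
        start_time=header.get("start_time", 0.0),
    )
    if rec.n_channels != 6:
        warnings.warn(
            f"record has {rec.n_channels} channels; the twin pipeline expects the "
            "6-channel abdominal patch",
            stacklevel=2,
        )
    annotations: list[BeatAnnotation] = []
    beats_path = prefix.with_suffix(".beats.csv")
    if beats_path.exists():
        bdf = pd.read_csv(beats_path)
        for label, grp in bdf.groupby("label", sort=False):
            annotations.append(BeatAnnotation(label=str(label), r_samples=np.sort(grp["sample"].to_numpy())))
    geometry = _geometry_from_dict(header["geometry"]) if "geometry" in header else None
    return DatasetBundle(recording=rec, annotations=annotations, geometry=geometry,
                         provenance=header.get("provenance", ""))


def write_fhr_csv(traces, path: str | Path) -> Path:
    """Export FHR traces as one CSV with per-fetus columns.

    ``traces`` is a non-empty list of :class:`~twinfecg.fhr_output.FHRTrace`.
    Columns: ``time_s``, then ``fhr_bpm_<label>`` (or ``maternal_hr_bpm``
    for the maternal trace) per trace. Each row is one heartbeat interval
    of some trace, indexed by the interval's end-beat time; gaps stay
    empty.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("traces must be non-empty")
    frames = []
    for tr in traces:
        col = "maternal_hr_bpm" if tr.fetus_label == "maternal" else f"fhr_bpm_{tr.fetus_label}"
        vals = np.where(tr.gap_mask, np.nan, tr.fhr_bpm)
        frames.append(pd.DataFrame({"time_s": np.round(tr.beat_times[1:], 6), col: vals}))
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on="time_s", how="outer")
    out = out.sort_values("time_s").reset_index(drop=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format="%.3f")
    return path


def read_fhr_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FHR file not found: {path}")
    return pd.read_csv(path)
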