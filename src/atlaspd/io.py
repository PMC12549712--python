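"""Reading and writing cohorts: SNIRF (HDF5) and a flat CSV dialect.

The SNIRF writer emits a minimal, valid continuous-wave file per subject
(`/nirs/data1/dataTimeSeries` with one measurementList entry per
channel-wavelength pair, probe wavelengths 695/830 nm).  The CSV dialect is
one file per subject with wavelength-suffixed channel columns
(``CH01@695nm``, ``CH01@830nm``, ...) plus a cohort-level ``labels.csv``
(subject_id,label).  Processed tensors round-trip through HDF5 with labels,
channel ids, and the provenance log stored alongside the data.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import BlockDesign
from .layout import ChannelLayout, default_layout
from .optics import WAVELENGTHS_NM
from .preprocess import DatasetTensor
from .synthgen import OpticalRecording, SubjectRecord

__all__ = [
    "write_snirf", "read_snirf", "write_cohort",
    "read_cohort_csv", "save_dataset", "load_dataset",
]


def _str_dataset(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def write_snirf(record: SubjectRecord, path: str | Path) -> Path:
    """Write one subject's raw intensity as a SNIRF (HDF5) file."""
    path = Path(path)
    rec = record.recording
    c, t, _ = rec.intensity.shape
    with h5py.File(path, "w") as f:
        _str_dataset(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _str_dataset(meta, "SubjectID", record.subject_id)
        _str_dataset(meta, "MeasurementDate", "unknown")
        _str_dataset(meta, "MeasurementTime", "unknown")
        _str_dataset(meta, "LengthUnit", "cm")
        _str_dataset(meta, "TimeUnit", "s")
        _str_dataset(meta, "FrequencyUnit", "Hz")
        _str_dataset(meta, "Label", record.label)
        meta.create_dataset("SamplingHz", data=float(rec.sampling_hz))
        _str_dataset(meta, "Design", json.dumps({
            "pre_task_s": rec.design.pre_task_s,
            "rest_before_s": rec.design.rest_before_s,
            "task_s": rec.design.task_s,
            "rest_after_s": rec.design.rest_after_s,
            "n_cycles": rec.design.n_cycles,
            "total_s": rec.design.total_s,
            "sampling_hz": rec.design.sampling_hz,
        }))

        data = nirs.create_group("data1")
        series = np.empty((t, 2 * c))
        for i in range(c):
            series[:, 2 * i] = rec.intensity[i, :, 0]
            series[:, 2 * i + 1] = rec.intensity[i, :, 1]
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.array([0.0, 1.0 / rec.sampling_hz]))
        for i in range(c):
            for w in range(2):
                ml = data.create_group(f"measurementList{2 * i + w + 1}")
                ml.create_dataset("sourceIndex", data=i + 1)
                ml.create_dataset("detectorIndex", data=i + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm))
        # abstract one source/detector pair per channel on a line, 3 cm apart
        d = rec.layout.source_detector_distance_cm
        probe.create_dataset("sourcePos3D",
                             data=np.c_[np.arange(c) * d, np.zeros(c), np.zeros(c)])
        probe.create_dataset("detectorPos3D",
                             data=np.c_[np.arange(c) * d, np.full(c, d), np.zeros(c)])
    return path


def read_snirf(path: str | Path, layout: ChannelLayout | None = None) -> SubjectRecord:
    """Read a SNIRF file written by :func:`write_snirf`."""
    layout = layout or default_layout()
    with h5py.File(path, "r") as f:
        meta = f["nirs/metaDataTags"]
        subject_id = meta["SubjectID"][()].decode()
        label = meta["Label"][()].decode()
        fs = float(meta["SamplingHz"][()])
        design = BlockDesign(**json.loads(meta["Design"][()].decode()))
        series = f["nirs/data1/dataTimeSeries"][()]
        wavelengths = tuple(f["nirs/probe/wavelengths"][()])
    t, cw = series.shape
    c = cw // 2
    intensity = np.empty((c, t, 2))
    for i in range(c):
        intensity[i, :, 0] = series[:, 2 * i]
        intensity[i, :, 1] = series[:, 2 * i + 1]
    rec = OpticalRecording(intensity, wavelengths, fs, layout, design)
    return SubjectRecord(subject_id, label, rec, np.full(c, np.nan))


def write_cohort(cohort: list[SubjectRecord], out_dir: str | Path,
                 fmt: str = "snirf") -> Path:
    """Write a cohort as SNIRF or CSV files plus a labels.csv index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        if fmt == "snirf":
            write_snirf(rec, out_dir / f"{rec.subject_id}.snirf")
        elif fmt == "csv":
            _write_subject_csv(rec, out_dir / f"{rec.subject_id}.csv")
        else:
            raise ValueError(f"unknown format {fmt!r}")
        rows.append({"subject_id": rec.subject_id, "label": rec.label})
    pd.DataFrame(rows).to_csv(out_dir / "labels.csv", index=False)
    if fmt == "csv":
        d = cohort[0].recording.design
        (out_dir / "design.json").write_text(json.dumps({
            "pre_task_s": d.pre_task_s, "rest_before_s": d.rest_before_s,
            "task_s": d.task_s, "rest_after_s": d.rest_after_s,
            "n_cycles": d.n_cycles, "total_s": d.total_s,
            "sampling_hz": d.sampling_hz,
        }))
    return out_dir


def _write_subject_csv(record: SubjectRecord, path: Path) -> None:
    rec = record.recording
    c = rec.intensity.shape[0]
    cols = {}
    for i, ch in enumerate(rec.layout.channel_ids[:c]):
        for w, wl in enumerate(rec.wavelengths_nm):
            cols[f"{ch}@{int(wl)}nm"] = rec.intensity[i, :, w]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_cohort_csv(in_dir: str | Path,
                    layout: ChannelLayout | None = None) -> list[SubjectRecord]:
    """Read a CSV cohort written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    layout = layout or default_layout()
    design = BlockDesign(**json.loads((in_dir / "design.json").read_text()))
    labels = pd.read_csv(in_dir / "labels.csv").set_index("subject_id")["label"]
    cohort = []
    for sid, label in labels.items():
        df = pd.read_csv(in_dir / f"{sid}.csv")
        c = layout.n_channels
        intensity = np.empty((c, len(df), 2))
        for i, ch in enumerate(layout.channel_ids):
            for w, wl in enumerate(WAVELENGTHS_NM):
                intensity[i, :, w] = df[f"{ch}@{int(wl)}nm"].to_numpy()
        rec = OpticalRecording(intensity, WAVELENGTHS_NM, design.sampling_hz,
                               layout, design)
        cohort.append(SubjectRecord(str(sid), str(label), rec, np.full(c, np.nan)))
    return cohort


def save_dataset(dataset: DatasetTensor, path: str | Path) -> Path:
    """Persist a processed tensor (HDF5 with labels and provenance)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=dataset.data)
        f.create_dataset("labels",
                         data=np.asarray(dataset.labels, dtype="S16"))
        f.create_dataset("channel_ids",
                         data=np.asarray(dataset.channel_ids, dtype="S8"))
        f.attrs["sampling_hz"] = dataset.sampling_hz
        f.attrs["normalized"] = dataset.normalized
        f.attrs["provenance"] = json.dumps(dataset.provenance)
        if dataset.excluded is not None:
            f.create_dataset("excluded", data=dataset.excluded)
        if dataset.design is not None:
            d = dataset.design
            f.attrs["design"] = json.dumps({
                "pre_task_s": d.pre_task_s, "rest_before_s": d.rest_before_s,
                "task_s": d.task_s, "rest_after_s": d.rest_after_s,
                "n_cycles": d.n_cycles, "total_s": d.total_s,
                "sampling_hz": d.sampling_hz,
            })
    return path


def load_dataset(path: str | Path) -> DatasetTensor:
    with h5py.File(path, "r") as f:
        design = None
        if "design" in f.attrs:
            design = BlockDesign(**json.loads(f.attrs["design"]))
        return DatasetTensor(
            data=f["data"][()],
            labels=np.asarray([s.decode() for s in f["labels"][()]]),
            channel_ids=tuple(s.decode() for s in f["channel_ids"][()]),
            sampling_hz=float(f.attrs["sampling_hz"]),
            design=design,
            excluded=f["excluded"][()] if "excluded" in f else None,
            normalized=bool(f.attrs["normalized"]),
            provenance=json.loads(f.attrs["provenance"]),
        )
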