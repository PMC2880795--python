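"""Plain-text file round-trips.

ERP matrices travel as TSV (column 1 = time_ms, then the channels in
canonical order) with a JSON sidecar carrying subject_id, group,
condition and sampling_rate_hz; a dataset is a directory of such pairs.
Decompositions are JSON; feature matrices are CSV; epoch sets are a
single concatenated TSV with an epoch-index column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .ica import MixingModel
from .synth import EpochSet, ERPDataset, GaussianBump, GroundTruth, SubjectERP

_SIDECAR_KEYS = ("subject_id", "group", "condition", "sampling_rate_hz")


def write_subject_erp(erp: SubjectERP, path: Path) -> None:
    path = Path(path)
    df = pd.DataFrame(erp.data.T, columns=list(erp.channel_order))
    df.insert(0, "time_ms", erp.time_ms)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    sidecar = {
        "subject_id": erp.subject_id,
        "group": erp.group,
        "condition": erp.condition,
        "sampling_rate_hz": erp.sampling_rate_hz,
        "channel_order": list(erp.channel_order),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_subject_erp(path: Path, expected_channels: int = 19) -> SubjectERP:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path} for {path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _SIDECAR_KEYS:
        if key not in sidecar:
            raise ValueError(f"sidecar {sidecar_path} lacks required key {key!r}")
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "time_ms":
        raise ValueError(f"{path}: first column must be time_ms")
    channels = tuple(df.columns[1:])
    if len(channels) != expected_channels:
        raise ValueError(f"{path}: expected {expected_channels} channel columns, found {len(channels)}")
    if "channel_order" in sidecar and tuple(sidecar["channel_order"]) != channels:
        raise ValueError(f"{path}: TSV channel columns disagree with sidecar channel_order")
    time_ms = df["time_ms"].to_numpy(dtype=float)
    steps = np.diff(time_ms)
    if time_ms.size > 1 and not np.allclose(steps, steps[0], atol=1e-6):
        raise ValueError(f"{path}: non-uniform time axis")
    return SubjectERP(
        data=df[list(channels)].to_numpy(dtype=float).T,
        time_ms=time_ms,
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        subject_id=str(sidecar["subject_id"]),
        group=str(sidecar["group"]),
        condition=str(sidecar["condition"]),
        channel_order=channels,
    )


def write_dataset(dataset: ERPDataset, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for erp in dataset.subjects:
        write_subject_erp(erp, directory / f"{erp.subject_id}__{erp.condition}.tsv")
    (directory / "provenance.json").write_text(json.dumps(dataset.provenance, indent=1, default=str))


def read_dataset(directory: Path, expected_channels: int = 19) -> ERPDataset:
    directory = Path(directory)
    files = sorted(directory.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no .tsv ERP files under {directory}")
    subjects = [read_subject_erp(f, expected_channels) for f in files]
    rates = {s.sampling_rate_hz for s in subjects}
    if len(rates) > 1:
        raise ValueError(f"inconsistent sampling rates across subjects: {rates}")
    orders = {s.channel_order for s in subjects}
    if len(orders) > 1:
        raise ValueError("inconsistent channel order across subjects")
    prov_file = directory / "provenance.json"
    provenance = json.loads(prov_file.read_text()) if prov_file.exists() else {"origin": str(directory)}
    return ERPDataset(subjects=subjects, provenance=provenance)


def write_ground_truth(gt: GroundTruth, path: Path) -> None:
    payload = {
        "channel_order": list(gt.channel_order),
        "topographies": gt.topographies.tolist(),  # row-major, channels x sources
        "waveforms": [
            {
                cond: [
                    {"center_ms": b.center_ms, "width_ms": b.width_ms, "amplitude_uv": b.amplitude_uv}
                    for b in bumps
                ]
                for cond, bumps in wf.items()
            }
            for wf in gt.waveforms
        ],
        "extremum_latency_ms": list(gt.extremum_latency_ms),
        "extremum_amplitude_uv": list(gt.extremum_amplitude_uv),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        topographies=np.array(d["topographies"], dtype=float),
        waveforms=tuple(
            {cond: tuple(GaussianBump(**b) for b in bumps) for cond, bumps in wf.items()}
            for wf in d["waveforms"]
        ),
        channel_order=tuple(d["channel_order"]),
        extremum_latency_ms=tuple(d["extremum_latency_ms"]),
        extremum_amplitude_uv=tuple(d["extremum_amplitude_uv"]),
    )


def write_model(model: MixingModel, path: Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_model(path: Path) -> MixingModel:
    return MixingModel.from_dict(json.loads(Path(path).read_text()))


def write_feature_matrix(fm: FeatureMatrix, path: Path) -> None:
    fm.to_frame().to_csv(path, index=False, float_format="%.9g")


def read_feature_matrix(path: Path) -> FeatureMatrix:
    return FeatureMatrix.from_frame(pd.read_csv(path))


def write_epochs(epochs: EpochSet, path: Path) -> None:
    frames = []
    for i, e in enumerate(epochs.epochs):
        df = pd.DataFrame(e.T, columns=[f"ch{j}" for j in range(e.shape[0])])
        df.insert(0, "epoch", i)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = {
        "sampling_rate_hz": epochs.sampling_rate_hz,
        "rejected": epochs.rejected.tolist(),
        "reasons": [list(r) for r in epochs.reasons],
        "planted_labels": epochs.planted_labels,
    }
    Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_epochs(path: Path) -> EpochSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    chans = [c for c in df.columns if c != "epoch"]
    epochs = [
        df.loc[df["epoch"] == i, chans].to_numpy(dtype=float).T
        for i in sorted(df["epoch"].unique())
    ]
    return EpochSet(
        epochs=epochs,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        rejected=np.array(meta["rejected"], dtype=bool),
        reasons=[tuple(r) for r in meta["reasons"]],
        planted_labels=meta.get("planted_labels"),
    )
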