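"""Plain-text serialization of recordings, spike matrices and bases.

Recordings are written as flat little-endian float32 binary (channel-major)
with a JSON sidecar; ground truth and waveform matrices go to CSV so every
artefact can be inspected with standard tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .codec import CompressionBasis
from .detection import SpikeMatrix
from .synthdata import Recording


def save_recording(recording: Recording, stem: str | Path) -> None:
    """Write ``<stem>.f32`` (samples), ``<stem>.json`` (metadata),
    ``<stem>.truth.csv`` (time_s, neuron_id) and ``<stem>.templates.csv``."""
    stem = Path(stem)
    recording.samples.astype("<f4").tofile(stem.with_suffix(".f32"))
    meta = {
        "fs": recording.fs,
        "n_channels": recording.n_channels,
        "duration": recording.duration,
        "band": list(recording.band),
        "target_ids": recording.target_ids.tolist(),
        "template_shape": list(recording.templates.shape),
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    rows = [
        {"time_s": float(t), "neuron_id": int(nid)}
        for nid in recording.target_ids
        for t in recording.true_spike_times[nid]
    ]
    pd.DataFrame(rows).sort_values("time_s").to_csv(stem.with_suffix(".truth.csv"), index=False)
    flat = recording.templates.reshape(-1, recording.templates.shape[-1])
    pd.DataFrame(flat).to_csv(stem.with_suffix(".templates.csv"), index=False)


def load_recording(stem: str | Path) -> Recording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    samples = np.fromfile(stem.with_suffix(".f32"), dtype="<f4").astype(float)
    samples = samples.reshape(meta["n_channels"], -1)
    truth = pd.read_csv(stem.with_suffix(".truth.csv"))
    target_ids = np.asarray(meta["target_ids"], int)
    times = [
        truth.loc[truth["neuron_id"] == nid, "time_s"].to_numpy() for nid in target_ids
    ]
    tmpl_shape = tuple(meta["template_shape"])
    templates = pd.read_csv(stem.with_suffix(".templates.csv")).to_numpy().reshape(tmpl_shape)
    return Recording(
        samples=samples,
        fs=meta["fs"],
        true_spike_times=times,
        neuron_ids=target_ids,
        templates=templates,
        band=tuple(meta["band"]),
        duration=meta["duration"],
        target_ids=target_ids,
    )


def save_spike_matrix(spikes: SpikeMatrix, stem: str | Path) -> None:
    """Write ``<stem>.csv`` (one column per spike) + ``<stem>.json``."""
    stem = Path(stem)
    pd.DataFrame(spikes.waveforms).to_csv(stem.with_suffix(".csv"), index=False)
    meta = {
        "fs": spikes.fs,
        "detection_index": spikes.detection_index.tolist(),
        "true_ids": spikes.true_ids.tolist(),
        "retained_mask": spikes.retained_mask.astype(int).tolist(),
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_spike_matrix(stem: str | Path) -> SpikeMatrix:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    waveforms = pd.read_csv(stem.with_suffix(".csv")).to_numpy()
    return SpikeMatrix(
        waveforms=waveforms,
        detection_index=np.asarray(meta["detection_index"], int),
        true_ids=np.asarray(meta["true_ids"], int),
        fs=meta["fs"],
        retained_mask=np.asarray(meta["retained_mask"], bool),
    )


def save_basis(basis: CompressionBasis, stem: str | Path) -> None:
    stem = Path(stem)
    pd.DataFrame(basis.W).to_csv(stem.with_suffix(".csv"), index=False)
    meta = {
        "kind": basis.kind,
        "M": basis.M,
        "interpolation_required": basis.interpolation_required,
        "singular_values": None
        if basis.singular_values is None
        else basis.singular_values.tolist(),
        "downsample_factor": basis.downsample_factor,
        "kept_rows": None if basis.kept_rows is None else basis.kept_rows.tolist(),
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_basis(stem: str | Path) -> CompressionBasis:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    W = pd.read_csv(stem.with_suffix(".csv")).to_numpy()
    return CompressionBasis(
        W=W,
        kind=meta["kind"],
        interpolation_required=meta["interpolation_required"],
        singular_values=None
        if meta["singular_values"] is None
        else np.asarray(meta["singular_values"]),
        downsample_factor=meta["downsample_factor"],
        kept_rows=None if meta["kept_rows"] is None else np.asarray(meta["kept_rows"], int),
    )
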