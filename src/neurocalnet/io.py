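"""Plain-format readers and writers for the pipeline's objects.

Movies travel as multi-page TIFF (uint16), traces and ΔF/F as CSV
(neurons x frames) or HDF5 groups, ROI sets as a JSON mask list plus an
optional label-image TIFF, events and sweeps as CSV with a small JSON
sidecar for acquisition metadata.  Vendor acquisition formats are out of
scope by design.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from neurocalnet.calcium import DffMatrix, TraceMatrix, TransientEvent
from neurocalnet.ephys import EphysSweep
from neurocalnet.roi import FluorescenceMovie, RoiSet

__all__ = [
    "read_movie",
    "write_movie",
    "read_traces_csv",
    "write_traces_csv",
    "read_traces_hdf5",
    "write_traces_hdf5",
    "write_roiset",
    "read_roiset",
    "write_events_csv",
    "read_events_csv",
    "read_sweep_csv",
    "write_sweep_csv",
]


def write_movie(path: str | Path, movie: FluorescenceMovie) -> None:
    data = np.clip(movie.data, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"frame_rate_hz": movie.frame_rate})


def read_movie(path: str | Path, frame_rate: float | None = None) -> FluorescenceMovie:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if frame_rate is None:
            meta = tf.shaped_metadata or tf.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            frame_rate = float(meta.get("frame_rate_hz", 30.0))
    return FluorescenceMovie(data=np.asarray(data, dtype=float), frame_rate=frame_rate)


def write_traces_csv(path: str | Path, traces: TraceMatrix) -> None:
    traces.to_frame().to_csv(path)


def read_traces_csv(path: str | Path, frame_rate: float = 30.0) -> TraceMatrix:
    df = pd.read_csv(path, index_col=0)
    return TraceMatrix(values=df.to_numpy(), frame_rate=frame_rate,
                       labels=[str(i) for i in df.index])


def write_traces_hdf5(path: str | Path, traces: TraceMatrix,
                      dff: DffMatrix | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("traces")
        g.create_dataset("values", data=traces.values)
        g.attrs["frame_rate"] = traces.frame_rate
        g.create_dataset(
            "labels", data=np.array(traces.labels, dtype=h5py.string_dtype())
        )
        if dff is not None:
            gd = f.create_group("dff")
            gd.create_dataset("dff", data=dff.dff)
            gd.create_dataset("baseline_f0", data=dff.baseline_f0)
            gd.attrs["frame_rate"] = dff.frame_rate
            gd.attrs["method"] = json.dumps(dff.method)


def read_traces_hdf5(path: str | Path) -> TraceMatrix:
    with h5py.File(path, "r") as f:
        g = f["traces"]
        return TraceMatrix(
            values=g["values"][()],
            frame_rate=float(g.attrs["frame_rate"]),
            labels=[s.decode() if isinstance(s, bytes) else str(s)
                    for s in g["labels"][()]],
        )


def write_roiset(path: str | Path, rois: RoiSet,
                 label_tiff: str | Path | None = None) -> None:
    payload = {
        "frame_shape": list(rois.frame_shape),
        "labels": rois.labels,
        "masks": [np.argwhere(m).tolist() for m in rois.masks],
    }
    Path(path).write_text(json.dumps(payload))
    if label_tiff is not None:
        tifffile.imwrite(label_tiff, rois.label_image().astype(np.uint16))


def read_roiset(path: str | Path) -> RoiSet:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["frame_shape"])
    masks = []
    for px in payload["masks"]:
        m = np.zeros(shape, dtype=bool)
        idx = np.asarray(px, dtype=int)
        m[idx[:, 0], idx[:, 1]] = True
        masks.append(m)
    return RoiSet(masks=masks, frame_shape=shape, labels=payload["labels"])


def write_events_csv(path: str | Path, events: list[TransientEvent],
                     frame_rate: float) -> None:
    rows = [
        {
            "neuron": ev.neuron,
            "onset_s": ev.onset_frame / frame_rate,
            "peak_s": ev.peak_frame / frame_rate,
            "amplitude_pct": ev.amplitude,
            "rise_s": ev.rise_time,
            "decay_s": ev.decay_time,
            "shape_ok": ev.shape_ok,
        }
        for ev in events
    ]
    pd.DataFrame(
        rows,
        columns=["neuron", "onset_s", "peak_s", "amplitude_pct", "rise_s",
                 "decay_s", "shape_ok"],
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path, frame_rate: float) -> list[TransientEvent]:
    df = pd.read_csv(path)
    return [
        TransientEvent(
            neuron=int(r.neuron),
            onset_frame=int(round(r.onset_s * frame_rate)),
            peak_frame=int(round(r.peak_s * frame_rate)),
            amplitude=float(r.amplitude_pct),
            rise_time=float(r.rise_s),
            decay_time=float(r.decay_s),
            shape_ok=bool(r.shape_ok),
        )
        for r in df.itertuples()
    ]


def write_sweep_csv(path: str | Path, sweep: EphysSweep,
                    sidecar: str | Path | None = None) -> None:
    pd.DataFrame({"time_s": sweep.time, "signal": sweep.signal}).to_csv(
        path, index=False
    )
    meta = {
        "sampling_rate": sweep.sampling_rate,
        "mode": sweep.mode,
        "holding_mv": sweep.holding_mv,
    }
    sidecar = Path(sidecar) if sidecar else Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps(meta))


def read_sweep_csv(path: str | Path, sidecar: str | Path | None = None) -> EphysSweep:
    df = pd.read_csv(path)
    sidecar = Path(sidecar) if sidecar else Path(path).with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return EphysSweep(
        signal=df["signal"].to_numpy(),
        sampling_rate=float(meta["sampling_rate"]),
        mode=meta["mode"],
        holding_mv=meta.get("holding_mv"),
    )
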