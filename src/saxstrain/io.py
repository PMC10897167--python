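"""On-disk interchange: TIFF frames with JSON sidecars, CSV tables.

An experiment directory holds one unsigned 32-bit single-page TIFF per frame
(``frame_0000.tif`` ...), a ``markers.csv`` table (time_s, marker_id, x_px,
y_px), and an ``experiment.json`` sidecar with timestamps, exposure, dose,
sample metadata, geometry, and (for synthetic data) the generating truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import DetectorFrame, Geometry
from .simulate import ExperimentBundle, LoadDisplacementCurve, SampleMeta, TensileTruth

__all__ = [
    "write_experiment",
    "read_experiment",
    "write_curve",
    "read_curve",
    "write_geometry",
    "read_geometry",
]


def write_geometry(geometry: Geometry, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(geometry), indent=2))


def read_geometry(path) -> Geometry:
    return Geometry(**json.loads(Path(path).read_text()))


def write_experiment(bundle: ExperimentBundle, directory) -> None:
    """Write frames, marker table, and the JSON sidecar of one experiment."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame_meta = []
    for i, frame in enumerate(bundle.frames):
        name = f"frame_{i:04d}.tif"
        tifffile.imwrite(directory / name, frame.data.astype(np.uint32))
        frame_meta.append(
            {"file": name, "time_s": frame.time_s, "exposure_s": frame.exposure_s,
             "dose_kgy": frame.dose_kgy}
        )
    bundle.ccd_markers.to_csv(directory / "markers.csv", index=False)
    sidecar = {
        "frames": frame_meta,
        "sample_meta": dataclasses.asdict(bundle.sample_meta),
        "truth": dataclasses.asdict(bundle.truth),
        "geometry": dataclasses.asdict(bundle.geometry),
    }
    (directory / "experiment.json").write_text(json.dumps(sidecar, indent=2))


def read_experiment(directory) -> ExperimentBundle:
    directory = Path(directory)
    sidecar = json.loads((directory / "experiment.json").read_text())
    frames = []
    for fm in sidecar["frames"]:
        data = tifffile.imread(directory / fm["file"])
        frames.append(
            DetectorFrame(data, time_s=fm["time_s"], exposure_s=fm["exposure_s"],
                          dose_kgy=fm["dose_kgy"])
        )
    meta = sidecar["sample_meta"]
    meta["group"] = tuple(meta["group"])
    return ExperimentBundle(
        frames=frames,
        ccd_markers=pd.read_csv(directory / "markers.csv"),
        sample_meta=SampleMeta(**meta),
        truth=TensileTruth(**sidecar["truth"]),
        geometry=Geometry(**sidecar["geometry"]),
    )


def write_curve(curve: LoadDisplacementCurve, path) -> None:
    pd.DataFrame(
        {"displacement_mm": curve.displacement_mm, "load_N": curve.load_n}
    ).to_csv(path, index=False)


def read_curve(path, sampling_hz: float = 50.0) -> LoadDisplacementCurve:
    table = pd.read_csv(path)
    return LoadDisplacementCurve(
        table["displacement_mm"].to_numpy(), table["load_N"].to_numpy(), sampling_hz
    )
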