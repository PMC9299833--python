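"""Readers and writers for the plain-text interchange formats.

Traces are two-column CSV (time_s, signal) with a JSON sidecar holding
units, sampling interval, polarity and generator parameters. Trains and
screen tables are long-format CSV. Bouton geometries are JSON with nm
coordinates. Images are TIFF with pixel-size metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from .synthgen import BoutonGeometry, Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_boutons",
    "read_boutons",
    "write_image",
    "read_image",
]


def write_trace(path, trace: Trace, params: dict | None = None) -> None:
    """Write a trace as CSV plus a JSON sidecar (same stem, .json)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "signal": trace.samples})
    df.to_csv(path, index=False)
    meta = {"dt": trace.dt, "units": trace.units, "polarity": trace.polarity}
    if params is not None:
        meta["params"] = params
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_trace(path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Trace(
        samples=df["signal"].to_numpy(dtype=float),
        dt=float(meta["dt"]),
        units=meta.get("units", "nA"),
        polarity=int(meta.get("polarity", -1)),
    )


def write_boutons(path, boutons: list[BoutonGeometry]) -> None:
    """Write bouton geometries (polygon + two point channels, nm) as JSON."""
    payload = [
        {
            "bouton_id": b.bouton_id,
            "polygon": [list(xy) for xy in b.polygon.exterior.coords[:-1]],
            "reference": np.asarray(b.reference).tolist(),
            "target": np.asarray(b.target).tolist(),
        }
        for b in boutons
    ]
    Path(path).write_text(json.dumps({"units": "nm", "boutons": payload}, indent=2))


def read_boutons(path) -> list[BoutonGeometry]:
    data = json.loads(Path(path).read_text())
    out = []
    for b in data["boutons"]:
        out.append(
            BoutonGeometry(
                polygon=Polygon(b["polygon"]),
                reference=np.asarray(b["reference"], dtype=float).reshape(-1, 2),
                target=np.asarray(b["target"], dtype=float).reshape(-1, 2),
                bouton_id=b.get("bouton_id", "bouton"),
            )
        )
    return out


def write_image(path, image: np.ndarray, pixel_size: float) -> None:
    """Write a (C, H, W) or (H, W) image as TIFF with pixel size metadata (nm)."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32),
                     metadata={"pixel_size_nm": pixel_size})


def read_image(path) -> tuple[np.ndarray, float | None]:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    px = meta.get("pixel_size_nm")
    return arr, (float(px) if px is not None else None)
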