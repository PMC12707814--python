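"""File formats: OME-TIFF stacks, centroid CSVs, filament JSON, trace HDF5.

Manifest dialect: ``punctum_id,x_um,y_um,z_um,diameter_um,coloc_label,polyline_id``.
An Imaris-style export dialect (``Position X,Position Y,Position Z,ID``) is
also read and written for interoperability with spot-detection exports.
Traces are stored in HDF5 (sweeps matrix + protocol/pharmacology metadata)
with a CSV fallback.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .errors import MetadataError, ValidationError
from .synth_ephys import Pharmacology, ProtocolSpec, SweepSet
from .synth_imaging import FilamentSet, GroundTruthPunctum, ImagingVolume, VoxelGrid

MANIFEST_COLUMNS = ["punctum_id", "x_um", "y_um", "z_um", "diameter_um", "coloc_label", "polyline_id"]


# ---------------------------------------------------------------------------
# stacks


def write_ome_tiff(volume: ImagingVolume, path) -> None:
    """Write channels as a CZYX OME-TIFF with physical voxel sizes in metadata."""
    names = sorted(volume.channels)
    stack = np.stack([volume.channels[n] for n in names]).astype(np.float32)
    g = volume.grid
    tifffile.imwrite(
        str(path),
        stack,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": g.voxel_size_xy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": g.voxel_size_xy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": g.voxel_size_z,
            "PhysicalSizeZUnit": "µm",
        },
        ome=True,
    )


def read_ome_tiff(path) -> ImagingVolume:
    """Read a CZYX OME-TIFF written by :func:`write_ome_tiff`."""
    with tifffile.TiffFile(str(path)) as tf:
        if tf.ome_metadata is None:
            raise MetadataError(f"{path}: not an OME-TIFF (voxel sizes unknown)")
        arr = tf.asarray()
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        pixels = root.find(".//ome:Pixels", ns)
        if pixels is None:
            raise MetadataError(f"{path}: OME metadata lacks Pixels element")
        vx = float(pixels.get("PhysicalSizeX", "0") or 0)
        vz = float(pixels.get("PhysicalSizeZ", "0") or 0)
        if vx <= 0 or vz <= 0:
            raise MetadataError(f"{path}: physical voxel sizes missing")
        names = [c.get("Name") or f"ch{i}" for i, c in enumerate(root.findall(".//ome:Channel", ns))]
    if arr.ndim == 3:
        arr = arr[None]
    if len(names) != arr.shape[0]:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    grid = VoxelGrid(shape_zyx=tuple(arr.shape[1:]), voxel_size_xy=vx, voxel_size_z=vz)
    return ImagingVolume(grid=grid, channels={n: arr[i].astype(float) for i, n in enumerate(names)})


# ---------------------------------------------------------------------------
# punctum tables


def write_manifest(puncta: list[GroundTruthPunctum], path) -> None:
    """Ground-truth manifest CSV; coordinates printed to 1e-9 µm."""
    rows = [
        {
            "punctum_id": i,
            "x_um": p.centroid_xyz[0],
            "y_um": p.centroid_xyz[1],
            "z_um": p.centroid_xyz[2],
            "diameter_um": p.diameter,
            "coloc_label": bool(p.coloc_label),
            "polyline_id": -1 if p.parent_polyline is None else int(p.parent_polyline),
        }
        for i, p in enumerate(puncta)
    ]
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9f")


def read_manifest(path) -> list[GroundTruthPunctum]:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest lacks columns {missing}")
    out = []
    for _, r in df.iterrows():
        pid = int(r["polyline_id"])
        out.append(
            GroundTruthPunctum(
                centroid_xyz=np.array([r["x_um"], r["y_um"], r["z_um"]]),
                diameter=float(r["diameter_um"]),
                coloc_label=bool(r["coloc_label"]),
                parent_polyline=None if pid < 0 else pid,
            )
        )
    return out


def write_imaris_csv(centroids_xyz: np.ndarray, path) -> None:
    """Spot-export dialect: ``Position X,Position Y,Position Z,ID`` (µm)."""
    c = np.atleast_2d(np.asarray(centroids_xyz, dtype=float))
    df = pd.DataFrame(
        {
            "Position X": c[:, 0],
            "Position Y": c[:, 1],
            "Position Z": c[:, 2],
            "ID": np.arange(len(c)),
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_centroids_csv(path) -> np.ndarray:
    """Read centroids from either the manifest or the Imaris-export dialect."""
    df = pd.read_csv(path)
    if {"Position X", "Position Y", "Position Z"}.issubset(df.columns):
        return df[["Position X", "Position Y", "Position Z"]].to_numpy(dtype=float)
    if {"x_um", "y_um", "z_um"}.issubset(df.columns):
        return df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    raise ValidationError(f"{path}: unrecognised centroid CSV dialect")


# ---------------------------------------------------------------------------
# filaments


def write_filaments_json(filaments: FilamentSet, path) -> None:
    payload = {
        "cell_id": filaments.cell_id,
        "polylines": [p.tolist() for p in filaments.polylines],
    }
    Path(path).write_text(json.dumps(payload))


def read_filaments_json(path) -> FilamentSet:
    payload = json.loads(Path(path).read_text())
    return FilamentSet(
        polylines=[np.asarray(p, dtype=float) for p in payload["polylines"]],
        cell_id=payload.get("cell_id", "cell0"),
    )


# ---------------------------------------------------------------------------
# traces


def write_sweepset_h5(sweeps: SweepSet, path) -> None:
    """Sweeps + protocol + pharmacology + seed in one HDF5 container."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("sweeps", data=sweeps.sweeps)
        f.attrs["sample_interval_us"] = sweeps.sample_interval_us
        f.attrs["units"] = sweeps.units
        f.attrs["t0_ms"] = sweeps.t0_ms
        if sweeps.protocol is not None:
            f.attrs["protocol_json"] = json.dumps(dataclasses.asdict(sweeps.protocol))
        pharm = sweeps.meta.get("pharmacology")
        if pharm is not None:
            f.attrs["pharmacology_json"] = json.dumps(dataclasses.asdict(pharm))
        if "seed" in sweeps.meta:
            f.attrs["seed"] = int(sweeps.meta["seed"])


def read_sweepset_h5(path) -> SweepSet:
    with h5py.File(str(path), "r") as f:
        arr = f["sweeps"][...]
        proto = None
        if "protocol_json" in f.attrs:
            proto = ProtocolSpec(**json.loads(f.attrs["protocol_json"]))
        meta = {}
        if "pharmacology_json" in f.attrs:
            meta["pharmacology"] = Pharmacology(**json.loads(f.attrs["pharmacology_json"]))
        if "seed" in f.attrs:
            meta["seed"] = int(f.attrs["seed"])
        return SweepSet(
            sweeps=arr,
            sample_interval_us=float(f.attrs["sample_interval_us"]),
            units=str(f.attrs["units"]),
            protocol=proto,
            t0_ms=float(f.attrs.get("t0_ms", 0.0)),
            meta=meta,
        )


def write_sweepset_csv(sweeps: SweepSet, path) -> None:
    """CSV fallback: one time column (ms) plus one column per sweep.

    Metadata goes into a JSON sidecar ``<path>.meta.json``.
    """
    t = sweeps.time_ms
    data = {"time_ms": t}
    for i, sw in enumerate(sweeps.sweeps):
        data[f"sweep{i}_{sweeps.units}"] = sw
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")
    meta = {
        "sample_interval_us": sweeps.sample_interval_us,
        "units": sweeps.units,
        "t0_ms": sweeps.t0_ms,
    }
    if sweeps.protocol is not None:
        meta["protocol"] = dataclasses.asdict(sweeps.protocol)
    pharm = sweeps.meta.get("pharmacology")
    if pharm is not None:
        meta["pharmacology"] = dataclasses.asdict(pharm)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def read_sweepset_csv(path) -> SweepSet:
    df = pd.read_csv(path)
    sidecar = Path(str(path) + ".meta.json")
    if not sidecar.exists():
        raise MetadataError(f"{path}: missing .meta.json sidecar")
    meta = json.loads(sidecar.read_text())
    cols = [c for c in df.columns if c.startswith("sweep")]
    proto = ProtocolSpec(**meta["protocol"]) if "protocol" in meta else None
    extra = {}
    if "pharmacology" in meta:
        extra["pharmacology"] = Pharmacology(**meta["pharmacology"])
    return SweepSet(
        sweeps=df[cols].to_numpy(dtype=float).T,
        sample_interval_us=float(meta["sample_interval_us"]),
        units=str(meta["units"]),
        protocol=proto,
        t0_ms=float(meta.get("t0_ms", 0.0)),
        meta=extra,
    )
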