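"""Reading and writing: OME-TIFF stacks, PLY meshes, CSV/JSON artifacts.

All writers are deterministic (fixed float formatting, sorted keys) so that
identical configuration + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from mptfm.mesh import SurfaceMesh
from mptfm.stack import ImageStack

FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------


def write_stack(path, channels: dict[str, ImageStack]) -> None:
    """Write channels to one OME-TIFF (axes CZYX, physical sizes in um)."""
    names = list(channels)
    first = channels[names[0]]
    dz, dy, dx = first.spacing
    data = np.stack([channels[n].data.astype(np.float32) for n in names])
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": names},
        },
    )


def read_stack(
    path,
    channel_map: dict[str, int] | list[str] | None = None,
    spacing_override: tuple[float, float, float] | None = None,
) -> dict[str, ImageStack]:
    """Read a TIFF/OME-TIFF into named :class:`ImageStack` channels.

    ``channel_map`` maps channel names to indices (or is a list of names in
    stored order); defaults to stored OME channel names or ``ch0, ch1, ...``.
    ``spacing_override`` is ``(dz, dy, dx)`` in um and is required when the
    file carries no physical pixel sizes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        spacing = None
        names = None
        if tf.ome_metadata:
            try:
                root = ET.fromstring(tf.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                px = root.find(".//ome:Pixels", ns)
                if px is not None and px.get("PhysicalSizeZ"):
                    spacing = (
                        float(px.get("PhysicalSizeZ")),
                        float(px.get("PhysicalSizeY")),
                        float(px.get("PhysicalSizeX")),
                    )
                chs = root.findall(".//ome:Channel", ns)
                if chs and all(c.get("Name") for c in chs):
                    names = [c.get("Name") for c in chs]
            except ET.ParseError:
                pass
    if spacing_override is not None:
        spacing = tuple(spacing_override)
    if spacing is None:
        raise ValueError("no voxel spacing in metadata; pass spacing_override")
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"expected CZYX or ZYX data, got shape {data.shape}")
    n_ch = data.shape[0]
    if isinstance(channel_map, dict):
        order = channel_map
    elif isinstance(channel_map, (list, tuple)):
        order = {n: i for i, n in enumerate(channel_map)}
    elif names is not None and len(names) == n_ch:
        order = {n: i for i, n in enumerate(names)}
    else:
        order = {f"ch{i}": i for i in range(n_ch)}
    missing = [n for n, i in order.items() if i >= n_ch]
    if missing:
        raise ValueError(f"channels not present in file: {missing}")
    return {
        name: ImageStack(data[i].astype(float), spacing, channel=name)
        for name, i in order.items()
    }


# ---------------------------------------------------------------------------
# PLY meshes with per-vertex scalars
# ---------------------------------------------------------------------------


def write_ply(path, mesh: SurfaceMesh) -> None:
    """ASCII PLY with per-vertex scalar properties and the center as comment."""
    scalars = {
        k: np.asarray(v, float)
        for k, v in mesh.vertex_data.items()
        if np.asarray(v).ndim == 1 and len(np.asarray(v)) == len(mesh.vertices)
    }
    names = sorted(scalars)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        cx, cy, cz = (float(v) for v in mesh.center)
        fh.write(f"comment center {cx!r} {cy!r} {cz!r}\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        for p in ("x", "y", "z"):
            fh.write(f"property double {p}\n")
        for n in names:
            fh.write(f"property double {n}\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        cols = [mesh.vertices[:, i] for i in range(3)] + [scalars[n] for n in names]
        for row in zip(*cols):
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_ply(path) -> SurfaceMesh:
    """Read a mesh written by :func:`write_ply` (scalars preserved)."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError("not a PLY file")
        n_vert = n_face = 0
        center = np.zeros(3)
        props: list[str] = []
        in_vertex = False
        while True:
            line = fh.readline().strip()
            if line == "end_header":
                break
            parts = line.split()
            if parts[0] == "comment" and parts[1] == "center":
                center = np.array([float(x) for x in parts[2:5]])
            elif parts[0] == "element":
                in_vertex = parts[1] == "vertex"
                if in_vertex:
                    n_vert = int(parts[2])
                else:
                    n_face = int(parts[2])
            elif parts[0] == "property" and in_vertex and parts[1] != "list":
                props.append(parts[2])
        rows = np.array(
            [[float(v) for v in fh.readline().split()] for _ in range(n_vert)]
        )
        faces = np.array(
            [[int(v) for v in fh.readline().split()[1:4]] for _ in range(n_face)]
        )
    vertices = rows[:, :3]
    data = {p: rows[:, 3 + i] for i, p in enumerate(props[3:])}
    return SurfaceMesh(vertices, faces, center, vertex_data=data)


# ---------------------------------------------------------------------------
# Tables, summaries, manifests
# ---------------------------------------------------------------------------


def write_table(path, df: pd.DataFrame, units: dict[str, str] | None = None) -> None:
    """CSV with an optional second header row of units."""
    path = Path(path)
    if units:
        unit_row = pd.DataFrame([[units.get(c, "") for c in df.columns]], columns=df.columns)
        out = pd.concat([unit_row, df], ignore_index=True)
    else:
        out = df
    out.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def write_summary(path, summary: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in np.asarray(obj).tolist()] if isinstance(
            obj, np.ndarray
        ) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, config: dict, seed: int, files: list[str]) -> None:
    write_summary(
        Path(outdir) / "manifest.json",
        {"config_hash": config_hash(config), "seed": seed, "outputs": sorted(files)},
    )
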