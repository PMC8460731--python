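"""File formats: volumes (NIfTI/NRRD), meshes (PLY/legacy VTK),
landmarks (CSV), transforms (JSON manifest + NPZ payload), configs (YAML).

Volumes go through SimpleITK with full geometry (spacing, origin,
direction); meshes through trimesh for PLY, with a small legacy-VTK ASCII
reader/writer since triangular ``POLYDATA`` is a two-array format.
Transforms have no standard container that covers velocity-flow
diffeomorphisms, so they serialize as a JSON manifest describing the
chain plus an ``.npz`` with the array payloads (documented in the JSON
itself).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import trimesh
import yaml

from .geometry import (
    Affine,
    Diffeomorphism,
    GeometryError,
    ImageVolume,
    LabelVolume,
    LandmarkSet,
    PlanarEmbedding,
    RegularGrid,
    TransformChain,
    TriangleMesh,
)

__all__ = [
    "read_volume", "write_volume",
    "read_mesh", "write_mesh",
    "read_image2d", "write_image2d",
    "read_landmarks", "write_landmarks",
    "read_transform", "write_transform",
    "load_config", "save_config",
]

_VOLUME_EXT = {".nii", ".nii.gz", ".nrrd", ".nhdr"}
_MESH_EXT = {".ply", ".vtk"}


def _ext(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def write_volume(path, vol: ImageVolume) -> Path:
    path = Path(path)
    if _ext(path) not in _VOLUME_EXT:
        raise GeometryError(f"unknown volume format: {path.name}")
    # SimpleITK indexes (z, y, x); our values are (i, j, k) = (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        vol.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(float(d) for d in vol.direction.ravel()))
    sitk.WriteImage(img, str(path))
    return path


def read_volume(path, as_label: bool = False) -> ImageVolume:
    path = Path(path)
    if _ext(path) not in _VOLUME_EXT:
        raise GeometryError(f"unknown volume format: {path.name}")
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.array(img.GetSpacing())
    origin = np.array(img.GetOrigin())
    direction = np.array(img.GetDirection()).reshape(3, 3)
    cls = LabelVolume if as_label else ImageVolume
    return cls(values.astype(float), spacing, origin, direction)


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def write_mesh(path, mesh: TriangleMesh, binary: bool = True) -> Path:
    path = Path(path)
    ext = _ext(path)
    if ext == ".ply":
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        tm.export(str(path), encoding="binary" if binary else "ascii")
    elif ext == ".vtk":
        _write_vtk_ascii(path, mesh)
    else:
        raise GeometryError(f"unknown mesh format: {path.name}")
    return path


def read_mesh(path) -> TriangleMesh:
    path = Path(path)
    ext = _ext(path)
    if ext == ".ply":
        tm = trimesh.load(str(path), process=False)
        return TriangleMesh(np.asarray(tm.vertices, dtype=float),
                            np.asarray(tm.faces, dtype=np.int64),
                            degenerate_ok=True)
    if ext == ".vtk":
        return _read_vtk_ascii(path)
    raise GeometryError(f"unknown mesh format: {path.name}")


def _write_vtk_ascii(path: Path, mesh: TriangleMesh) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntriangle surface\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_vtk_ascii(path: Path) -> TriangleMesh:
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise GeometryError(f"{path}: not a legacy VTK file (line 1)")
    if lines[2].strip().upper() != "ASCII":
        raise GeometryError(f"{path}: only ASCII legacy VTK is supported")
    for ln in lines[3:]:
        tokens.extend(ln.split())
    it = iter(range(len(tokens)))
    i = 0
    verts = faces = None
    while i < len(tokens):
        tok = tokens[i].upper()
        if tok == "POINTS":
            n = int(tokens[i + 1])
            vals = tokens[i + 3:i + 3 + 3 * n]
            verts = np.array(vals, dtype=float).reshape(n, 3)
            i += 3 + 3 * n
        elif tok == "POLYGONS":
            m = int(tokens[i + 1])
            total = int(tokens[i + 2])
            vals = tokens[i + 3:i + 3 + total]
            arr = np.array(vals, dtype=np.int64)
            faces = []
            j = 0
            while j < len(arr):
                k = arr[j]
                if k != 3:
                    raise GeometryError(
                        f"{path}: only triangular polygons supported "
                        f"(got a {k}-gon at token offset {i + 3 + j})")
                faces.append(arr[j + 1:j + 4])
                j += k + 1
            faces = np.array(faces)
            i += 3 + total
        else:
            i += 1
    if verts is None or faces is None:
        raise GeometryError(f"{path}: missing POINTS or POLYGONS section")
    return TriangleMesh(verts, faces, degenerate_ok=True)


# ---------------------------------------------------------------------------
# 2D section images (TIFF/PNG + JSON geometry sidecar)
# ---------------------------------------------------------------------------

def write_image2d(path, img) -> Path:
    """Write a section image with a ``.json`` geometry sidecar.

    TIFF stores float32 values losslessly; PNG is supported for 8-bit
    previews (values scaled to [0, 255]).
    """
    import tifffile
    from .geometry import Image2D  # noqa: F811

    path = Path(path)
    ext = _ext(path)
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(str(path), img.values.astype(np.float32))
    elif ext == ".png":
        from PIL import Image

        lo, hi = float(img.values.min()), float(img.values.max())
        scale = 255.0 / (hi - lo) if hi > lo else 1.0
        arr = ((img.values - lo) * scale).astype(np.uint8)
        Image.fromarray(arr.T).save(str(path))
    else:
        raise GeometryError(f"unknown 2D image format: {path.name}")
    sidecar = {"spacing": [float(s) for s in img.spacing],
               "origin": [float(o) for o in img.origin],
               "section_depth": float(img.section_depth)}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))
    return path


def read_image2d(path):
    import tifffile
    from .geometry import Image2D

    path = Path(path)
    if _ext(path) not in (".tif", ".tiff"):
        raise GeometryError(
            f"only TIFF sections round-trip values: {path.name}")
    values = np.asarray(tifffile.imread(str(path)), dtype=float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise GeometryError(f"missing geometry sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    return Image2D(values, meta["spacing"], meta["origin"],
                   meta["section_depth"])


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def write_landmarks(path, lms: LandmarkSet) -> Path:
    path = Path(path)
    df = pd.DataFrame({"label": lms.labels,
                       "x": lms.points[:, 0], "y": lms.points[:, 1],
                       "z": lms.points[:, 2], "space": lms.space})
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path)
    required = {"label", "x", "y", "z"}
    if not required <= set(df.columns):
        raise GeometryError(
            f"{path}: landmark CSV needs columns {sorted(required)}")
    space = str(df["space"].iloc[0]) if "space" in df.columns else "world"
    return LandmarkSet(df[["x", "y", "z"]].to_numpy(dtype=float),
                       [str(l) for l in df["label"]], space)


# ---------------------------------------------------------------------------
# Transforms (JSON manifest + npz payload)
# ---------------------------------------------------------------------------

def write_transform(path, transform) -> Path:
    """Serialize an Affine, Diffeomorphism or TransformChain.

    ``path`` is the JSON manifest; arrays go to ``path`` with suffix
    ``.npz``.  The manifest lists each element's type, direction, and the
    npz keys holding its arrays.
    """
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    if not isinstance(transform, TransformChain):
        transform = TransformChain([(transform, "forward")])
    manifest = {"format": "mrhist-transform-chain", "version": 1,
                "payload": path.with_suffix(".npz").name, "elements": []}
    for i, (t, direction) in enumerate(transform):
        key = f"el{i}"
        if isinstance(t, Affine):
            arrays[f"{key}_linear"] = t.linear
            arrays[f"{key}_translation"] = t.translation
            manifest["elements"].append(
                {"type": "affine", "direction": direction, "key": key})
        elif isinstance(t, Diffeomorphism):
            arrays[f"{key}_origin"] = t.grid.origin
            arrays[f"{key}_spacing"] = t.grid.spacing
            arrays[f"{key}_dts"] = np.array([dt for dt, _ in t.steps])
            arrays[f"{key}_velocities"] = np.stack(
                [V for _, V in t.steps])
            arrays[f"{key}_bounds_lo"] = t.domain_bounds[0]
            arrays[f"{key}_bounds_hi"] = t.domain_bounds[1]
            manifest["elements"].append(
                {"type": "diffeomorphism", "direction": direction,
                 "key": key, "grid_shape": list(t.grid.shape)})
        elif isinstance(t, PlanarEmbedding):
            manifest["elements"].append(
                {"type": "planar_embedding", "direction": direction,
                 "depth": float(t.depth)})
        else:
            raise GeometryError(
                f"cannot serialize transform element {type(t).__name__}")
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_transform(path) -> TransformChain:
    path = Path(path)
    manifest = json.loads(path.read_text())
    if manifest.get("format") != "mrhist-transform-chain":
        raise GeometryError(f"{path}: not a transform manifest")
    payload = np.load(path.parent / manifest["payload"])
    elements = []
    for el in manifest["elements"]:
        direction = el["direction"]
        if el["type"] == "affine":
            key = el["key"]
            t = Affine(payload[f"{key}_linear"],
                       payload[f"{key}_translation"])
        elif el["type"] == "diffeomorphism":
            key = el["key"]
            shape = tuple(el["grid_shape"])
            grid = RegularGrid(payload[f"{key}_origin"],
                               payload[f"{key}_spacing"], shape)
            dts = payload[f"{key}_dts"]
            vels = payload[f"{key}_velocities"]
            t = Diffeomorphism(grid,
                               [(float(dt), V) for dt, V in zip(dts, vels)],
                               domain_bounds=(payload[f"{key}_bounds_lo"],
                                              payload[f"{key}_bounds_hi"]))
        elif el["type"] == "planar_embedding":
            t = PlanarEmbedding(el["depth"])
        else:
            raise GeometryError(f"{path}: unknown element type {el['type']}")
        elements.append((t, direction))
    return TransformChain(elements)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise GeometryError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(path, cfg: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
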