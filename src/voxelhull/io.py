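"""File formats: calibration/joints/skeleton JSON, PLY clouds, PNG silhouettes.

PLY support covers ASCII and binary little-endian files with ``double`` or
``float`` vertex properties ``x y z`` and optional ``nx ny nz``.  Voxel
reconstructions are exported as point clouds of occupied voxel centers with
a ``voxel_size`` header comment plus a JSON sidecar recording the grid
origin, voxel size, and dims so they can be re-imported losslessly.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np

from .carving import ProbabilitySilhouette
from .errors import CalibrationError
from .geometry import CameraModel
from .grid import VoxelGrid

__all__ = [
    "read_calibration",
    "write_calibration",
    "read_joints",
    "write_joints",
    "read_skeleton_bones",
    "write_skeleton_bones",
    "read_ply",
    "write_ply",
    "write_voxel_ply",
    "load_voxel_grid",
    "read_silhouette",
    "write_silhouette",
    "read_silhouettes",
]

_CAMERA_FIELDS = {"id", "fx", "fy", "cx", "cy", "R", "t", "width", "height"}


def write_calibration(path, cameras: Sequence[CameraModel]) -> None:
    doc = {
        "cameras": [
            {
                "id": c.camera_id,
                "fx": c.fx,
                "fy": c.fy,
                "cx": c.cx,
                "cy": c.cy,
                "R": c.rotation.ravel().tolist(),
                "t": c.translation.tolist(),
                "width": c.width,
                "height": c.height,
            }
            for c in cameras
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_calibration(path) -> List[CameraModel]:
    """Read and validate a calibration file.

    Rotations within 1e-6 of orthonormal are re-orthonormalized via SVD;
    anything worse is rejected.  Unknown per-camera fields produce a
    warning; duplicate camera ids are an error.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise CalibrationError(f"calibration file is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "cameras" not in doc:
        raise CalibrationError("calibration file must contain a 'cameras' list")
    cameras: List[CameraModel] = []
    seen = set()
    for i, entry in enumerate(doc["cameras"]):
        unknown = set(entry) - _CAMERA_FIELDS
        if unknown:
            warnings.warn(f"camera entry {i}: ignoring unknown fields {sorted(unknown)}")
        missing = _CAMERA_FIELDS - set(entry)
        if missing:
            raise CalibrationError(f"camera entry {i}: missing fields {sorted(missing)}")
        cam_id = str(entry["id"])
        if cam_id in seen:
            raise CalibrationError(f"duplicate camera id {cam_id!r}")
        seen.add(cam_id)
        R = np.asarray(entry["R"], dtype=float).reshape(3, 3)
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-6:
            raise CalibrationError(
                f"camera {cam_id!r}: field 'R' is not orthonormal (error {err:.3g})"
            )
        if err > 1e-12:
            u, _, vt = np.linalg.svd(R)
            R = u @ vt
        if np.linalg.det(R) < 0:
            raise CalibrationError(f"camera {cam_id!r}: field 'R' has determinant -1")
        try:
            cameras.append(
                CameraModel(
                    fx=float(entry["fx"]),
                    fy=float(entry["fy"]),
                    cx=float(entry["cx"]),
                    cy=float(entry["cy"]),
                    rotation=R,
                    translation=np.asarray(entry["t"], dtype=float),
                    width=int(entry["width"]),
                    height=int(entry["height"]),
                    camera_id=cam_id,
                )
            )
        except ValueError as exc:
            raise CalibrationError(f"camera {cam_id!r}: {exc}") from exc
    return cameras


def write_joints(path, detections) -> None:
    doc = {
        cam_id: {name: [float(uv[0]), float(uv[1])] for name, uv in per_cam.items()}
        for cam_id, per_cam in detections.items()
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_joints(path):
    doc = json.loads(Path(path).read_text())
    return {
        str(cam_id): {str(name): (float(uv[0]), float(uv[1])) for name, uv in per_cam.items()}
        for cam_id, per_cam in doc.items()
    }


def write_skeleton_bones(path, bones: Sequence[Tuple[str, str]]) -> None:
    Path(path).write_text(json.dumps([list(b) for b in bones], indent=1))


def read_skeleton_bones(path) -> List[Tuple[str, str]]:
    doc = json.loads(Path(path).read_text())
    return [(str(a), str(b)) for a, b in doc]


# ---------------------------------------------------------------------------
# PLY

def write_ply(path, points: np.ndarray, normals: Optional[np.ndarray] = None,
              binary: bool = True, comments: Sequence[str] = ()) -> None:
    points = np.atleast_2d(np.asarray(points, dtype="<f8"))
    n = points.shape[0]
    props = ["x", "y", "z"]
    cols = [points]
    if normals is not None:
        normals = np.atleast_2d(np.asarray(normals, dtype="<f8"))
        if normals.shape != points.shape:
            raise ValueError("normals must match points shape")
        props += ["nx", "ny", "nz"]
        cols.append(normals)
    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0"]
    header += [f"comment {c}" for c in comments]
    header.append(f"element vertex {n}")
    header += [f"property double {p}" for p in props]
    header.append("end_header")
    data = np.hstack(cols)
    path = Path(path)
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(data.astype("<f8").tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            np.savetxt(fh, data, fmt="%.17g")


_PLY_TYPES = {"float": ("<f4", 4), "float32": ("<f4", 4), "double": ("<f8", 8),
              "float64": ("<f8", 8)}


def read_ply(path, require_normals: bool = False):
    """Read a PLY point cloud; returns ``(points, normals_or_None, comments)``."""
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header")
    if end < 0:
        raise ValueError("malformed PLY: no end_header")
    header = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end:]
    body = body[body.find(b"\n") + 1 :]
    if not header or header[0].strip() != "ply":
        raise ValueError("malformed PLY: missing magic")
    fmt = None
    n_vertex = None
    props: List[Tuple[str, str]] = []
    comments: List[str] = []
    in_vertex = False
    for line in header[1:]:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "comment":
            comments.append(line.partition(" ")[2])
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise ValueError("list properties are not supported")
            props.append((tok[1], tok[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValueError(f"unsupported PLY format {fmt!r}")
    if n_vertex is None:
        raise ValueError("malformed PLY: no vertex element")
    names = [p[1] for p in props]
    for want in ("x", "y", "z"):
        if want not in names:
            raise ValueError(f"PLY is missing vertex property {want!r}")
    if fmt == "ascii":
        table = np.loadtxt(body.decode("ascii").splitlines(), ndmin=2)
        if table.shape[0] != n_vertex or table.shape[1] != len(props):
            raise ValueError("PLY body does not match header")
    else:
        dtype = np.dtype([(f"c{i}", _PLY_TYPES[t][0]) for i, (t, _) in enumerate(props)])
        table = np.frombuffer(body, dtype=dtype, count=n_vertex)
        table = np.column_stack([table[f"c{i}"].astype(float) for i in range(len(props))])
    cols = {name: table[:, i] for i, name in enumerate(names)}
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    if all(k in cols for k in ("nx", "ny", "nz")):
        normals = np.column_stack([cols["nx"], cols["ny"], cols["nz"]])
    if require_normals and normals is None:
        raise ValueError("PLY has no normals (nx/ny/nz) but they were required")
    return points, normals, comments


def write_voxel_ply(path, grid: VoxelGrid, binary: bool = True) -> None:
    """Export occupied voxel centers plus a `.meta.json` grid sidecar."""
    path = Path(path)
    write_ply(path, grid.occupied_centers(), binary=binary,
              comments=[f"voxel_size {grid.voxel_size!r}"])
    meta = {
        "origin": grid.origin.tolist(),
        "voxel_size": grid.voxel_size,
        "dims": list(grid.dims),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_voxel_grid(path) -> VoxelGrid:
    """Rebuild a :class:`VoxelGrid` from a voxel PLY and its sidecar."""
    path = Path(path)
    points, _, _ = read_ply(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    origin = np.asarray(meta["origin"], dtype=float)
    d = float(meta["voxel_size"])
    dims = tuple(int(x) for x in meta["dims"])
    occ = np.zeros(dims, dtype=bool)
    if points.shape[0]:
        idx = np.rint((points - origin) / d - 0.5).astype(np.int64)
        if np.any(idx < 0) or np.any(idx >= np.array(dims)):
            raise ValueError("voxel PLY contains points outside its sidecar grid")
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return VoxelGrid(origin, d, occ)


# ---------------------------------------------------------------------------
# silhouettes

def write_silhouette(path, silhouette: ProbabilitySilhouette) -> None:
    iio.imwrite(Path(path), silhouette.values)


def read_silhouette(path, camera_id: str = "") -> ProbabilitySilhouette:
    img = iio.imread(Path(path))
    if img.ndim == 3:  # tolerate grayscale saved with redundant channels
        img = img[..., 0]
    return ProbabilitySilhouette(np.asarray(img, dtype=np.uint8), camera_id=camera_id)


def read_silhouettes(directory, cameras: Sequence[CameraModel]) -> List[ProbabilitySilhouette]:
    """Read `{camera_id}.png` for every camera, in camera order."""
    directory = Path(directory)
    out = []
    for cam in cameras:
        p = directory / f"{cam.camera_id}.png"
        if not p.exists():
            raise FileNotFoundError(f"missing silhouette for camera {cam.camera_id!r}: {p}")
        out.append(read_silhouette(p, camera_id=cam.camera_id))
    return out
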