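"""Depth rasters, point clouds, and the pinhole back-projection between them.

The camera model is the standard top-down pinhole: a pixel at column u,
row v with depth D (mm) maps to camera-frame coordinates

    x = D * (u - cx) / fx,   y = D * (v - cy) / fy,   z = D,

with +x right (columns), +y down (rows), +z away from the camera.  Depth
is interpreted as z-depth (distance along the optical axis), the native
convention of stereo depth sensors.  Units are millimetres end to end.

File formats: PLY (ascii and binary_little_endian, with optional per-vertex
``label`` scalar and RGB), whitespace XYZ text with an optional fourth
label column, and 16-bit PGM depth rasters with a JSON intrinsics sidecar.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Intrinsics",
    "DepthFrame",
    "LabeledCloud",
    "CloudFormatError",
    "depth_to_cloud",
    "read_cloud",
    "write_cloud",
    "read_depth_frame",
    "write_depth_frame",
    "DEFAULT_FOCAL_LENGTH",
]

# Focal length of the depth sensor used throughout (pixels at 400x240).
DEFAULT_FOCAL_LENGTH = 215.9346


class CloudFormatError(ValueError):
    """Raised for malformed point-cloud or raster files."""


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics; ``cx``/``cy`` default to the frame centre."""

    fx: float = DEFAULT_FOCAL_LENGTH
    fy: float = DEFAULT_FOCAL_LENGTH
    width: int = 400
    height: int = 240
    cx: float | None = None
    cy: float | None = None

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError(f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}")
        if self.cx is None:
            object.__setattr__(self, "cx", self.width / 2.0)
        if self.cy is None:
            object.__setattr__(self, "cy", self.height / 2.0)
        if not (0 <= self.cx <= self.width) or not (0 <= self.cy <= self.height):
            raise ValueError("principal point lies outside the frame")

    def to_dict(self):
        return {"fx": self.fx, "fy": self.fy, "width": self.width,
                "height": self.height, "cx": self.cx, "cy": self.cy}

    @classmethod
    def from_dict(cls, d):
        return cls(**{k: d[k] for k in ("fx", "fy", "width", "height", "cx", "cy") if k in d})


@dataclass
class DepthFrame:
    """A rectangular raster of depth values (mm) with validity mask.

    Depth 0 is the sensor dropout convention and is treated as invalid;
    an explicit ``valid_mask`` may invalidate further pixels.
    """

    intrinsics: Intrinsics
    depth: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.depth.shape != (self.intrinsics.height, self.intrinsics.width):
            raise ValueError(
                f"depth raster shape {self.depth.shape} does not match intrinsics "
                f"({self.intrinsics.height}, {self.intrinsics.width})")
        if np.any(self.depth < 0):
            raise ValueError("negative depth values")
        if self.valid_mask is None:
            self.valid_mask = self.depth > 0
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool) & (self.depth > 0)


@dataclass
class LabeledCloud:
    """N x 3 points (mm, camera frame) with optional {0,1} labels and RGB."""

    points: np.ndarray
    labels: np.ndarray | None = None
    rgb: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.points.shape[0] < 1:
            raise ValueError("cloud must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
            if self.labels.shape[0] != self.points.shape[0]:
                raise ValueError("labels length does not match point count")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0 or 1")
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb, dtype=np.float64).reshape(-1, 3)
            if self.rgb.shape[0] != self.points.shape[0]:
                raise ValueError("rgb length does not match point count")
            if self.rgb.min() < 0 or self.rgb.max() > 1:
                raise ValueError("rgb values must lie in [0, 1]")

    def __len__(self):
        return self.points.shape[0]


def depth_to_cloud(frame: DepthFrame) -> LabeledCloud:
    """Back-project every valid pixel of a depth raster to a 3D point.

    Point order is row-major over valid pixels and deterministic.  The
    output z channel equals the input depth exactly.
    """
    K = frame.intrinsics
    mask = frame.valid_mask
    if not mask.any():
        raise CloudFormatError("depth frame has no valid pixels")
    rows, cols = np.nonzero(mask)
    D = frame.depth[rows, cols]
    x = D * (cols - K.cx) / K.fx
    y = D * (rows - K.cy) / K.fy
    return LabeledCloud(points=np.column_stack([x, y, D]))


# ---------------------------------------------------------------------------
# PLY I/O.  Subset: single "vertex" element; float32/float64 x,y,z; optional
# uchar red/green/blue; optional label scalar (any integer or float type).
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "float": ("f", 4), "float32": ("f", 4), "double": ("d", 8), "float64": ("d", 8),
    "uchar": ("B", 1), "uint8": ("B", 1), "char": ("b", 1), "int8": ("b", 1),
    "short": ("h", 2), "int16": ("h", 2), "ushort": ("H", 2), "uint16": ("H", 2),
    "int": ("i", 4), "int32": ("i", 4), "uint": ("I", 4), "uint32": ("I", 4),
}


def write_cloud(cloud: LabeledCloud, path, binary: bool | None = None) -> None:
    """Write a cloud as PLY (``.ply``, default binary_little_endian) or
    XYZ text (``.xyz``/``.txt``, 3 or 4 whitespace columns)."""
    path = Path(path)
    if path.suffix.lower() in (".xyz", ".txt"):
        cols = [cloud.points]
        if cloud.labels is not None:
            cols.append(cloud.labels[:, None].astype(float))
        np.savetxt(path, np.hstack(cols), fmt="%.6f")
        return
    if binary is None:
        binary = True
    fmt = "binary_little_endian" if binary else "ascii"
    n = len(cloud)
    header = ["ply", f"format {fmt} 1.0", f"element vertex {n}"]
    header += [f"property double {c}" for c in ("x", "y", "z")]
    if cloud.rgb is not None:
        header += [f"property uchar {c}" for c in ("red", "green", "blue")]
    if cloud.labels is not None:
        header.append("property int label")
    header += ["end_header"]
    rgb255 = None if cloud.rgb is None else np.rint(cloud.rgb * 255).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            rec = "<3d" + ("3B" if rgb255 is not None else "") + ("i" if cloud.labels is not None else "")
            packer = struct.Struct(rec)
            for i in range(n):
                vals = list(cloud.points[i])
                if rgb255 is not None:
                    vals += list(rgb255[i])
                if cloud.labels is not None:
                    vals.append(int(cloud.labels[i]))
                fh.write(packer.pack(*vals))
        else:
            for i in range(n):
                parts = [f"{v:.10g}" for v in cloud.points[i]]
                if rgb255 is not None:
                    parts += [str(int(v)) for v in rgb255[i]]
                if cloud.labels is not None:
                    parts.append(str(int(cloud.labels[i])))
                fh.write((" ".join(parts) + "\n").encode("ascii"))


def _parse_ply_header(fh):
    line = fh.readline().strip()
    if line != b"ply":
        raise CloudFormatError("not a PLY file: missing 'ply' magic at line 1")
    fmt = None
    n_vertex = None
    props = []
    lineno = 1
    while True:
        raw = fh.readline()
        lineno += 1
        if not raw:
            raise CloudFormatError(f"unexpected end of header at line {lineno}")
        tokens = raw.strip().decode("ascii", "replace").split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            if tokens[1] not in ("ascii", "binary_little_endian"):
                raise CloudFormatError(f"unsupported PLY format '{tokens[1]}' at line {lineno}")
            fmt = tokens[1]
        elif tokens[0] == "element":
            if tokens[1] != "vertex":
                raise CloudFormatError(f"unsupported element '{tokens[1]}' at line {lineno}")
            n_vertex = int(tokens[2])
        elif tokens[0] == "property":
            if tokens[1] == "list":
                raise CloudFormatError(f"list properties unsupported at line {lineno}")
            if tokens[1] not in _PLY_TYPES:
                raise CloudFormatError(f"unknown property type '{tokens[1]}' at line {lineno}")
            props.append((tokens[2], tokens[1]))
        elif tokens[0] == "end_header":
            break
        else:
            raise CloudFormatError(f"unrecognised header line {lineno}: {raw!r}")
    if fmt is None or n_vertex is None:
        raise CloudFormatError("PLY header missing format or vertex element")
    return fmt, n_vertex, props


def read_cloud(path) -> LabeledCloud:
    """Read a PLY or XYZ point cloud file; see :func:`write_cloud`."""
    path = Path(path)
    if path.suffix.lower() in (".xyz", ".txt"):
        data = np.loadtxt(path, ndmin=2)
        if data.shape[1] == 3:
            return LabeledCloud(points=data)
        if data.shape[1] == 4:
            return LabeledCloud(points=data[:, :3], labels=data[:, 3].astype(np.int64))
        raise CloudFormatError(f"XYZ file must have 3 or 4 columns, found {data.shape[1]}")
    with open(path, "rb") as fh:
        fmt, n, props = _parse_ply_header(fh)
        names = [p[0] for p in props]
        for c in ("x", "y", "z"):
            if c not in names:
                raise CloudFormatError(f"PLY vertex element lacks property '{c}'")
        if fmt == "ascii":
            rows = []
            for i in range(n):
                line = fh.readline()
                if not line.strip():
                    raise CloudFormatError(
                        f"PLY declares {n} vertices but data ends at vertex {i}")
                vals = line.split()
                if len(vals) != len(props):
                    raise CloudFormatError(
                        f"vertex {i}: expected {len(props)} values, found {len(vals)}")
                rows.append([float(v) for v in vals])
            table = np.asarray(rows)
        else:
            rec = "<" + "".join(_PLY_TYPES[t][0] for _, t in props)
            packer = struct.Struct(rec)
            payload = fh.read(packer.size * n)
            if len(payload) < packer.size * n:
                raise CloudFormatError(
                    f"PLY declares {n} vertices ({packer.size * n} bytes) but payload "
                    f"holds only {len(payload)} bytes")
            table = np.asarray([packer.unpack_from(payload, i * packer.size) for i in range(n)],
                               dtype=np.float64)
    col = {name: table[:, i] for i, (name, _) in enumerate(props)}
    points = np.column_stack([col["x"], col["y"], col["z"]])
    labels = col["label"].astype(np.int64) if "label" in col else None
    rgb = None
    if all(c in col for c in ("red", "green", "blue")):
        rgb = np.column_stack([col["red"], col["green"], col["blue"]]) / 255.0
    return LabeledCloud(points=points, labels=labels, rgb=rgb)


# ---------------------------------------------------------------------------
# Depth raster I/O: 16-bit binary PGM (depth in mm) + JSON intrinsics sidecar.
# ---------------------------------------------------------------------------


def write_depth_frame(frame: DepthFrame, path) -> None:
    path = Path(path)
    depth = np.where(frame.valid_mask, frame.depth, 0.0)
    d16 = np.clip(np.rint(depth), 0, 65535).astype(">u2")
    with open(path, "wb") as fh:
        fh.write(f"P5\n{frame.intrinsics.width} {frame.intrinsics.height}\n65535\n".encode())
        fh.write(d16.tobytes())
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(frame.intrinsics.to_dict(), indent=1))


def read_depth_frame(path) -> DepthFrame:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"P5":
            raise CloudFormatError("depth raster must be binary PGM (P5)")
        dims = fh.readline().split()
        maxval = int(fh.readline())
        if maxval != 65535:
            raise CloudFormatError("depth PGM must be 16-bit (maxval 65535)")
        w, h = int(dims[0]), int(dims[1])
        payload = fh.read(2 * w * h)
        if len(payload) < 2 * w * h:
            raise CloudFormatError(
                f"PGM payload truncated: expected {2*w*h} bytes, found {len(payload)}")
    depth = np.frombuffer(payload, dtype=">u2").reshape(h, w).astype(np.float64)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        K = Intrinsics.from_dict(json.loads(sidecar.read_text()))
        if (K.width, K.height) != (w, h):
            raise CloudFormatError("intrinsics sidecar disagrees with raster dimensions")
    else:
        K = Intrinsics(width=w, height=h)
    return DepthFrame(intrinsics=K, depth=depth)
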