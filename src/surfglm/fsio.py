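"""Readers and writers for FreeSurfer surface-map files and triangle meshes.

Two binary formats are handled, both big-endian by specification:

* MGH / MGZ — the volume container FreeSurfer uses for per-vertex surface
  maps.  A surface map is stored as a degenerate volume of shape
  ``(V, 1, 1, nframes)`` where ``V`` is the number of vertices.  ``.mgz``
  files are the same byte stream gzip-compressed.
* Binary triangle surfaces (``lh.white`` and friends) — vertex coordinates
  plus triangular faces.

Vertex indices are 0-based everywhere in this package, including text
reports.  This follows the FreeSurfer convention for ``.mgh`` maps and keeps
indices consistent with the in-memory arrays.
"""

from __future__ import annotations

import gzip
import os
import re
import struct
import tempfile
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FormatError",
    "MghImage",
    "SurfaceMesh",
    "VertexMapStack",
    "read_mgh",
    "write_mgh",
    "read_surface",
    "write_surface",
    "load_stack",
    "map_filename",
    "parse_map_filename",
]


class FormatError(ValueError):
    """Raised when a file does not conform to the expected binary layout."""


# MGH dtype codes (FreeSurfer convention).
_MGH_DTYPES = {0: np.dtype(">u1"), 1: np.dtype(">i4"), 3: np.dtype(">f4"), 4: np.dtype(">i2")}
_MGH_CODES = {np.dtype(np.uint8): 0, np.dtype(np.int32): 1, np.dtype(np.float32): 3, np.dtype(np.int16): 4}

_HEADER_SIZE = 284
_SURF_MAGIC = b"\xff\xff\xfe"

# Default direction cosines written when no geometry is known; this is the
# conventional FreeSurfer default for coronal volumes and is what most tools
# write for surface maps, where the geometry block is meaningless anyway.
_DEFAULT_MDC = np.array([[-1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=np.float32)


@dataclass
class MghImage:
    """An MGH volume: a 4-D array plus the header fields we preserve.

    Parameters
    ----------
    data:
        Array of shape ``(width, height, depth, nframes)``.
    dtype_code:
        0 = uint8, 1 = int32, 3 = float32, 4 = int16.
    ras_valid:
        Whether the geometry block (spacing, direction cosines) is meaningful.
    spacing:
        Voxel spacing in mm.
    footer:
        ``(TR, flip_angle, TE, TI)`` scan parameters, or ``None`` if absent.
    """

    data: np.ndarray
    dtype_code: int = 3
    ras_valid: bool = True
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    footer: tuple[float, float, float, float] | None = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"MGH data must be 4-D, got shape {self.data.shape}")
        if self.dtype_code not in _MGH_DTYPES:
            raise FormatError(f"unsupported MGH dtype code {self.dtype_code}")

    @classmethod
    def from_map(cls, values: np.ndarray) -> "MghImage":
        """Wrap a per-vertex map (1-D, length V) as a float32 surface MGH."""
        values = np.asarray(values, dtype=np.float32)
        if values.ndim != 1:
            raise ValueError("per-vertex map must be 1-D")
        return cls(data=values.reshape(-1, 1, 1, 1), dtype_code=3)

    @property
    def vertex_values(self) -> np.ndarray:
        """The map as a 1-D vector (requires height = depth = nframes = 1)."""
        w, h, d, f = self.data.shape
        if (h, d, f) != (1, 1, 1):
            raise ValueError(f"not a single-subject surface map: shape {self.data.shape}")
        return self.data[:, 0, 0, 0]


def _open_maybe_gz(path: Path, mode: str):
    if path.suffix == ".mgz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_mgh(path: os.PathLike | str) -> MghImage:
    """Read an ``.mgh`` (or gzip-compressed ``.mgz``) file."""
    path = Path(path)
    with _open_maybe_gz(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER_SIZE:
        raise FormatError(f"{path}: truncated header ({len(raw)} bytes)")
    version, width, height, depth, nframes, dtype_code, _dof = struct.unpack(">7i", raw[:28])
    if version != 1:
        raise FormatError(f"{path}: unsupported MGH version {version}")
    if dtype_code not in _MGH_DTYPES:
        raise FormatError(f"{path}: unsupported MGH dtype code {dtype_code}")
    (ras_good,) = struct.unpack(">h", raw[28:30])
    spacing = (1.0, 1.0, 1.0)
    if ras_good > 0:
        spacing = struct.unpack(">3f", raw[30:42])
    dtype = _MGH_DTYPES[dtype_code]
    n_items = width * height * depth * nframes
    end = _HEADER_SIZE + n_items * dtype.itemsize
    if len(raw) < end:
        raise FormatError(
            f"{path}: truncated payload ({len(raw) - _HEADER_SIZE} bytes, "
            f"expected {n_items * dtype.itemsize})"
        )
    flat = np.frombuffer(raw[_HEADER_SIZE:end], dtype=dtype)
    # File order is width-fastest: frames, depth, height, width (C order).
    data = flat.reshape(nframes, depth, height, width).transpose(3, 2, 1, 0)
    data = np.ascontiguousarray(data.astype(dtype.newbyteorder("=")))
    footer = None
    if len(raw) >= end + 16:
        footer = struct.unpack(">4f", raw[end : end + 16])
    return MghImage(
        data=data,
        dtype_code=dtype_code,
        ras_valid=bool(ras_good > 0),
        spacing=tuple(float(s) for s in spacing),
        footer=footer,
    )


def write_mgh(img: MghImage, path: os.PathLike | str) -> None:
    """Write an :class:`MghImage`; a ``.mgz`` suffix triggers gzip compression."""
    path = Path(path)
    if img.dtype_code not in _MGH_DTYPES:
        raise FormatError(f"unsupported MGH dtype code {img.dtype_code}")
    dtype = _MGH_DTYPES[img.dtype_code]
    w, h, d, f = img.data.shape
    header = struct.pack(">7i", 1, w, h, d, f, img.dtype_code, 0)
    header += struct.pack(">h", 1 if img.ras_valid else 0)
    geom = struct.pack(">3f", *img.spacing)
    geom += _DEFAULT_MDC.astype(">f4").tobytes()
    geom += struct.pack(">3f", 0.0, 0.0, 0.0)
    header += geom
    header += b"\x00" * (_HEADER_SIZE - len(header))
    payload = np.ascontiguousarray(img.data.transpose(3, 2, 1, 0), dtype=dtype).tobytes()
    out = header + payload
    if img.footer is not None:
        out += struct.pack(">4f", *img.footer)
    with _open_maybe_gz(path, "wb") as fh:
        fh.write(out)


@dataclass
class SurfaceMesh:
    """A triangle mesh with derived per-vertex quantities.

    ``vertex_area`` allocates one third of each incident triangle's area to
    each of its corners (barycentric allocation), so that the per-vertex
    areas sum exactly to the total surface area and cluster extents come out
    in mm².
    """

    coords: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int, 0-based

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.coords)):
            raise FormatError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.coords)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with u < v."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    @cached_property
    def adjacency(self) -> list[np.ndarray]:
        """Per-vertex sorted neighbor index lists (symmetric by construction)."""
        adj: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return [np.array(sorted(a), dtype=np.int64) for a in adj]

    @cached_property
    def triangle_area(self) -> np.ndarray:
        a = self.coords[self.faces[:, 0]]
        b = self.coords[self.faces[:, 1]]
        c = self.coords[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    @cached_property
    def vertex_area(self) -> np.ndarray:
        area = np.zeros(self.n_vertices)
        third = self.triangle_area / 3.0
        for k in range(3):
            np.add.at(area, self.faces[:, k], third)
        return area

    @cached_property
    def edge_mean(self) -> float:
        """Mean edge length in mm."""
        d = self.coords[self.edges[:, 0]] - self.coords[self.edges[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())

    @cached_property
    def total_area(self) -> float:
        return float(self.triangle_area.sum())


def read_surface(path: os.PathLike | str) -> SurfaceMesh:
    """Read a FreeSurfer binary triangle surface."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = fh.read()
    if raw[:3] != _SURF_MAGIC:
        raise FormatError(f"{path}: bad magic {raw[:3]!r}, not a binary triangle surface")
    nn = raw.find(b"\n\n", 3)
    if nn < 0:
        raise FormatError(f"{path}: unterminated comment")
    offset = nn + 2
    v_count, f_count = struct.unpack(">2i", raw[offset : offset + 8])
    offset += 8
    coords = np.frombuffer(raw, dtype=">f4", count=v_count * 3, offset=offset).reshape(-1, 3)
    offset += v_count * 12
    faces = np.frombuffer(raw, dtype=">i4", count=f_count * 3, offset=offset).reshape(-1, 3)
    if faces.size and (faces.min() < 0 or faces.max() >= v_count):
        raise FormatError(f"{path}: face index out of range (V={v_count})")
    return SurfaceMesh(coords=coords.astype(np.float64), faces=faces.astype(np.int64))


def write_surface(mesh: SurfaceMesh, path: os.PathLike | str, comment: str = "created by surfglm") -> None:
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(_SURF_MAGIC)
        fh.write(comment.encode("latin-1") + b"\n\n")
        fh.write(struct.pack(">2i", mesh.n_vertices, mesh.n_faces))
        fh.write(mesh.coords.astype(">f4").tobytes())
        fh.write(mesh.faces.astype(">i4").tobytes())


# ---------------------------------------------------------------------------
# Subjects-directory conventions


def map_filename(hemi: str, measure: str, fwhm: int, target: str) -> str:
    """File name of a smoothed, template-resampled surface map."""
    return f"{hemi}.{measure}.fwhm{int(fwhm)}.{target}.mgh"


_MAP_RE = re.compile(r"^(lh|rh)\.(.+)\.fwhm(\d+)\.([^.]+)\.mgh(\.gz)?$")


def parse_map_filename(name: str) -> dict:
    """Parse ``lh.<measure>.fwhm<k>.<target>.mgh`` into its components.

    The measure itself may contain dots (``area.pial``, ``w-g.pct``), so the
    hemisphere is taken from the front and the target / fwhm tokens from the
    back.
    """
    name = os.path.basename(str(name))
    if name.endswith(".mgz"):
        name = name[:-4] + ".mgh"
    m = _MAP_RE.match(name)
    if not m:
        raise ValueError(f"not a recognized surface-map file name: {name!r}")
    return {
        "hemi": m.group(1),
        "measure": m.group(2),
        "fwhm": int(m.group(3)),
        "target": m.group(4),
    }


class VertexMapStack:
    """An N_subjects × V matrix of one per-vertex measure.

    Rows are bound to an ordered list of subject identifiers.  The backing
    array may be an on-disk memory map when the matrix would exceed the
    memory budget; the API is identical either way, and consumers address
    the matrix in vertex chunks so that only ``n × chunk_size`` values are
    materialized at once.
    """

    def __init__(self, data: np.ndarray, ids: Sequence[str]):
        if data.ndim != 2:
            raise ValueError("stack must be 2-D (subjects × vertices)")
        if len(ids) != data.shape[0]:
            raise ValueError("number of ids must match number of rows")
        self.data = data
        self.ids = list(ids)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]

    def chunk(self, cols: np.ndarray) -> np.ndarray:
        """Materialize the columns ``cols`` as an in-memory float64 array."""
        return np.asarray(self.data[:, cols], dtype=np.float64)


def _subject_map_path(dir_subj: Path, sid: str, hemi: str, measure: str, fwhm: int, target: str) -> Path | None:
    base = dir_subj / str(sid) / "surf" / map_filename(hemi, measure, fwhm, target)
    if base.exists():
        return base
    gz = base.with_suffix(".mgz")
    if gz.exists():
        return gz
    return None


def load_stack(
    dir_subj: os.PathLike | str,
    ids: Sequence[str],
    hemi: str,
    measure: str,
    fwhm: int,
    target: str,
    mem_budget_bytes: int = 1 << 30,
) -> VertexMapStack:
    """Load one map per subject into an N × V stack, in the order of ``ids``.

    Missing files are collected and reported together.  When the full matrix
    would exceed ``mem_budget_bytes`` it is backed by a temporary on-disk
    memory map instead of RAM.
    """
    dir_subj = Path(dir_subj)
    paths = []
    missing = []
    for sid in ids:
        p = _subject_map_path(dir_subj, sid, hemi, measure, fwhm, target)
        if p is None:
            missing.append(str(sid))
        else:
            paths.append(p)
    if missing:
        raise FileNotFoundError(
            f"no {hemi}.{measure} map for {len(missing)} subject(s): {', '.join(missing)}"
        )
    first = read_mgh(paths[0]).vertex_values
    n_v = first.shape[0]
    n = len(ids)
    if n * n_v * 8 > mem_budget_bytes:
        tmp = tempfile.NamedTemporaryFile(prefix="surfglm_stack_", suffix=".dat", delete=False)
        tmp.close()
        data = np.memmap(tmp.name, dtype=np.float64, mode="w+", shape=(n, n_v))
    else:
        data = np.empty((n, n_v), dtype=np.float64)
    data[0] = first
    for i, p in enumerate(paths[1:], start=1):
        vals = read_mgh(p).vertex_values
        if vals.shape[0] != n_v:
            raise FormatError(
                f"{p}: vertex count {vals.shape[0]} differs from first subject ({n_v})"
            )
        data[i] = vals
    return VertexMapStack(data, ids)
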