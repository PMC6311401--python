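"""STL input/output (binary and ASCII dialects).

Digital dental models are exchanged as STL; this module reads either
dialect into a :class:`~rootaxis.geometry.TriangleMesh` with duplicate
vertices welded at 1e-6 mm, and writes both dialects back out.

Dialect detection follows the de-facto convention: files beginning with
``solid`` are tentatively ASCII but fall back to binary when no facet can
be parsed (some exporters write binary files with a ``solid`` header).
Structural errors in binary files are reported with the byte offset at
which the file ends short.
"""

from __future__ import annotations

import io
import os
from pathlib import Path

import numpy as np
import trimesh

from .geometry import GeometryError, TriangleMesh

__all__ = ["read_stl", "write_stl", "STLParseError", "write_outline_csv"]

_BINARY_HEADER = 80
_FACET_BYTES = 50
_WELD_TOL = 1e-6  # mm


class STLParseError(GeometryError):
    """Malformed STL file."""


def _looks_ascii(head: bytes) -> bool:
    return head.lstrip()[:5].lower() == b"solid"


def _validate_binary(raw: bytes, path: str) -> None:
    if len(raw) < _BINARY_HEADER + 4:
        raise STLParseError(
            f"{path}: binary STL truncated in header at byte {len(raw)} "
            f"(need at least {_BINARY_HEADER + 4})"
        )
    n_facets = int(np.frombuffer(raw, dtype="<u4", count=1, offset=_BINARY_HEADER)[0])
    expected = _BINARY_HEADER + 4 + n_facets * _FACET_BYTES
    if len(raw) < expected:
        raise STLParseError(
            f"{path}: binary STL declares {n_facets} facets "
            f"({expected} bytes) but the file ends at byte {len(raw)}"
        )


def _weld(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than the weld tolerance (grid snap)."""
    key = np.round(vertices / _WELD_TOL).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    welded = vertices[first]
    faces = inverse[faces]
    # drop faces degenerated by the weld
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    return welded, faces[ok]


def read_stl(path: str | os.PathLike) -> TriangleMesh:
    """Read a binary or ASCII STL file into a welded triangle mesh."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) == 0:
        raise STLParseError(f"{path}: empty file")

    dialect = "ascii" if _looks_ascii(raw[:_BINARY_HEADER]) else "binary"
    if dialect == "ascii":
        try:
            data = trimesh.exchange.stl.load_stl_ascii(io.BytesIO(raw))
            if len(data.get("faces", ())) == 0:
                dialect = "binary"
        except Exception:
            dialect = "binary"  # 'solid'-headed binary file
    if dialect == "binary":
        _validate_binary(raw, str(path))
        try:
            data = trimesh.exchange.stl.load_stl_binary(io.BytesIO(raw))
        except Exception as exc:  # pragma: no cover - validated above
            raise STLParseError(f"{path}: {exc}") from exc

    vertices = np.asarray(data["vertices"], dtype=np.float64)
    faces = np.asarray(data["faces"], dtype=np.int64)
    if len(faces) == 0:
        raise STLParseError(f"{path}: STL contains no facets")
    vertices, faces = _weld(vertices, faces)
    mesh = TriangleMesh(vertices, faces)
    mesh.validate()
    return mesh


def write_stl(mesh: TriangleMesh, path: str | os.PathLike, dialect: str = "binary") -> None:
    """Write a mesh as STL.  Binary stores 32-bit floats, so a round trip
    reproduces coordinates to ~1e-5 mm, not exactly."""
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    mesh.validate()
    tm = mesh.to_trimesh()
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    data = tm.export(file_type=file_type)
    path = Path(path)
    if isinstance(data, str):
        path.write_text(data)
    else:
        path.write_bytes(data)


def write_outline_csv(loops, path: str | os.PathLike) -> None:
    """Debug export: outline points as CSV rows ``loop_id,x,y,z``."""
    with open(path, "w") as fh:
        fh.write("loop_id,x,y,z\n")
        for i, loop in enumerate(loops):
            for p in loop.points:
                fh.write(f"{i},{p[0]:.9g},{p[1]:.9g},{p[2]:.9g}\n")
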