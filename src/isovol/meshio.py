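"""Boundary-mesh I/O (OFF / PLY) via trimesh."""

from __future__ import annotations

import numpy as np
import trimesh

from .solids import TriangleMesh

__all__ = ["write_mesh", "read_mesh"]


def write_mesh(mesh: TriangleMesh, path: str) -> None:
    """Write a triangle mesh as OFF or PLY (by file extension)."""
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.triangles, process=False
    )
    tm.export(path)


def read_mesh(path: str) -> TriangleMesh:
    """Read an OFF/PLY triangle mesh (triangulating polygon faces)."""
    tm = trimesh.load_mesh(path, process=False)
    faces = np.asarray(tm.faces, dtype=np.int64)
    return TriangleMesh(np.asarray(tm.vertices, dtype=float), faces)
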