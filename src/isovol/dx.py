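"""OpenDX scalar-grid I/O ("object 1 class gridpositions" dialect).

This is the grid format emitted by APBS and by DelPhi-to-DX converters, so
externally computed Poisson-Boltzmann potentials can be injected into the
pipeline.  Only regular grids with axis-aligned, isotropic deltas map onto a
:class:`~isovol.lattice.Lattice`; anything else is rejected.  Data values
follow the usual DX ordering (z varies fastest), which matches the C-order
flattening of our ``(nx, ny, nz)`` value arrays.
"""

from __future__ import annotations

import numpy as np

from .lattice import Lattice, ScalarFieldGrid

__all__ = ["read_dx", "write_dx"]


def write_dx(field: ScalarFieldGrid, path: str, comment: str = "") -> None:
    lat = field.lattice
    nx, ny, nz = lat.dims
    h = lat.spacing
    lines = []
    if comment:
        for row in comment.splitlines():
            lines.append(f"# {row}")
    lines.append(f"object 1 class gridpositions counts {nx} {ny} {nz}")
    lines.append(f"origin {lat.origin[0]:.6e} {lat.origin[1]:.6e} {lat.origin[2]:.6e}")
    lines.append(f"delta {h:.6e} 0.000000e+00 0.000000e+00")
    lines.append(f"delta 0.000000e+00 {h:.6e} 0.000000e+00")
    lines.append(f"delta 0.000000e+00 0.000000e+00 {h:.6e}")
    lines.append(f"object 2 class gridconnections counts {nx} {ny} {nz}")
    lines.append(
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows"
    )
    flat = field.values.ravel()
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dx(path: str) -> ScalarFieldGrid:
    counts = origin = None
    deltas: list[list[float]] = []
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if line.startswith("object") and "gridpositions" in line:
                counts = tuple(int(v) for v in tok[-3:])
            elif tok[0] == "origin":
                origin = tuple(float(v) for v in tok[1:4])
            elif tok[0] == "delta":
                deltas.append([float(v) for v in tok[1:4]])
            elif line.startswith("object") and "data follows" in line:
                n_items = int(tok[tok.index("items") + 1])
            elif n_items is not None and len(values) < n_items:
                try:
                    values.extend(float(v) for v in tok)
                except ValueError:
                    break
    if counts is None or origin is None or len(deltas) != 3 or n_items is None:
        raise ValueError(f"{path}: not a gridpositions OpenDX scalar grid")
    d = np.asarray(deltas)
    if not np.allclose(d, np.diag(np.diag(d))):
        raise ValueError(f"{path}: only axis-aligned deltas are supported")
    steps = np.diag(d)
    if not np.allclose(steps, steps[0]):
        raise ValueError(f"{path}: only isotropic (cubic) grids are supported")
    if len(values) != n_items:
        raise ValueError(
            f"{path}: expected {n_items} data values, found {len(values)}"
        )
    lat = Lattice(origin=origin, spacing=float(steps[0]), dims=counts)
    return ScalarFieldGrid(lat, np.asarray(values, dtype=float).reshape(counts))
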