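"""Solid regions on a lattice and their boolean (CSG) volume algebra.

A :class:`SolidRegion` is the universal currency of the toolkit: solid
isopotentials, molecular surfaces, binding cavities, interface regions and
every CSG output are all closed boundary meshes backed by a per-lattice-point
signed insideness field (a point is inside iff its value is >= 0).

CSG is realised on the lattice: intersection, union and difference combine
the signed fields pointwise (min / max / min with negation), which makes the
boolean occupancy exact and re-extracts the boundary mesh from the combined
field.  Where a lattice edge's crossing comes from a single operand, the
crossing position is inherited from that operand's interpolation; elsewhere
the crossing falls back toward the cube midpoint.  Volumes come from the
Surveyor's (divergence-theorem) formula over the closed boundary mesh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .lattice import Lattice
from .marching import extract_surface

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "SolidRegion",
    "csg",
    "volume",
    "jaccard_distance",
    "resample_to",
    "mesh_volume",
    "mesh_is_closed",
    "occupancy_from_mesh",
]


@dataclass
class TriangleMesh:
    """Triangles (index triples, CCW seen from outside) over vertices in Å."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise ValueError("triangle indices out of range")
            if np.any(
                (self.triangles[:, 0] == self.triangles[:, 1])
                | (self.triangles[:, 1] == self.triangles[:, 2])
                | (self.triangles[:, 0] == self.triangles[:, 2])
            ):
                raise ValueError("a triangle repeats a vertex index")

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def is_empty(self) -> bool:
        return self.n_triangles == 0


def mesh_is_closed(mesh: TriangleMesh) -> bool:
    """True iff every undirected edge is shared by exactly two triangles with
    consistent (opposite) orientation.  An empty mesh is trivially closed."""
    if mesh.is_empty():
        return True
    t = mesh.triangles
    directed = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    # each directed edge must appear exactly once
    d_keys = directed[:, 0] * (mesh.vertices.shape[0] + 1) + directed[:, 1]
    if len(np.unique(d_keys)) != len(d_keys):
        return False
    lo = directed.min(axis=1)
    hi = directed.max(axis=1)
    u_keys = lo * (mesh.vertices.shape[0] + 1) + hi
    _, counts = np.unique(u_keys, return_counts=True)
    return bool(np.all(counts == 2))


def mesh_volume(mesh: TriangleMesh) -> float:
    """Surveyor's Formula: |sum over triangles of det[v0 v1 v2]| / 6."""
    if mesh.is_empty():
        return 0.0
    v = mesh.vertices[mesh.triangles]  # (T, 3, 3)
    dets = np.einsum(
        "ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])
    )
    return float(abs(dets.sum()) / 6.0)


class SolidRegion:
    """A closed solid: lattice occupancy + lazily extracted boundary mesh.

    ``signed`` is the per-point insideness field; ``occupancy`` is exactly
    ``signed >= 0``.  The boundary mesh and the Surveyor volume are computed
    on demand and cached.
    """

    def __init__(
        self,
        lattice: Lattice,
        signed: np.ndarray,
        leaves: tuple[str, list[np.ndarray]] | None = None,
    ):
        signed = np.asarray(signed, dtype=float)
        if signed.shape != lattice.dims:
            raise ValueError(
                f"signed field shape {signed.shape} != lattice dims {lattice.dims}"
            )
        if not np.all(np.isfinite(signed)):
            raise ValueError("signed field must be finite")
        self.lattice = lattice
        self.signed = signed
        # CSG provenance: signed == op(leaves) pointwise, used for exact
        # crossing positions on edges where several operands compete
        self.leaves = leaves
        self._mesh: TriangleMesh | None = None
        self._volume: float | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_occupancy(cls, lattice: Lattice, occupancy: np.ndarray) -> "SolidRegion":
        """Solid from a boolean occupancy map; boundary crossings fall at
        lattice-edge midpoints (the cube-midpoint convention)."""
        occupancy = np.asarray(occupancy, dtype=bool)
        return cls(lattice, np.where(occupancy, 1.0, -1.0))

    @classmethod
    def empty(cls, lattice: Lattice) -> "SolidRegion":
        return cls(lattice, np.full(lattice.dims, -1.0))

    # -- basic queries -------------------------------------------------------

    @property
    def occupancy(self) -> np.ndarray:
        return self.signed >= 0.0

    def is_empty(self) -> bool:
        return not bool(self.occupancy.any())

    @property
    def mesh(self) -> TriangleMesh:
        if self._mesh is None:
            verts, tris = extract_surface(
                self.lattice.axes(), self.signed, leaves=self.leaves
            )
            self._mesh = TriangleMesh(verts, tris)
        return self._mesh

    def volume(self) -> float:
        """Surveyor's-formula volume of the boundary mesh, in ų (cached)."""
        if self._volume is None:
            mesh = self.mesh
            if not mesh.is_empty() and not mesh_is_closed(mesh):
                raise ValueError("volume undefined: boundary mesh is not closed")
            self._volume = mesh_volume(mesh)
        return self._volume

    def voxel_volume(self) -> float:
        """Independent voxel-counting estimate: spacing^3 x inside points,
        each lattice point owning its half-open cube."""
        return float(self.occupancy.sum()) * self.lattice.spacing**3

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SolidRegion(dims={self.lattice.dims}, "
            f"spacing={self.lattice.spacing}, inside={int(self.occupancy.sum())})"
        )


# -- CSG --------------------------------------------------------------------

_TINY = np.finfo(float).tiny


def _negate(signed: np.ndarray) -> np.ndarray:
    # Points exactly on a boundary (signed == 0) belong to the solid, so the
    # complement must exclude them: nudge to a negative denormal.
    out = -signed
    out[out == 0.0] = -_TINY
    return out


def _as_leaves(s: SolidRegion, op: str) -> list[np.ndarray] | None:
    if s.leaves is None:
        return [s.signed]
    return list(s.leaves[1]) if s.leaves[0] == op else None


def csg(op: str, a: SolidRegion, b: SolidRegion) -> SolidRegion:
    """Boolean combination of two solids on congruent lattices.

    ``op`` is one of ``intersection``, ``union``, ``difference``.  Occupancy
    of the output is the exact pointwise AND / OR / AND-NOT of the inputs.
    Operand provenance is kept where the result is a flat min/max of
    operands, so boundary crossings stay exact at operand creases; deeper
    mixed nestings fall back to interpolating the combined field.
    """
    a.lattice.require_congruent(b.lattice, f"CSG {op}")
    leaves: tuple[str, list[np.ndarray]] | None = None
    if op == "intersection":
        s = np.minimum(a.signed, b.signed)
        la, lb = _as_leaves(a, "min"), _as_leaves(b, "min")
        if la is not None and lb is not None:
            leaves = ("min", la + lb)
    elif op == "union":
        s = np.maximum(a.signed, b.signed)
        la, lb = _as_leaves(a, "max"), _as_leaves(b, "max")
        if la is not None and lb is not None:
            leaves = ("max", la + lb)
    elif op == "difference":
        s = np.minimum(a.signed, _negate(b.signed))
        la = _as_leaves(a, "min")
        lb = _as_leaves(b, "max")  # De Morgan: -max(b_i) = min(-b_i)
        if la is not None and lb is not None:
            leaves = ("min", la + [_negate(l) for l in lb])
    else:
        raise ValueError(f"unknown CSG op {op!r}")
    return SolidRegion(a.lattice, s, leaves=leaves)


def complement(s: SolidRegion) -> SolidRegion:
    """Set complement as a signed field (an unbounded region: useful as a
    CSG operand, not meshable on its own)."""
    leaves = None
    if s.leaves is None:
        leaves = ("min", [_negate(s.signed)])
    elif s.leaves[0] == "max":  # De Morgan
        leaves = ("min", [_negate(l) for l in s.leaves[1]])
    elif s.leaves[0] == "min":
        leaves = ("max", [_negate(l) for l in s.leaves[1]])
    return SolidRegion(s.lattice, _negate(s.signed), leaves=leaves)


def intersection(a: SolidRegion, b: SolidRegion) -> SolidRegion:
    return csg("intersection", a, b)


def union(a: SolidRegion, b: SolidRegion) -> SolidRegion:
    return csg("union", a, b)


def difference(a: SolidRegion, b: SolidRegion) -> SolidRegion:
    return csg("difference", a, b)


def volume(s: SolidRegion) -> float:
    return s.volume()


def jaccard_distance(a: SolidRegion, b: SolidRegion) -> float:
    """1 - V(A∩B) / V(A∪B); in [0, 1]; symmetric.

    Undefined (raises) when both solids are empty.
    """
    a.lattice.require_congruent(b.lattice, "Jaccard distance")
    if a.is_empty() and b.is_empty():
        raise ValueError("Jaccard distance undefined for two empty solids")
    v_union = union(a, b).volume()
    if v_union == 0.0:
        # nonempty occupancy but degenerate mesh volume; treat as disjoint
        return 1.0
    v_inter = intersection(a, b).volume()
    d = 1.0 - v_inter / v_union
    return float(min(max(d, 0.0), 1.0))


# -- point-in-mesh resampling ----------------------------------------------

def occupancy_from_mesh(
    mesh: TriangleMesh, lattice: Lattice, _offset_scale: float = 1e-3
) -> np.ndarray:
    """Voxelize a closed mesh onto a lattice by axis-aligned ray parity.

    Rays run along +x at every (y, z) lattice line; ray origins are nudged by
    a tiny irrational fraction of the spacing so rays never hit triangle
    edges or vertices exactly.
    """
    if not mesh_is_closed(mesh):
        raise ValueError("point-in-solid test requires a closed mesh")
    nx, ny, nz = lattice.dims
    occ = np.zeros(lattice.dims, dtype=bool)
    if mesh.is_empty():
        return occ
    h = lattice.spacing
    dy = _offset_scale * h * (np.sqrt(2) - 1.0)
    dz = _offset_scale * h * (np.sqrt(3) - 1.0)
    xs, ys, zs = lattice.axes()
    yq = ys + dy
    zq = zs + dz

    # crossing x-values per (j, k) column
    crossings: dict[tuple[int, int], list[float]] = {}
    tri = mesh.vertices[mesh.triangles]  # (T, 3, 3)
    for A, B, C in tri:
        ylo, yhi = min(A[1], B[1], C[1]), max(A[1], B[1], C[1])
        zlo, zhi = min(A[2], B[2], C[2]), max(A[2], B[2], C[2])
        j0 = int(np.searchsorted(yq, ylo))
        j1 = int(np.searchsorted(yq, yhi))
        k0 = int(np.searchsorted(zq, zlo))
        k1 = int(np.searchsorted(zq, zhi))
        if j0 >= j1 or k0 >= k1:
            continue
        d1 = B - A
        d2 = C - A
        det = d1[1] * d2[2] - d2[1] * d1[2]
        if det == 0.0:
            continue  # triangle parallel to the rays
        jj, kk = np.meshgrid(np.arange(j0, j1), np.arange(k0, k1), indexing="ij")
        py = yq[jj] - A[1]
        pz = zq[kk] - A[2]
        u = (py * d2[2] - d2[1] * pz) / det
        v = (d1[1] * pz - py * d1[2]) / det
        hit = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        if not hit.any():
            continue
        xhit = A[0] + u[hit] * d1[0] + v[hit] * d2[0]
        for j, k, xv in zip(jj[hit], kk[hit], xhit):
            crossings.setdefault((int(j), int(k)), []).append(float(xv))

    for (j, k), xvals in crossings.items():
        xvals.sort()
        # parity of crossings strictly beyond each lattice x
        idx = np.searchsorted(xvals, xs, side="right")
        occ[:, j, k] = ((len(xvals) - idx) % 2).astype(bool)
    return occ


def resample_to(s: SolidRegion, target: Lattice) -> SolidRegion:
    """Re-evaluate a solid on another lattice via point-in-solid tests."""
    if s.lattice.congruent(target):
        return SolidRegion(target, s.signed.copy())
    if target.spacing > 2.0 * s.lattice.spacing:
        raise ValueError(
            "resampling to a lattice more than 2x coarser loses the boundary; "
            f"source spacing {s.lattice.spacing}, target {target.spacing}"
        )
    occ = occupancy_from_mesh(s.mesh, target)
    return SolidRegion.from_occupancy(target, occ)


# -- occupancy run-length text fixtures -------------------------------------

def occupancy_to_rle(s: SolidRegion) -> str:
    """Compact run-length text encoding of an occupancy map (test fixtures)."""
    flat = s.occupancy.ravel()
    runs = []
    if flat.size:
        change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
        bounds = np.concatenate([[0], change, [flat.size]])
        runs = [
            f"{int(flat[b])}x{e - b}" for b, e in zip(bounds[:-1], bounds[1:])
        ]
    lat = s.lattice
    head = (
        f"dims {lat.dims[0]} {lat.dims[1]} {lat.dims[2]} "
        f"origin {lat.origin[0]!r} {lat.origin[1]!r} {lat.origin[2]!r} "
        f"spacing {lat.spacing!r}"
    )
    return head + "\n" + " ".join(runs) + "\n"


def occupancy_from_rle(text: str) -> SolidRegion:
    head, body = text.strip().split("\n", 1)
    tok = head.split()
    dims = (int(tok[1]), int(tok[2]), int(tok[3]))
    origin = (float(tok[5]), float(tok[6]), float(tok[7]))
    spacing = float(tok[9])
    lat = Lattice(origin=origin, spacing=spacing, dims=dims)
    flat = np.empty(lat.n_points, dtype=bool)
    pos = 0
    for run in body.split():
        val, n = run.split("x")
        flat[pos:pos + int(n)] = bool(int(val))
        pos += int(n)
    if pos != lat.n_points:
        raise ValueError("run-length data does not match lattice dims")
    return SolidRegion.from_occupancy(lat, flat.reshape(lat.dims))
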