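"""Molecular-surface solids, cavity solids, and interface regions.

The interface region of a complex follows the atom-proximity rule: residues
of one protein with any atom within 5 Å of the partner are interfacial, and
the region is the CSG union of 5 Å spheres centred on every atom of those
residues.  Residues are deliberately not filtered by solvent exposure —
buried "hot spot" residues stay in.

The solvent-excluded surface (SES) is approximated by grid morphology:
dilate the union of van der Waals balls by the probe radius, then erode by
the same radius (a morphological closing), both as Euclidean-distance
threshold operations on the lattice.  Crevices too narrow for the probe are
sealed, as with the classical rolling-probe construction, to within lattice
resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .electrostatics import ChargedStructure, ResidueID
from .lattice import Lattice
from .solids import SolidRegion, occupancy_from_mesh

logger = logging.getLogger(__name__)

__all__ = [
    "RegionParams",
    "union_of_balls_solid",
    "sphere_union_solid",
    "molecular_surface_solid",
    "interface_residues",
    "interface_region",
    "cavity_solid",
    "read_sphere_spec",
    "write_sphere_spec",
]


@dataclass(frozen=True)
class RegionParams:
    """Geometric parameters for surfaces and interface regions (Å)."""

    probe_radius: float = 1.4
    interface_cutoff: float = 5.0
    interface_sphere_radius: float = 5.0

    def __post_init__(self) -> None:
        for name in ("probe_radius", "interface_cutoff", "interface_sphere_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


_FAR = -1.0e9


def _balls_signed(
    centers: np.ndarray, radii: np.ndarray, lat: Lattice
) -> np.ndarray:
    """Signed insideness max_i(r_i - |p - x_i|), evaluated exactly within a
    margin of each ball and left at a large negative elsewhere."""
    signed = np.full(lat.dims, _FAR)
    x, y, z = lat.axes()
    h = lat.spacing
    for pos, r in zip(centers, radii):
        margin = r + 3.0 * h
        i0, i1 = np.searchsorted(x, [pos[0] - margin, pos[0] + margin])
        j0, j1 = np.searchsorted(y, [pos[1] - margin, pos[1] + margin])
        k0, k1 = np.searchsorted(z, [pos[2] - margin, pos[2] + margin])
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        dx = x[i0:i1] - pos[0]
        dy = y[j0:j1] - pos[1]
        dz = z[k0:k1] - pos[2]
        d = np.sqrt(
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        np.maximum(signed[i0:i1, j0:j1, k0:k1], r - d,
                   out=signed[i0:i1, j0:j1, k0:k1])
    return signed


def sphere_union_solid(
    centers: np.ndarray, radii: np.ndarray, lat: Lattice
) -> SolidRegion:
    """Union-of-balls solid from explicit sphere centers and radii."""
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(centers),))
    if len(centers) == 0:
        return SolidRegion.empty(lat)
    return SolidRegion(lat, _balls_signed(centers, radii, lat))


def union_of_balls_solid(
    s: ChargedStructure, lat: Lattice, inflate: float = 0.0
) -> SolidRegion:
    """Solid of points within (atom radius + inflate) of any atom."""
    if s.n_atoms == 0:
        return SolidRegion.empty(lat)
    return sphere_union_solid(s.positions, s.radii + inflate, lat)


def molecular_surface_solid(
    s: ChargedStructure, lat: Lattice, p: RegionParams | None = None
) -> SolidRegion:
    """Solvent-excluded solid by morphological closing at the probe radius."""
    p = p or RegionParams()
    if s.n_atoms == 0:
        return SolidRegion.empty(lat)
    balls = union_of_balls_solid(s, lat)
    dilated = union_of_balls_solid(s, lat, inflate=p.probe_radius)
    # distance of every point in the dilated solid to its exterior; erosion
    # keeps points deeper than the probe radius.  The EDT measures to the
    # nearest exterior lattice point, overshooting the continuum boundary by
    # about half a voxel, hence the debias term.
    d_in = distance_transform_edt(
        dilated.occupancy, sampling=(lat.spacing,) * 3
    )
    ses_signed = d_in - 0.5 * lat.spacing - p.probe_radius
    # closing never removes the input region: keep the union-of-balls floor
    return SolidRegion(lat, np.maximum(ses_signed, balls.signed))


def interface_residues(
    a: ChargedStructure, b: ChargedStructure, p: RegionParams | None = None
) -> tuple[list[ResidueID], list[ResidueID]]:
    """Residues of each protein with any atom within the cutoff of the other.

    All atoms count (hydrogens included when present).  Lists come back in
    deterministic (chain, number, insertion) order.
    """
    p = p or RegionParams()
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise ValueError("interface_residues needs two nonempty structures")
    tree_b = cKDTree(b.positions)
    d_a, _ = tree_b.query(a.positions)
    tree_a = cKDTree(a.positions)
    d_b, _ = tree_a.query(b.positions)

    def pick(s: ChargedStructure, dists: np.ndarray) -> list[ResidueID]:
        out = []
        for rid in s.residue_ids():
            if dists[s.residue_index[rid]].min() <= p.interface_cutoff:
                out.append(rid)
        return out

    return pick(a, d_a), pick(b, d_b)


def interface_region(
    a: ChargedStructure,
    b: ChargedStructure,
    lat: Lattice,
    p: RegionParams | None = None,
) -> SolidRegion:
    """CSG union of fixed-radius spheres on every atom of the interfacial
    residues of both proteins."""
    p = p or RegionParams()
    rids_a, rids_b = interface_residues(a, b, p)
    centers = []
    for s, rids in ((a, rids_a), (b, rids_b)):
        for rid in rids:
            centers.append(s.positions[s.residue_index[rid]])
    if not centers:
        logger.warning("no interfacial residues within cutoff; empty region")
        return SolidRegion.empty(lat)
    centers = np.concatenate(centers, axis=0)
    return sphere_union_solid(
        centers, np.full(len(centers), p.interface_sphere_radius), lat
    )


def interface_lattice(
    a: ChargedStructure,
    b: ChargedStructure,
    p: RegionParams | None = None,
    spacing: float = 0.5,
) -> Lattice:
    """Smallest lattice covering the interface region with a safety margin."""
    p = p or RegionParams()
    rids_a, rids_b = interface_residues(a, b, p)
    pts = [s.positions[s.residue_index[rid]]
           for s, rids in ((a, rids_a), (b, rids_b)) for rid in rids]
    if not pts:
        raise ValueError("no interfacial residues; cannot size a lattice")
    pts = np.concatenate(pts, axis=0)
    margin = p.interface_sphere_radius + 3.0 * spacing
    return Lattice.from_bounds(pts.min(axis=0) - margin,
                               pts.max(axis=0) + margin, spacing)


# -- cavity inputs ----------------------------------------------------------

def read_sphere_spec(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Sphere-union cavity spec: one ``x y z radius`` line per sphere
    (``#`` comments allowed)."""
    centers, radii = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 'x y z radius', got {line!r}"
                )
            centers.append([float(v) for v in tok[:3]])
            radii.append(float(tok[3]))
    return np.asarray(centers, dtype=float), np.asarray(radii, dtype=float)


def write_sphere_spec(centers: np.ndarray, radii: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# x y z radius (Å)\n")
        for c, r in zip(np.asarray(centers).reshape(-1, 3), np.ravel(radii)):
            fh.write(f"{c[0]:.4f} {c[1]:.4f} {c[2]:.4f} {r:.4f}\n")


def cavity_solid(spec, lat: Lattice) -> SolidRegion:
    """Binding-cavity solid from a sphere-union spec or a boundary mesh.

    ``spec`` may be a path to a sphere-spec text file, a path to an OFF/PLY
    mesh (resampled onto the lattice), or an ``(centers, radii)`` pair.
    """
    if isinstance(spec, (tuple, list)) and len(spec) == 2:
        centers, radii = spec
        centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        if len(centers) == 0:
            raise ValueError("empty cavity specification")
        return sphere_union_solid(centers, radii, lat)
    path = str(spec)
    if path.lower().endswith((".off", ".ply")):
        from .meshio import read_mesh

        mesh = read_mesh(path)
        occ = occupancy_from_mesh(mesh, lat)  # validates closedness
        return SolidRegion.from_occupancy(lat, occ)
    centers, radii = read_sphere_spec(path)
    if len(centers) == 0:
        raise ValueError(f"{path}: empty cavity specification")
    return sphere_union_solid(centers, radii, lat)
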