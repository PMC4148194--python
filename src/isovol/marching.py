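"""Marching-cubes extraction of solid isopotential boundaries.

The solid on one side of an isopotential is represented by the lattice
points inside it plus a closed, outward-oriented triangle mesh through the
crossing points on inside<->outside lattice edges (linear interpolation of
the field along each edge).

Per-cube triangle layouts come from a 256-case lookup table indexed by the
inside/outside pattern of the cube's corners.  The table is generated once
at import time by tracing the boundary chords of the inside region across
the six cube faces: on an ambiguous face (two diagonal inside corners) the
chords are paired by a fixed, face-local convention (the pairing that keeps
the inside corners connected).  Because the convention depends only on the
shared face, adjacent cubes always agree, so assembled surfaces are
watertight by construction — including every saddle configuration.

Solids clipped by the lattice boundary are capped: the signed field is
padded with an "outside" ghost layer a negligible distance (1e-9 of a
spacing) beyond the box, which closes the mesh with boundary faces while
perturbing the volume by a relatively negligible amount.
"""

from __future__ import annotations

import logging

import numpy as np

from .lattice import ScalarFieldGrid, ThresholdSpec

logger = logging.getLogger(__name__)

__all__ = ["TRI_TABLE", "extract_surface", "marching_cubes"]

# -- cube topology ----------------------------------------------------------
# Corner c has offset bits (x, y, z) = (c & 1, c >> 1 & 1, c >> 2 & 1).
CORNER_OFFSETS = np.array([[c & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)])

# 12 edges as corner pairs, grouped by axis.
EDGES: list[tuple[int, int]] = []
for _axis in range(3):
    for _c in range(8):
        if not (_c >> _axis) & 1:
            EDGES.append((_c, _c | (1 << _axis)))
_EDGE_INDEX = {frozenset(e): i for i, e in enumerate(EDGES)}

# For each edge: offset of its lower corner within the cube, and its axis.
EDGE_CORNER = np.array([CORNER_OFFSETS[a] for a, _ in EDGES])
EDGE_AXIS = np.array([i // 4 for i in range(12)])


def _face_cycles() -> list[list[int]]:
    """Corner cycles of the 6 faces, CCW as seen from outside the cube."""
    cycles = []
    for axis in range(3):
        b, c = [a for a in range(3) if a != axis]
        for side in (0, 1):
            cyc = []
            for bb, cc in ((0, 0), (1, 0), (1, 1), (0, 1)):
                cyc.append((side << axis) | (bb << b) | (cc << c))
            # orient so the right-hand normal points out of the cube
            p = CORNER_OFFSETS[cyc].astype(float)
            normal = np.cross(p[1] - p[0], p[2] - p[0])
            outward = np.zeros(3)
            outward[axis] = 1.0 if side == 1 else -1.0
            if np.dot(normal, outward) < 0:
                cyc = [cyc[0]] + cyc[1:][::-1]
            cycles.append(cyc)
    return cycles


_FACE_CYCLES = _face_cycles()

# Edge pairs that lie on a common cube face.  A triangle diagonal joining two
# such crossing points would sit on the face and could be duplicated by the
# neighbouring cube's triangulation, breaking watertightness; the loop
# triangulation below avoids them.
_COFACE = np.zeros((12, 12), dtype=bool)
for _cyc in _FACE_CYCLES:
    _face_edges = [
        _EDGE_INDEX[frozenset((_cyc[i], _cyc[(i + 1) % 4]))] for i in range(4)
    ]
    for _a in _face_edges:
        for _b in _face_edges:
            _COFACE[_a, _b] = True


def _triangulate_loop(raw_loop: list[int]) -> list[tuple[int, int, int]]:
    """Triangulate a boundary loop of crossing edges, avoiding interior
    diagonals that lie on a cube face (minimal-cost interval DP).

    The loop is canonicalised over rotation and reflection first, so the
    same geometric polygon always receives the same diagonals no matter
    which side of the surface a cube sees: the boundary pieces shared by
    complementary solids (e.g. A∩B and A-B) then cancel exactly in volume
    sums."""
    n = len(raw_loop)
    if n == 3:
        return [tuple(raw_loop)]
    rotations = {tuple(raw_loop[r:] + raw_loop[:r]) for r in range(n)}
    rev = raw_loop[::-1]
    candidates = rotations | {tuple(rev[r:] + rev[:r]) for r in range(n)}
    canonical = min(candidates)
    flipped = canonical not in rotations
    loop = list(canonical)

    def diag_cost(i: int, j: int) -> int:
        if (j - i) % n in (1, n - 1):
            return 0  # a loop edge, shared with the face chord
        return 1 if _COFACE[loop[i], loop[j]] else 0

    INF = 10**9
    cost = [[0] * n for _ in range(n)]
    split = [[-1] * n for _ in range(n)]
    for span in range(2, n):
        for i in range(0, n - span):
            j = i + span
            best, arg = INF, -1
            for k in range(i + 1, j):
                c = cost[i][k] + cost[k][j] + diag_cost(i, k) + diag_cost(k, j)
                if c < best:
                    best, arg = c, k
            cost[i][j], split[i][j] = best, arg
    tris: list[tuple[int, int, int]] = []

    def emit(i: int, j: int) -> None:
        if j - i < 2:
            return
        k = split[i][j]
        tris.append((loop[i], loop[k], loop[j]))
        emit(i, k)
        emit(k, j)

    emit(0, n - 1)
    if flipped:
        tris = [(a, c, b) for (a, b, c) in tris]
    return tris


def _trace_config(config: int) -> list[tuple[int, int, int]]:
    """Triangles (as edge-index triples) for one corner inside/outside pattern."""
    inside = [(config >> c) & 1 for c in range(8)]
    # Directed boundary chords per face: exit crossing -> next entry crossing,
    # walking the face perimeter CCW viewed from outside the cube.
    chords: dict[int, int] = {}
    for cyc in _FACE_CYCLES:
        events: list[tuple[str, int]] = []
        for i in range(4):
            a, b = cyc[i], cyc[(i + 1) % 4]
            if inside[a] == inside[b]:
                continue
            e = _EDGE_INDEX[frozenset((a, b))]
            events.append(("exit" if inside[a] else "enter", e))
        for i, (kind, e) in enumerate(events):
            if kind == "exit":
                nkind, ne = events[(i + 1) % len(events)]
                assert nkind == "enter"
                chords[e] = ne
    # Chain chords into closed loops around the cube surface.
    triangles: list[tuple[int, int, int]] = []
    while chords:
        start = next(iter(chords))
        loop = [start]
        cur = chords.pop(start)
        while cur != start:
            loop.append(cur)
            cur = chords.pop(cur)
        triangles.extend(_triangulate_loop(loop))
    return triangles


def _build_table() -> list[np.ndarray]:
    table = [np.asarray(_trace_config(cfg), dtype=np.int64).reshape(-1, 3)
             for cfg in range(256)]
    # Fix global orientation using the single-corner case: with only corner 0
    # inside, normals must point away from corner 0 (outward).
    tris = table[1]
    mids = 0.5 * (CORNER_OFFSETS[[a for a, _ in EDGES]]
                  + CORNER_OFFSETS[[b for _, b in EDGES]])
    v = mids[tris[0]]
    normal = np.cross(v[1] - v[0], v[2] - v[0])
    if np.dot(normal, v.mean(axis=0)) < 0:
        table = [t[:, ::-1].copy() for t in table]
    return table


#: 256-entry lookup: corner configuration -> (m, 3) array of edge indices.
TRI_TABLE = _build_table()


# -- extraction -------------------------------------------------------------

def extract_surface(
    axes: tuple[np.ndarray, np.ndarray, np.ndarray],
    signed: np.ndarray,
    cap_boundary: bool = True,
    leaves: tuple[str, list[np.ndarray]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the zero level set of a signed insideness field.

    Parameters
    ----------
    axes : three 1-D coordinate arrays (rectilinear; cubic in normal use)
    signed : array of shape ``(len(x), len(y), len(z))``; a point is inside
        the solid iff its value is >= 0.
    cap_boundary : close solids that reach the lattice boundary with faces
        essentially on the boundary plane (logs a warning when it happens).
    leaves : optional ``(op, [arrays])`` with op "min" or "max" and
        ``signed = op(arrays)`` pointwise.  When given, crossing positions on
        edges where several operands compete are solved exactly from the
        per-operand linear interpolants (the zero of a min/max of linear
        functions) instead of interpolating the combined field; edges owned
        by a single operand are unaffected.

    Returns
    -------
    (vertices, triangles) : float (V, 3) and int (T, 3) arrays.  Triangles
    are counter-clockwise seen from outside the solid.
    """
    signed = np.asarray(signed, dtype=float)
    if not np.all(np.isfinite(signed)):
        raise ValueError("signed field contains non-finite values")
    if signed.ndim != 3 or any(n < 2 for n in signed.shape):
        raise ValueError("field must be 3-D with at least 2 points per axis")
    x, y, z = (np.asarray(a, dtype=float) for a in axes)
    if (len(x), len(y), len(z)) != signed.shape:
        raise ValueError("axis lengths do not match field shape")

    occ = signed >= 0.0
    touches = (
        occ[0].any() or occ[-1].any()
        or occ[:, 0].any() or occ[:, -1].any()
        or occ[:, :, 0].any() or occ[:, :, -1].any()
    )
    if touches:
        if not cap_boundary:
            raise ValueError("solid reaches the lattice boundary")
        logger.warning(
            "solid reaches the lattice boundary; clipping and capping with "
            "boundary faces"
        )
        eps = 1e-9 * min(x[1] - x[0], y[1] - y[0], z[1] - z[0])
        x = np.concatenate(([x[0] - eps], x, [x[-1] + eps]))
        y = np.concatenate(([y[0] - eps], y, [y[-1] + eps]))
        z = np.concatenate(([z[0] - eps], z, [z[-1] + eps]))
        signed = np.pad(signed, 1, mode="constant", constant_values=-1.0)
        if leaves is not None:
            leaves = (
                leaves[0],
                [np.pad(l, 1, mode="constant", constant_values=-1.0)
                 for l in leaves[1]],
            )

    nx, ny, nz = signed.shape
    occ = (signed >= 0.0).astype(np.uint8)

    config = np.zeros((nx - 1, ny - 1, nz - 1), dtype=np.uint8)
    for c, (dx, dy, dz) in enumerate(CORNER_OFFSETS):
        config |= occ[dx:nx - 1 + dx, dy:ny - 1 + dy, dz:nz - 1 + dz] << np.uint8(c)

    mixed = np.nonzero((config != 0) & (config != 255))
    if mixed[0].size == 0:
        return np.zeros((0, 3), dtype=float), np.zeros((0, 3), dtype=np.int64)

    strides = np.array([ny * nz, nz, 1], dtype=np.int64)
    base = mixed[0] * strides[0] + mixed[1] * strides[1] + mixed[2] * strides[2]
    cfg_vals = config[mixed]

    # Global edge key: 3 * flat index of the edge's lower endpoint + axis.
    edge_point_off = EDGE_CORNER @ strides  # (12,)
    edge_key_off = 3 * edge_point_off + EDGE_AXIS  # (12,)

    key_chunks = []
    for cfg in np.unique(cfg_vals):
        tris = TRI_TABLE[cfg]  # (m, 3) local edge ids
        sel = base[cfg_vals == cfg]  # (n,)
        keys = 3 * sel[:, None, None] + edge_key_off[tris][None, :, :]
        key_chunks.append(keys.reshape(-1, 3))
    tri_keys = np.concatenate(key_chunks, axis=0)

    uniq, inverse = np.unique(tri_keys.ravel(), return_inverse=True)
    triangles = inverse.reshape(-1, 3).astype(np.int64)

    axis_id = uniq % 3
    p_flat = uniq // 3
    i1 = p_flat // (ny * nz)
    j1 = (p_flat // nz) % ny
    k1 = p_flat % nz
    ijk1 = np.stack([i1, j1, k1], axis=1)
    ijk2 = ijk1.copy()
    ijk2[np.arange(len(uniq)), axis_id] += 1

    s1 = signed[ijk1[:, 0], ijk1[:, 1], ijk1[:, 2]]
    s2 = signed[ijk2[:, 0], ijk2[:, 1], ijk2[:, 2]]
    if leaves is None:
        t = s1 / (s1 - s2)
    else:
        t = _exact_crossing(leaves, ijk1, ijk2, s1)
    t = np.clip(t, 0.0, 1.0)

    coords = (x, y, z)
    p1 = np.stack([coords[a][ijk1[:, a]] for a in range(3)], axis=1)
    p2 = np.stack([coords[a][ijk2[:, a]] for a in range(3)], axis=1)
    vertices = p1 + t[:, None] * (p2 - p1)
    return vertices, triangles


def _exact_crossing(leaves, ijk1, ijk2, s1) -> np.ndarray:
    """Crossing parameter of a min/max of linear interpolants along edges.

    Measured from the ijk1 endpoint.  For a min tree the solid exits where
    the first operand goes negative; for a max tree where the last positive
    operand does.
    """
    op, arrays = leaves
    inside1 = s1 >= 0.0
    la = np.stack(
        [arr[ijk1[:, 0], ijk1[:, 1], ijk1[:, 2]] for arr in arrays]
    )  # (m, E)
    lb = np.stack(
        [arr[ijk2[:, 0], ijk2[:, 1], ijk2[:, 2]] for arr in arrays]
    )
    # orient every edge inside -> outside
    A = np.where(inside1, la, lb)
    B = np.where(inside1, lb, la)
    denom = A - B
    safe = np.where(denom == 0.0, 1.0, denom)
    ti = A / safe
    if op == "min":
        # inside endpoint has all operands >= 0; the exit is the first
        # operand crossing (those negative at the outside endpoint)
        ti = np.where(B < 0.0, ti, np.inf)
        t_in = ti.min(axis=0)
    elif op == "max":
        # outside endpoint has all operands < 0; the exit is the last
        # crossing among operands positive at the inside endpoint
        ti = np.where(A >= 0.0, ti, -np.inf)
        t_in = ti.max(axis=0)
    else:  # pragma: no cover
        raise ValueError(f"unknown CSG leaf op {op!r}")
    # convert back to the ijk1 -> ijk2 parameterisation
    return np.where(inside1, t_in, 1.0 - t_in)


def marching_cubes(field: ScalarFieldGrid, spec: ThresholdSpec):
    """Extract the solid isopotential of ``field`` at threshold ``spec``.

    Returns a :class:`~isovol.solids.SolidRegion` whose occupancy equals
    :func:`~isovol.lattice.classify_points` and whose boundary vertices sit
    on inside<->outside lattice edges at the linearly interpolated crossing
    parameter t = (k - phi1) / (phi2 - phi1).
    """
    from .solids import SolidRegion  # cycle guard

    return SolidRegion(field.lattice, spec.signed(field.values))
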