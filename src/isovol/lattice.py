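"""Regular cubic lattices and scalar fields sampled on them.

Everything downstream — isopotential solids, cavity and interface regions,
CSG outputs — lives on a :class:`Lattice`: an axis-aligned cubic grid defined
by an origin, a single edge length (the *resolution*, in Å) and point counts
per axis.  Potentials are in kT/e at the electrostatic model's temperature;
distance fields are in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Lattice",
    "ScalarFieldGrid",
    "ThresholdSpec",
    "classify_points",
]

#: Two lattices are congruent when origin, spacing and dims agree to this (Å).
CONGRUENCE_TOL = 1e-9


@dataclass(frozen=True)
class Lattice:
    """A regular cubic lattice of points.

    Point (i, j, k) sits at ``origin + spacing * (i, j, k)``.  Cubes are
    indexed by their minimal-corner point; the voxel owned by a point is the
    half-open cube ``[p, p + spacing)^3``.

    Parameters
    ----------
    origin : (3,) array-like
        Position of point (0, 0, 0), in Å (PDB frame).
    spacing : float
        Lattice edge length in Å, > 0 — the working "resolution".
    dims : (3,) ints
        Number of lattice points per axis, each >= 2.
    """

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        origin = tuple(float(v) for v in np.asarray(self.origin, dtype=float))
        dims = tuple(int(v) for v in self.dims)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", float(self.spacing))
        if not np.all(np.isfinite(origin)):
            raise ValueError("lattice origin must be finite")
        if not (self.spacing > 0):
            raise ValueError(f"lattice spacing must be > 0, got {self.spacing}")
        if len(dims) != 3 or any(d < 2 for d in dims):
            raise ValueError(f"lattice dims must be three counts >= 2, got {dims}")

    # -- geometry -----------------------------------------------------------

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis coordinate arrays (x, y, z), each 1-D."""
        return tuple(
            self.origin[a] + self.spacing * np.arange(self.dims[a])
            for a in range(3)
        )

    def points(self) -> np.ndarray:
        """All lattice-point positions, shape ``dims + (3,)``."""
        x, y, z = self.axes()
        xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    def upper_corner(self) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * (np.asarray(self.dims) - 1)

    def congruent(self, other: "Lattice", tol: float = CONGRUENCE_TOL) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) <= tol
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def require_congruent(self, other: "Lattice", what: str = "operation") -> None:
        if not self.congruent(other):
            raise ValueError(
                f"{what} requires congruent lattices, got {self} vs {other}"
            )

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_bounds(
        cls,
        lower: np.ndarray,
        upper: np.ndarray,
        spacing: float = 0.5,
    ) -> "Lattice":
        """Smallest lattice at ``spacing`` covering the box [lower, upper]."""
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if np.any(upper < lower):
            raise ValueError("upper corner must dominate lower corner")
        dims = tuple(
            int(max(2, np.ceil((upper[a] - lower[a]) / spacing) + 1))
            for a in range(3)
        )
        return cls(origin=tuple(lower), spacing=spacing, dims=dims)


@dataclass
class ScalarFieldGrid:
    """A scalar field sampled at every lattice point.

    ``values`` has shape ``lattice.dims`` (C order; x is the slowest index,
    matching OpenDX data ordering when flattened).
    """

    lattice: Lattice
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.lattice.dims:
            raise ValueError(
                f"field shape {self.values.shape} != lattice dims {self.lattice.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must all be finite")

    def __add__(self, other: "ScalarFieldGrid") -> "ScalarFieldGrid":
        self.lattice.require_congruent(other.lattice, "field addition")
        return ScalarFieldGrid(self.lattice, self.values + other.values)

    def __sub__(self, other: "ScalarFieldGrid") -> "ScalarFieldGrid":
        self.lattice.require_congruent(other.lattice, "field subtraction")
        return ScalarFieldGrid(self.lattice, self.values - other.values)


@dataclass(frozen=True)
class ThresholdSpec:
    """An isopotential threshold k (kT/e) and the side the solid occupies.

    Following the convention for finite solids, a positive k selects the
    region with potential >= k ("above") and a negative k the region with
    potential <= k ("below") — the complementary regions are infinite in
    volume.  ``side=None`` applies that default; it may be overridden
    explicitly, e.g. for distance fields.
    """

    k: float
    side: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", float(self.k))
        if self.k == 0:
            raise ValueError(
                "k must be nonzero: the region on either side of 0 is "
                "unbounded and its volume undefined"
            )
        side = self.side
        if side is None:
            side = "above" if self.k > 0 else "below"
        if side not in ("above", "below"):
            raise ValueError(f"side must be 'above' or 'below', got {side!r}")
        object.__setattr__(self, "side", side)

    def signed(self, values: np.ndarray) -> np.ndarray:
        """Signed insideness: >= 0 exactly where a point is inside the solid."""
        if self.side == "above":
            return np.asarray(values, dtype=float) - self.k
        return self.k - np.asarray(values, dtype=float)


def classify_points(field: ScalarFieldGrid, spec: ThresholdSpec) -> np.ndarray:
    """Mark every lattice point inside (True) or outside the isopotential.

    A point is inside iff phi >= k (side="above") or phi <= k
    (side="below"); exact equality counts as inside, so solids are
    topologically closed.
    """
    return spec.signed(field.values) >= 0.0
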