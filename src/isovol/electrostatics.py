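"""Charged structures and electrostatic potential fields.

Structures carry per-atom coordinates, radii (Å) and partial charges (e),
grouped into residues identified by ``(chain, residue number, insertion
code)``.  PQR is the canonical charge source; plain PDB files are accepted
with an approximate formal-charge fallback.

Potential fields, in kT/e on a lattice, come from one of three models:

``debye_huckel``
    Screened-Coulomb superposition
    ``phi(p) = sum_i l_vac q_i exp(-kappa d_i) / (eps_solvent d_i)``
    with ``d_i = max(|p - x_i|, 0.5 spacing)`` (singularity clamp) and
    ``l_vac = e^2 / (4 pi eps0 kB T)`` in Å.  Exact for a uniform dielectric;
    fast and linear in the charges.

``fd_lpb``
    Finite-difference linearized Poisson-Boltzmann: a 7-point-stencil
    successive over-relaxation solve of
    ``div(eps grad phi) - eps_solvent kappa^2 phi = -4 pi l_vac rho``
    with a two-dielectric union-of-balls solute mask and Debye-Hückel
    Dirichlet boundary values.  The point-charge singularity is split off
    analytically (the grid solves only the smooth reaction/screening
    correction), so near-charge accuracy is not limited by grid charge
    spreading.  Captures electrostatic focusing by low-dielectric protein
    interiors.

``external_grid``
    A potential grid computed elsewhere (e.g. a nonlinear PB solver) and
    imported from an OpenDX file, exactly or by trilinear resampling.

Residue *nullification* zeroes one residue's charges while keeping its atoms
(and hence the dielectric mask) intact, so the structural, solvent-displacing
role of the residue is preserved while its electrostatic contribution is
removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import Lattice, ScalarFieldGrid

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ChargedStructure",
    "ElectrostaticModel",
    "ResidueID",
    "load_pqr",
    "load_pdb",
    "write_pqr",
    "assign_default_charges",
    "compute_field",
    "nullify_residue",
    "coulomb_length",
]

# CODATA: e^2/(4 pi eps0) in eV*Å and Boltzmann constant in eV/K.
_E2_OVER_4PIEPS0 = 14.399645478
_KB_EV = 8.617333262e-5


def coulomb_length(temperature: float = 298.15) -> float:
    """l_vac = e^2 / (4 pi eps0 kB T) in Å — the distance at which two unit
    charges in vacuum interact with thermal energy kT (560.47 Å at 298.15 K)."""
    return _E2_OVER_4PIEPS0 / (_KB_EV * temperature)


ResidueID = tuple[str, int, str]  # (chain, residue number, insertion code)


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    insertion_code: str
    position: tuple[float, float, float]
    radius: float
    charge: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"atom {self.serial}: radius must be >= 0")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position")

    @property
    def residue_id(self) -> ResidueID:
        return (self.chain, self.residue_number, self.insertion_code)


class ChargedStructure:
    """Atoms with coordinates, radii and partial charges, grouped by residue.

    Array attributes (``positions`` (N, 3), ``radii``, ``charges``) back all
    numerical work; :meth:`atoms` materialises :class:`AtomRecord` views.
    """

    def __init__(self, atoms: list[AtomRecord]):
        self._records = list(atoms)
        n = len(self._records)
        self.positions = np.array(
            [a.position for a in self._records], dtype=float
        ).reshape(n, 3)
        self.radii = np.array([a.radius for a in self._records], dtype=float)
        self.charges = np.array([a.charge for a in self._records], dtype=float)
        self.residue_index: dict[ResidueID, np.ndarray] = {}
        by_rid: dict[ResidueID, list[int]] = {}
        for i, a in enumerate(self._records):
            by_rid.setdefault(a.residue_id, []).append(i)
        for rid, idx in by_rid.items():
            self.residue_index[rid] = np.asarray(idx, dtype=int)

    # -- views --------------------------------------------------------------

    @property
    def atoms(self) -> list[AtomRecord]:
        return list(self._records)

    @property
    def n_atoms(self) -> int:
        return len(self._records)

    def residue_ids(self) -> list[ResidueID]:
        """Residue ids in deterministic (chain, number, insertion) order."""
        return sorted(self.residue_index)

    def residue_name(self, rid: ResidueID) -> str:
        return self._records[int(self.residue_index[rid][0])].residue_name

    def net_charge(self) -> float:
        return float(self.charges.sum())

    def bounds(self, margin: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        pad = self.radii.max() if self.n_atoms else 0.0
        lo = self.positions.min(axis=0) - pad - margin
        hi = self.positions.max(axis=0) + pad + margin
        return lo, hi

    def with_charges(self, charges: np.ndarray) -> "ChargedStructure":
        charges = np.asarray(charges, dtype=float)
        records = [
            replace(a, charge=float(q)) for a, q in zip(self._records, charges)
        ]
        return ChargedStructure(records)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ChargedStructure({self.n_atoms} atoms, "
            f"{len(self.residue_index)} residues, "
            f"net {self.net_charge():+.2f} e)"
        )


# -- PQR / PDB I/O ----------------------------------------------------------

def _split_resnum(tok: str) -> tuple[int, str]:
    """Residue-number token, possibly with a trailing insertion code."""
    i = len(tok)
    while i > 0 and not tok[i - 1].isdigit():
        i -= 1
    if i == 0:
        raise ValueError(f"bad residue number {tok!r}")
    return int(tok[:i]), tok[i:]


def load_pqr(path: str) -> ChargedStructure:
    """Parse a whitespace-separated PQR file (ATOM/HETATM records with
    trailing charge and radius columns; chain column optional)."""
    records: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tok = raw.split()
            if not tok or tok[0] not in ("ATOM", "HETATM"):
                continue
            try:
                if len(tok) >= 11:
                    (_, serial, name, resname, chain, resnum) = tok[:6]
                    rest = tok[6:11]
                elif len(tok) == 10:
                    (_, serial, name, resname, resnum) = tok[:5]
                    chain = ""
                    rest = tok[5:10]
                else:
                    raise ValueError("too few columns")
                x, y, z, charge, radius = (float(v) for v in rest)
                number, icode = _split_resnum(resnum)
                records.append(
                    AtomRecord(
                        serial=int(serial),
                        name=name,
                        residue_name=resname,
                        chain=chain,
                        residue_number=number,
                        insertion_code=icode,
                        position=(x, y, z),
                        radius=radius,
                        charge=charge,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: cannot parse PQR atom record "
                    f"(need coordinates, charge and radius columns): {exc}"
                ) from exc
    return ChargedStructure(records)


def write_pqr(s: ChargedStructure, path: str) -> None:
    with open(path, "w") as fh:
        for a in s.atoms:
            chain = a.chain if a.chain else ""
            resnum = f"{a.residue_number}{a.insertion_code}"
            fields = ["ATOM", f"{a.serial:>6d}", f"{a.name:<4s}",
                      f"{a.residue_name:<4s}"]
            if chain:
                fields.append(chain)
            fields += [
                f"{resnum:>5s}",
                f"{a.position[0]:>10.4f}", f"{a.position[1]:>10.4f}",
                f"{a.position[2]:>10.4f}",
                f"{a.charge:>8.4f}", f"{a.radius:>7.4f}",
            ]
            fh.write(" ".join(fields) + "\n")
        fh.write("END\n")


#: Bondi-style van der Waals radii by element (Å) for the PDB fallback path.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 1.40, "ZN": 1.39, "MG": 1.73, "CA": 1.74, "NA": 2.27, "K": 2.75,
}
_DEFAULT_VDW = 1.50

#: Formal side-chain charges placed on terminal atoms (e).
_FORMAL_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
}

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def load_pdb(path: str, assign_charges: bool = True) -> ChargedStructure:
    """Read a PDB file via Biopython; radii from the van der Waals table and
    (optionally) approximate formal charges on ionisable side chains."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pdb", path)
    records: list[AtomRecord] = []
    serial = 0
    for model in structure:
        for chain in model:
            for residue in chain:
                _, resnum, icode = residue.id
                for atom in residue:
                    serial += 1
                    element = (atom.element or "").strip().upper()
                    radius = VDW_RADII.get(element, _DEFAULT_VDW)
                    records.append(
                        AtomRecord(
                            serial=serial,
                            name=atom.get_name(),
                            residue_name=residue.get_resname().strip(),
                            chain=chain.id.strip(),
                            residue_number=int(resnum),
                            insertion_code=icode.strip(),
                            position=tuple(float(v) for v in atom.coord),
                            radius=radius,
                            charge=0.0,
                        )
                    )
        break  # first model only
    s = ChargedStructure(records)
    if assign_charges:
        s = assign_default_charges(s)
    return s


def assign_default_charges(
    s: ChargedStructure,
    n_termini: tuple[ResidueID, ...] = (),
    c_termini: tuple[ResidueID, ...] = (),
) -> ChargedStructure:
    """Place formal charges on ionisable side-chain terminal atoms.

    Asp -0.5 on OD1/OD2, Glu -0.5 on OE1/OE2, Lys +1 on NZ, Arg +0.5 on
    NH1/NH2, His neutral; flagged N/C termini get +1 on N / -1 on OXT (or O).
    This is an approximate fallback for structures without fitted partial
    charges; prefer PQR input.
    """
    logger.info(
        "assigning approximate formal charges (PQR input with fitted partial "
        "charges is preferred)"
    )
    charges = np.zeros(s.n_atoms)
    warned: set[str] = set()
    for i, a in enumerate(s.atoms):
        resname = a.residue_name.upper()
        if resname not in _STANDARD_RESIDUES:
            if resname not in warned:
                warned.add(resname)
                warnings.warn(
                    f"unknown residue {resname!r}: assigned zero charge",
                    stacklevel=2,
                )
            continue
        charges[i] = _FORMAL_CHARGES.get((resname, a.name.upper()), 0.0)
        if a.residue_id in n_termini and a.name.upper() == "N":
            charges[i] += 1.0
        if a.residue_id in c_termini and a.name.upper() in ("OXT", "O"):
            charges[i] += -1.0
    return s.with_charges(charges)


# -- electrostatic models ---------------------------------------------------

@dataclass(frozen=True)
class ElectrostaticModel:
    """Parameters of the potential-field model.

    kappa is the inverse Debye length in Å^-1 (0 = no ionic screening);
    eps_solute applies to the fd_lpb solute interior only.
    """

    model: str = "debye_huckel"  # debye_huckel | fd_lpb | external_grid
    eps_solvent: float = 80.0
    eps_solute: float = 4.0
    kappa: float = 0.0
    temperature: float = 298.15
    grid_path: str | None = None  # for external_grid
    sor_omega: float = 1.8
    sor_tol: float = 1e-5  # kT/e, max update per sweep
    sor_max_iter: int = 20000
    clamp_factor: float = 0.5  # singularity clamp, fraction of spacing

    def __post_init__(self) -> None:
        if self.model not in ("debye_huckel", "fd_lpb", "external_grid"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.eps_solvent <= 0 or self.eps_solute <= 0:
            raise ValueError("dielectric constants must be > 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def l_vac(self) -> float:
        return coulomb_length(self.temperature)


def _debye_huckel_phi(
    positions: np.ndarray,
    charges: np.ndarray,
    points: np.ndarray,
    m: ElectrostaticModel,
    clamp: float,
) -> np.ndarray:
    """Screened-Coulomb potential at arbitrary points, shape ``points.shape[:-1]``."""
    phi = np.zeros(points.shape[:-1])
    live = np.nonzero(charges)[0]
    for i in live:
        d = np.linalg.norm(points - positions[i], axis=-1)
        np.maximum(d, clamp, out=d)
        if m.kappa > 0:
            phi += m.l_vac * charges[i] * np.exp(-m.kappa * d) / (m.eps_solvent * d)
        else:
            phi += m.l_vac * charges[i] / (m.eps_solvent * d)
    return phi


def _solute_mask(s: ChargedStructure, lat: Lattice) -> np.ndarray:
    """Boolean union-of-balls mask of the solute interior on the lattice."""
    mask = np.zeros(lat.dims, dtype=bool)
    x, y, z = lat.axes()
    h = lat.spacing
    for pos, r in zip(s.positions, s.radii):
        if r <= 0:
            continue
        i0, i1 = np.searchsorted(x, [pos[0] - r - h, pos[0] + r + h])
        j0, j1 = np.searchsorted(y, [pos[1] - r - h, pos[1] + r + h])
        k0, k1 = np.searchsorted(z, [pos[2] - r - h, pos[2] + r + h])
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        dx = x[i0:i1] - pos[0]
        dy = y[j0:j1] - pos[1]
        dz = z[k0:k1] - pos[2]
        d2 = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        mask[i0:i1, j0:j1, k0:k1] |= d2 <= r * r
    return mask


def _fd_lpb_solve(
    s: ChargedStructure, lat: Lattice, m: ElectrostaticModel
) -> np.ndarray:
    """Regularised two-dielectric linearized PB solve.

    The potential is split as phi = phi_c + psi, where phi_c is the analytic
    Coulomb field of the charges in the (uniform) solute dielectric; the
    smooth correction psi — the reaction field of the dielectric boundary
    and the ionic screening — is solved by red-black SOR on the 7-point
    stencil.  The splitting removes the point-charge singularity from the
    grid, so accuracy near charges is set by the analytic part.  Charges are
    assumed to sit inside the solute mask (their own atom balls).
    """
    h = lat.spacing
    mask = _solute_mask(s, lat)
    eps = np.where(mask, m.eps_solute, m.eps_solvent)
    pts = lat.points()
    clamp = m.clamp_factor * h

    # analytic singular part: Coulomb in the solute dielectric (no screening)
    m_coul = replace(m, eps_solvent=m.eps_solute, kappa=0.0)
    phi_c = _debye_huckel_phi(s.positions, s.charges, pts, m_coul, clamp)

    # face dielectrics: harmonic means toward +axis neighbours
    def face(eps_a, eps_b):
        return 2.0 * eps_a * eps_b / (eps_a + eps_b)

    ex = face(eps[:-1], eps[1:])
    ey = face(eps[:, :-1], eps[:, 1:])
    ez = face(eps[:, :, :-1], eps[:, :, 1:])

    screen = np.where(mask, 0.0, m.eps_solvent * m.kappa**2 * h * h)

    interior = np.s_[1:-1, 1:-1, 1:-1]
    exm, exp_ = ex[:-1, 1:-1, 1:-1], ex[1:, 1:-1, 1:-1]
    eym, eyp = ey[1:-1, :-1, 1:-1], ey[1:-1, 1:, 1:-1]
    ezm, ezp = ez[1:-1, 1:-1, :-1], ez[1:-1, 1:-1, 1:]
    diag = exm + exp_ + eym + eyp + ezm + ezp + screen[interior]

    # source of the correction: dielectric-contrast flux of phi_c plus the
    # screening term, both vanishing identically near buried charges
    e_ref = m.eps_solute
    pc = phi_c
    contrast_flux = (
        (exm - e_ref) * (pc[:-2, 1:-1, 1:-1] - pc[interior])
        + (exp_ - e_ref) * (pc[2:, 1:-1, 1:-1] - pc[interior])
        + (eym - e_ref) * (pc[1:-1, :-2, 1:-1] - pc[interior])
        + (eyp - e_ref) * (pc[1:-1, 2:, 1:-1] - pc[interior])
        + (ezm - e_ref) * (pc[1:-1, 1:-1, :-2] - pc[interior])
        + (ezp - e_ref) * (pc[1:-1, 1:-1, 2:] - pc[interior])
    )
    src = contrast_flux - screen[interior] * pc[interior]

    # Dirichlet boundary: psi = (screened closed form) - phi_c
    psi = np.zeros(lat.dims)
    for face_slice in (
        np.s_[0, :, :], np.s_[-1, :, :],
        np.s_[:, 0, :], np.s_[:, -1, :],
        np.s_[:, :, 0], np.s_[:, :, -1],
    ):
        psi[face_slice] = (
            _debye_huckel_phi(s.positions, s.charges, pts[face_slice], m, clamp)
            - phi_c[face_slice]
        )

    nx, ny, nz = lat.dims
    ii, jj, kk = np.meshgrid(
        np.arange(1, nx - 1), np.arange(1, ny - 1), np.arange(1, nz - 1),
        indexing="ij",
    )
    parity = (ii + jj + kk) % 2
    omega = m.sor_omega
    max_delta = np.inf
    for _iteration in range(m.sor_max_iter):
        max_delta = 0.0
        for color in (0, 1):
            nb = (
                exm * psi[:-2, 1:-1, 1:-1] + exp_ * psi[2:, 1:-1, 1:-1]
                + eym * psi[1:-1, :-2, 1:-1] + eyp * psi[1:-1, 2:, 1:-1]
                + ezm * psi[1:-1, 1:-1, :-2] + ezp * psi[1:-1, 1:-1, 2:]
            )
            new = (nb + src) / diag
            cur = psi[interior]
            delta = np.where(parity == color, new - cur, 0.0)
            psi[interior] = cur + omega * delta
            max_delta = max(max_delta, float(np.abs(delta).max()))
        if max_delta < m.sor_tol:
            break
    else:
        raise RuntimeError(
            f"fd_lpb SOR did not converge in {m.sor_max_iter} iterations; "
            f"max residual {max_delta:.3e} kT/e"
        )
    return phi_c + psi


def compute_field(
    s: ChargedStructure, lat: Lattice, m: ElectrostaticModel
) -> ScalarFieldGrid:
    """Electrostatic potential of ``s`` on lattice ``lat``, in kT/e."""
    if m.model == "external_grid":
        from .dx import read_dx

        if m.grid_path is None:
            raise ValueError("external_grid model needs grid_path")
        grid = read_dx(m.grid_path)
        return _resample_field(grid, lat)
    if s.n_atoms == 0:
        raise ValueError("cannot compute a field for an empty structure")
    if m.model == "debye_huckel":
        clamp = m.clamp_factor * lat.spacing
        phi = _debye_huckel_phi(s.positions, s.charges, lat.points(), m, clamp)
        return ScalarFieldGrid(lat, phi)
    return ScalarFieldGrid(lat, _fd_lpb_solve(s, lat, m))


def _resample_field(grid: ScalarFieldGrid, lat: Lattice) -> ScalarFieldGrid:
    if grid.lattice.congruent(lat):
        return ScalarFieldGrid(lat, grid.values.copy())
    from scipy.ndimage import map_coordinates

    pts = lat.points()
    src = grid.lattice
    idx = (pts - np.asarray(src.origin)) / src.spacing
    lo = idx.min()
    hi = (idx - (np.asarray(src.dims) - 1)).max()
    if lo < -1e-9 or hi > 1e-9:
        raise ValueError(
            "target lattice extends outside the imported grid; "
            "trilinear resampling cannot extrapolate"
        )
    coords = np.stack([idx[..., a].ravel() for a in range(3)])
    vals = map_coordinates(grid.values, coords, order=1, mode="nearest")
    return ScalarFieldGrid(lat, vals.reshape(lat.dims))


def nullify_residue(s: ChargedStructure, rid: ResidueID) -> ChargedStructure:
    """Zero all charges of one residue, keeping atoms (and dielectric) intact."""
    if rid not in s.residue_index:
        raise KeyError(
            f"unknown residue id {rid!r}; valid ids: {s.residue_ids()}"
        )
    charges = s.charges.copy()
    charges[s.residue_index[rid]] = 0.0
    return s.with_charges(charges)
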