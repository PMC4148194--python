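"""Per-residue charge-nullification scans.

Cavity scans ask which residues of a *test* protein create the electrostatic
differences between its binding cavity and a *reference* cavity: every
residue is nullified in turn, the test cavity field is rebuilt, and

    v_r = V( (E_test,r ∩ I) - (E_ref ∩ I) )

is compared against the unmodified baseline v0.  The prediction threshold is
T = (v0 + min_r v_r) / 2 — a residue is predicted influential when nullifying
it reduces the electrostatic difference by at least half of the best
reduction any single residue achieves.

Interface scans nullify each residue of one side of a complex and measure
D_r = ΔEC against the wild-type complex.  The upper and lower prediction
thresholds are half the extreme responses, T_u = max_r D_r / 2 and
T_l = min_r D_r / 2; a threshold is only applied when fewer than 10% of the
scanned residues cross it (many crossings mean there is no outlier to call).

Predicted residues that belong to an intramolecular salt bridge are
additionally flagged: mutating them would likely destabilise the cavity or
interface rather than merely reshape its field.

Scans do not rank predicted residues against each other: the magnitude of
v_r or D_r for two predicted residues carries no information about their
relative influence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .electrostatics import (
    ChargedStructure,
    ElectrostaticModel,
    ResidueID,
    compute_field,
    nullify_residue,
)
from .interfaces import (
    INTERFACE_K_SWEEP,
    interface_field_from_potentials,
    _lone_field,
)
from .lattice import Lattice, ScalarFieldGrid, ThresholdSpec
from .marching import marching_cubes
from .regions import RegionParams, interface_lattice, interface_region
from .solids import SolidRegion, complement, intersection

logger = logging.getLogger(__name__)

__all__ = [
    "SaltBridge",
    "ScanRecord",
    "ScanResult",
    "salt_bridges",
    "scan_cavity",
    "scan_cavity_multi_k",
    "scan_interface",
    "scan_interface_multi_k",
    "cavity_prediction_threshold",
    "interface_prediction_thresholds",
    "CAVITY_K_SWEEP",
]

#: Default threshold sweep for cavity calibration (kT/e).
CAVITY_K_SWEEP = (-2.5, -5.0, -7.5, -10.0)

# -- salt bridges -----------------------------------------------------------

_BASIC_N = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
_ACIDIC_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass(frozen=True)
class SaltBridge:
    basic: ResidueID
    acidic: ResidueID
    distance: float
    same_chain: bool


def salt_bridges(s: ChargedStructure, cutoff: float = 4.0) -> list[SaltBridge]:
    """Distance-rule salt-bridge screen: a basic side-chain nitrogen
    (Arg NH1/NH2/NE, Lys NZ, His ND1/NE2) within ``cutoff`` Å of an acidic
    side-chain oxygen (Asp OD1/OD2, Glu OE1/OE2)."""
    basic_idx, acidic_idx = [], []
    for i, a in enumerate(s.atoms):
        resname = a.residue_name.upper()
        name = a.name.upper()
        if name in _BASIC_N.get(resname, ()):
            basic_idx.append(i)
        elif name in _ACIDIC_O.get(resname, ()):
            acidic_idx.append(i)
    if not basic_idx or not acidic_idx:
        return []
    atoms = s.atoms
    tree = cKDTree(s.positions[acidic_idx])
    bridges: dict[tuple[ResidueID, ResidueID], SaltBridge] = {}
    for bi in basic_idx:
        for local in tree.query_ball_point(s.positions[bi], cutoff):
            ai = acidic_idx[local]
            d = float(np.linalg.norm(s.positions[bi] - s.positions[ai]))
            key = (atoms[bi].residue_id, atoms[ai].residue_id)
            if key not in bridges or d < bridges[key].distance:
                bridges[key] = SaltBridge(
                    basic=key[0],
                    acidic=key[1],
                    distance=d,
                    same_chain=key[0][0] == key[1][0],
                )
    return sorted(bridges.values(), key=lambda b: (b.basic, b.acidic))


def _bridged_residues(bridges: list[SaltBridge]) -> set[ResidueID]:
    out: set[ResidueID] = set()
    for b in bridges:
        out.add(b.basic)
        out.add(b.acidic)
    return out


# -- thresholds (reconstructed from the verbal definitions) -----------------

def cavity_prediction_threshold(v0: float, v_min: float) -> float:
    """T = (v0 + min_r v_r) / 2: differences reduced by half of the best
    single-residue reduction."""
    return 0.5 * (v0 + v_min)


def interface_prediction_thresholds(d_values) -> tuple[float, float]:
    """(T_u, T_l) = (max_r D_r / 2, min_r D_r / 2)."""
    d = np.asarray(list(d_values), dtype=float)
    return float(d.max() / 2.0), float(d.min() / 2.0)


# -- results ----------------------------------------------------------------

@dataclass
class ScanRecord:
    """One residue's nullification response.

    ``statistic`` is v_r (ų, cavity scans) or D_r = ΔEC (ų, interface
    scans).  ``label`` is the primary prediction; ``salt_bridge_stability``
    marks predicted residues that are also salt-bridge members.
    """

    residue_id: ResidueID
    statistic: float
    salt_bridge: bool
    label: str = "none"
    salt_bridge_stability: bool = False


@dataclass
class ScanResult:
    kind: str  # "cavity" | "interface"
    k_used: float
    baseline: float  # v0 (cavity) or EC_ref (interface)
    records: list[ScanRecord]
    T: float | None = None       # cavity threshold
    T_u: float | None = None     # interface upper threshold
    T_l: float | None = None     # interface lower threshold
    thresholds_applied: dict = field(default_factory=dict)
    notes: tuple[str, ...] = (
        "difference direction: (nullified test field) - (reference field)",
        "threshold formulas reconstructed from the half-reduction rule",
    )

    def predictions(self) -> list[ResidueID]:
        return [r.residue_id for r in self.records if r.label != "none"]

    def record(self, rid: ResidueID) -> ScanRecord:
        for r in self.records:
            if r.residue_id == rid:
                return r
        raise KeyError(rid)


# -- cavity scan ------------------------------------------------------------

def _variant_fields(
    test: ChargedStructure,
    lat: Lattice,
    model: ElectrostaticModel,
    residues: list[ResidueID],
):
    """Baseline and per-residue nullified potential grids of the test protein."""
    base = compute_field(test, lat, model).values
    variants = {}
    for rid in residues:
        variants[rid] = compute_field(nullify_residue(test, rid), lat, model).values
    return base, variants


def scan_cavity(
    test: ChargedStructure,
    ref_field: ScalarFieldGrid,
    C_test: SolidRegion,
    C_ref: SolidRegion,
    k: ThresholdSpec,
    model: ElectrostaticModel,
    salt_bridge_cutoff: float = 4.0,
    symmetric_difference: bool = False,
) -> ScanResult:
    """Nullify every residue of ``test`` in turn and measure how much the
    electrostatic difference from the reference cavity field shrinks.

    ``ref_field`` is the reference protein's potential on the working
    lattice (pre-aligned coordinates); ``C_test``/``C_ref`` the two cavity
    solids.  ``symmetric_difference=True`` adds V(e_ref - e_test,r) to the
    statistic instead of using the one-sided difference.
    """
    lat = ref_field.lattice
    for s_ in (C_test, C_ref):
        lat.require_congruent(s_.lattice, "cavity scan")
    residues = test.residue_ids()
    base, variants = _variant_fields(test, lat, model, residues)
    return _scan_cavity_at_k(
        test, ref_field, C_test, C_ref, k, lat, base, variants,
        salt_bridge_cutoff, symmetric_difference,
    )


def _scan_cavity_at_k(
    test, ref_field, C_test, C_ref, k, lat, base, variants,
    salt_bridge_cutoff, symmetric_difference,
) -> ScanResult:
    I = intersection(C_test, C_ref)
    if I.is_empty():
        raise ValueError("cavities do not overlap: I = C_test ∩ C_ref is empty")
    E_ref = marching_cubes(ref_field, k)
    e_ref = intersection(E_ref, I)

    def stat(values: np.ndarray) -> float:
        # (E ∩ I) - (E_ref ∩ I) flattens to E ∩ I ∩ ¬E_ref, keeping operand
        # boundary crossings exact
        E = SolidRegion(lat, k.signed(values))
        e = intersection(E, I)
        v = intersection(e, complement(E_ref)).volume()
        if symmetric_difference:
            v += intersection(e_ref, complement(E)).volume()
        return v

    v0 = stat(base)
    v_r = {rid: stat(vals) for rid, vals in variants.items()}

    bridged = _bridged_residues(salt_bridges(test, salt_bridge_cutoff))
    records = [
        ScanRecord(rid, v_r[rid], rid in bridged) for rid in sorted(v_r)
    ]
    if v0 == 0.0:
        logger.warning(
            "baseline cavity-field difference is zero; nothing to reduce, "
            "no predictions"
        )
        return ScanResult("cavity", k.k, v0, records, T=None,
                          thresholds_applied={"cavity": False})
    T = cavity_prediction_threshold(v0, min(v_r.values()))
    for rec in records:
        if rec.statistic <= T:
            rec.label = "influential_difference"
            if rec.salt_bridge:
                rec.salt_bridge_stability = True
    return ScanResult("cavity", k.k, v0, records, T=T,
                      thresholds_applied={"cavity": True})


def scan_cavity_multi_k(
    test: ChargedStructure,
    ref_field: ScalarFieldGrid,
    C_test: SolidRegion,
    C_ref: SolidRegion,
    model: ElectrostaticModel,
    ks=CAVITY_K_SWEEP,
    salt_bridge_cutoff: float = 4.0,
) -> tuple[ScanResult, dict[float, float]]:
    """Run the cavity scan over a threshold sweep and keep the level where
    the per-residue responses spread the most (max_r v_r - min_r v_r):
    the most discriminating calibration.

    Potential grids are threshold-independent, so fields are computed once
    and re-thresholded.  Returns (result at selected k, spread per k).
    """
    lat = ref_field.lattice
    residues = test.residue_ids()
    base, variants = _variant_fields(test, lat, model, residues)
    spreads: dict[float, float] = {}
    results: dict[float, ScanResult] = {}
    for kval in ks:
        spec = ThresholdSpec(kval)
        res = _scan_cavity_at_k(
            test, ref_field, C_test, C_ref, spec, lat, base, variants,
            salt_bridge_cutoff, False,
        )
        stats = [r.statistic for r in res.records]
        spreads[kval] = max(stats) - min(stats) if stats else 0.0
        results[kval] = res
    best = max(spreads, key=lambda kv: spreads[kv])
    return results[best], spreads


# -- interface scan ---------------------------------------------------------

def scan_interface(
    a: ChargedStructure,
    b: ChargedStructure,
    side: str,
    k: float,
    model: ElectrostaticModel,
    params: RegionParams | None = None,
    region: SolidRegion | None = None,
    salt_bridge_cutoff: float = 4.0,
    outlier_fraction: float = 0.1,
) -> ScanResult:
    """Nullify every residue on one side ('A' or 'B') of a complex and
    measure D_r = ΔEC at threshold k > 0."""
    result, _ = _interface_scan_core(
        a, b, side, [float(k)], model, params, region,
        salt_bridge_cutoff, outlier_fraction, selected_k=float(k),
    )
    return result


def scan_interface_multi_k(
    a: ChargedStructure,
    b: ChargedStructure,
    side: str,
    model: ElectrostaticModel,
    ks=INTERFACE_K_SWEEP,
    params: RegionParams | None = None,
    region: SolidRegion | None = None,
    salt_bridge_cutoff: float = 4.0,
    outlier_fraction: float = 0.1,
    calibrated_k: float | None = None,
) -> tuple[ScanResult, dict[float, float]]:
    """Interface scan over a threshold sweep, keeping the k where the D_r
    spread is largest.  ``calibrated_k`` short-circuits the sweep — a side
    interacting with an already-calibrated partner reuses that threshold."""
    if calibrated_k is not None:
        res = scan_interface(
            a, b, side, calibrated_k, model, params, region,
            salt_bridge_cutoff, outlier_fraction,
        )
        return res, {calibrated_k: float("nan")}
    return _interface_scan_core(
        a, b, side, [float(kv) for kv in ks], model, params, region,
        salt_bridge_cutoff, outlier_fraction, selected_k=None,
    )


def _interface_scan_core(
    a, b, side, ks, model, params, region, salt_bridge_cutoff,
    outlier_fraction, selected_k,
):
    if side not in ("A", "B"):
        raise ValueError("side must be 'A' or 'B'")
    params = params or RegionParams()
    if region is None:
        lat = interface_lattice(a, b, params, spacing=0.5)
        region = interface_region(a, b, lat, params)
    lat = region.lattice
    if region.is_empty():
        raise ValueError("interface region is empty; no complementarity to scan")

    phi_a = _lone_field(a, b, lat, model, True)
    phi_b = _lone_field(b, a, lat, model, True)
    scanned = a if side == "A" else b
    residues = scanned.residue_ids()

    # variant lone potentials of the scanned side (the partner's lone field
    # is unchanged by nullification: atoms, hence dielectric, are identical)
    variant_phi = {}
    for rid in residues:
        nulled = nullify_residue(scanned, rid)
        if side == "A":
            variant_phi[rid] = _lone_field(nulled, b, lat, model, True)
        else:
            variant_phi[rid] = _lone_field(nulled, a, lat, model, True)

    def ec(pa: np.ndarray, pb: np.ndarray, kval: float) -> float:
        pos = interface_field_from_potentials(pa, pb, region, +kval)
        neg = interface_field_from_potentials(pa, pb, region, -kval)
        return pos.volume() + neg.volume()

    bridged = _bridged_residues(salt_bridges(scanned, salt_bridge_cutoff))
    results: dict[float, ScanResult] = {}
    spreads: dict[float, float] = {}
    for kval in ks:
        ec_ref = ec(phi_a, phi_b, kval)
        if ec_ref == 0.0:
            if selected_k is not None:
                raise ValueError(
                    f"no electrostatic complementarity at k = {kval} kT/e"
                )
            spreads[kval] = -np.inf
            continue
        d_r: dict[ResidueID, float] = {}
        for rid in residues:
            if side == "A":
                ec_var = ec(variant_phi[rid], phi_b, kval)
            else:
                ec_var = ec(phi_a, variant_phi[rid], kval)
            d_r[rid] = ec_var - ec_ref
        results[kval] = _label_interface(
            kval, ec_ref, d_r, bridged, outlier_fraction
        )
        stats = list(d_r.values())
        spreads[kval] = max(stats) - min(stats)
    if not results:
        raise ValueError("no electrostatic complementarity at any scanned k")
    if selected_k is None:
        selected_k = max(spreads, key=lambda kv: spreads[kv])
    return results[selected_k], spreads


def _label_interface(
    kval: float,
    ec_ref: float,
    d_r: dict[ResidueID, float],
    bridged: set[ResidueID],
    outlier_fraction: float,
) -> ScanResult:
    T_u, T_l = interface_prediction_thresholds(d_r.values())
    n = len(d_r)
    upper_crossers = [rid for rid, d in d_r.items() if d >= T_u and d > 0]
    lower_crossers = [rid for rid, d in d_r.items() if d <= T_l and d < 0]
    apply_upper = len(upper_crossers) < outlier_fraction * n
    apply_lower = len(lower_crossers) < outlier_fraction * n
    if not apply_upper and upper_crossers:
        logger.info(
            "upper threshold suppressed: %d/%d residues cross it",
            len(upper_crossers), n,
        )
    if not apply_lower and lower_crossers:
        logger.info(
            "lower threshold suppressed: %d/%d residues cross it",
            len(lower_crossers), n,
        )
    records = []
    for rid in sorted(d_r):
        rec = ScanRecord(rid, d_r[rid], rid in bridged)
        if apply_upper and rid in upper_crossers:
            rec.label = "hinders_complementarity"
        elif apply_lower and rid in lower_crossers:
            rec.label = "contributes_complementarity"
        if rec.label != "none" and rec.salt_bridge:
            rec.salt_bridge_stability = True
        records.append(rec)
    return ScanResult(
        "interface", kval, ec_ref, records,
        T_u=T_u, T_l=T_l,
        thresholds_applied={"upper": apply_upper, "lower": apply_lower},
    )
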