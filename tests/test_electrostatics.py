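"""Charged structures, PQR/PDB/DX I/O, potential models, nullification."""

import numpy as np
import pytest

from isovol import (
    ElectrostaticModel,
    ScalarFieldGrid,
    assign_default_charges,
    compute_field,
    load_pqr,
    nullify_residue,
    read_dx,
    write_dx,
)
from isovol.electrostatics import (
    ChargedStructure,
    _solute_mask,
    coulomb_length,
    write_pqr,
)

from conftest import make_lattice, single_atom, structure_of

EPS = 80.0
L_VAC = coulomb_length()


class TestPQR:
    def test_single_atom_line(self, tmp_path):
        p = tmp_path / "one.pqr"
        p.write_text("ATOM 1 NZ LYS A 12 1.0 2.0 3.0 1.0000 1.5000\n")
        s = load_pqr(str(p))
        assert s.n_atoms == 1
        assert list(s.residue_index) == [("A", 12, "")]
        a = s.atoms[0]
        assert a.charge == 1.0 and a.radius == 1.5
        np.testing.assert_allclose(a.position, [1.0, 2.0, 3.0])

    def test_two_chains_distinct_residue_ids(self, tmp_path):
        p = tmp_path / "two.pqr"
        p.write_text(
            "ATOM 1 CA GLY A 1 0 0 0 0.0 1.7\n"
            "ATOM 2 CA GLY B 1 5 0 0 0.0 1.7\n"
        )
        s = load_pqr(str(p))
        assert set(s.residue_index) == {("A", 1, ""), ("B", 1, "")}

    def test_chainless_pqr_accepted(self, tmp_path):
        p = tmp_path / "nochain.pqr"
        p.write_text("ATOM 1 CA GLY 7 0 0 0 -0.3 1.7\n")
        s = load_pqr(str(p))
        assert s.atoms[0].chain == ""
        assert s.atoms[0].residue_number == 7

    def test_net_charge_is_column_sum(self, tmp_path):
        charges = [0.25, -0.5, 1.0, -0.1, 0.35]
        lines = [
            f"ATOM {i + 1} X UNK A {i + 1} {i}.0 0 0 {q} 1.5"
            for i, q in enumerate(charges)
        ]
        p = tmp_path / "five.pqr"
        p.write_text("\n".join(lines) + "\n")
        assert load_pqr(str(p)).net_charge() == pytest.approx(sum(charges))

    def test_missing_columns_reported_with_line_number(self, tmp_path):
        p = tmp_path / "bad.pqr"
        p.write_text("ATOM 1 CA GLY A 1 0 0 0\n")
        with pytest.raises(ValueError, match="bad.pqr:1"):
            load_pqr(str(p))

    def test_write_read_round_trip(self, tmp_path):
        s = structure_of(
            single_atom(+1.0, 1.8, (1.25, -2.5, 0.125), resnum=3, name="NZ",
                        resname="LYS"),
            single_atom(-0.5, 1.5, (4.0, 0.0, 1.0), resnum=4, name="OE1",
                        resname="GLU"),
        )
        path = str(tmp_path / "rt.pqr")
        write_pqr(s, path)
        back = load_pqr(path)
        assert back.n_atoms == s.n_atoms
        np.testing.assert_allclose(back.positions, s.positions)
        np.testing.assert_allclose(back.charges, s.charges)
        np.testing.assert_allclose(back.radii, s.radii)
        assert back.residue_ids() == s.residue_ids()


class TestDefaultCharges:
    def _residue(self, resname, atom_names, resnum=1):
        return [
            single_atom(0.0, 1.5, (i * 1.5, 0, 0), resnum=resnum, name=n,
                        resname=resname)
            for i, n in enumerate(atom_names)
        ]

    def test_lone_asp_nets_minus_one(self):
        s = structure_of(*self._residue("ASP", ["CB", "CG", "OD1", "OD2"]))
        assert assign_default_charges(s).net_charge() == pytest.approx(-1.0)

    def test_gly_chain_is_neutral(self):
        atoms = []
        for i in range(3):
            atoms += self._residue("GLY", ["N", "CA", "C", "O"], resnum=i + 1)
        s = structure_of(*atoms)
        assert assign_default_charges(s).net_charge() == 0.0

    def test_lys_glu_pair_neutral_with_nonzero_field(self):
        atoms = self._residue("LYS", ["NZ"], resnum=1) + [
            single_atom(0.0, 1.5, (4.0, 0, 0), resnum=2, name="OE1",
                        resname="GLU"),
            single_atom(0.0, 1.5, (5.5, 0, 0), resnum=2, name="OE2",
                        resname="GLU"),
        ]
        s = assign_default_charges(structure_of(*atoms))
        assert s.net_charge() == pytest.approx(0.0)
        lat = make_lattice(10.0, 1.0)
        field = compute_field(s, lat, ElectrostaticModel())
        assert np.abs(field.values).max() > 0.01  # dipole field present

    def test_unknown_residue_warns_and_zeroes(self):
        s = structure_of(single_atom(0.0, 1.5, (0, 0, 0), resname="XYZ"))
        with pytest.warns(UserWarning, match="XYZ"):
            out = assign_default_charges(s)
        assert out.net_charge() == 0.0


class TestDebyeHuckelField:
    def test_zero_charges_give_zero_field(self, lat8):
        s = structure_of(single_atom(0.0))
        field = compute_field(s, lat8, ElectrostaticModel())
        assert np.all(field.values == 0.0)

    def test_single_charge_matches_coulomb_closed_form(self):
        """phi = l_vac q / (eps d): 1.000 kT/e at d = l_vac/80 for q = +1."""
        s = structure_of(single_atom(+1.0, position=(0.1, 0.0, 0.0)))
        lat = make_lattice(10.0, 0.5, center=(0.1, 0.0, 0.0))
        field = compute_field(s, lat, ElectrostaticModel())
        pts = lat.points()
        d = np.linalg.norm(pts - np.array([0.1, 0.0, 0.0]), axis=-1)
        off = d > 0.5  # beyond the singularity clamp
        expected = L_VAC / (EPS * d[off])
        np.testing.assert_allclose(field.values[off], expected, atol=1e-6)
        # spot value: the distance where the potential is exactly 1 kT/e
        assert L_VAC / EPS == pytest.approx(7.006, abs=5e-3)

    def test_superposition(self, lat8):
        a = structure_of(single_atom(+1.0, position=(2.0, 0, 0)))
        b = structure_of(single_atom(-1.0, position=(-2.0, 0, 0), resnum=2))
        both = structure_of(
            single_atom(+1.0, position=(2.0, 0, 0)),
            single_atom(-1.0, position=(-2.0, 0, 0), resnum=2),
        )
        m = ElectrostaticModel(kappa=0.05)
        fa = compute_field(a, lat8, m).values
        fb = compute_field(b, lat8, m).values
        fab = compute_field(both, lat8, m).values
        np.testing.assert_allclose(fab, fa + fb, rtol=1e-12)

    def test_screening_reduces_long_range_potential(self, lat8):
        s = structure_of(single_atom(+1.0))
        bare = compute_field(s, lat8, ElectrostaticModel()).values
        screened = compute_field(s, lat8, ElectrostaticModel(kappa=0.2)).values
        assert np.all(screened <= bare + 1e-12)


class TestNullification:
    def _three_residue(self):
        return structure_of(
            single_atom(+1.0, position=(0, 0, 0), resnum=1),
            single_atom(-1.0, position=(3, 0, 0), resnum=2),
            single_atom(0.0, position=(0, 3, 0), resnum=3),
        )

    def test_charges_zeroed_atoms_kept(self):
        s = self._three_residue()
        out = nullify_residue(s, ("A", 1, ""))
        assert out.n_atoms == s.n_atoms
        assert out.charges[0] == 0.0
        np.testing.assert_allclose(out.positions, s.positions)
        np.testing.assert_allclose(out.radii, s.radii)

    def test_unknown_residue_lists_valid_ids(self):
        with pytest.raises(KeyError, match="valid ids"):
            nullify_residue(self._three_residue(), ("A", 99, ""))

    def test_nullifying_neutral_residue_keeps_field_bit_identical(self, lat8):
        s = self._three_residue()
        m = ElectrostaticModel()
        f0 = compute_field(s, lat8, m).values
        f1 = compute_field(nullify_residue(s, ("A", 3, "")), lat8, m).values
        np.testing.assert_array_equal(f0, f1)

    def test_nullification_equals_superposition_of_removed_charges(self, lat8):
        s = self._three_residue()
        m = ElectrostaticModel()
        full = compute_field(s, lat8, m).values
        nulled = compute_field(nullify_residue(s, ("A", 2, "")), lat8, m).values
        alone = compute_field(
            structure_of(single_atom(-1.0, position=(3, 0, 0), resnum=2)),
            lat8, m,
        ).values
        np.testing.assert_allclose(full - nulled, alone, atol=1e-9)

    def test_dielectric_mask_untouched_under_fd_lpb(self, lat8):
        s = self._three_residue()
        nulled = nullify_residue(s, ("A", 1, ""))
        np.testing.assert_array_equal(
            _solute_mask(s, lat8), _solute_mask(nulled, lat8)
        )


class TestFiniteDifferenceLPB:
    def test_uniform_dielectric_matches_coulomb(self):
        """eps_solute = eps_solvent, kappa = 0: within 5% of the Coulomb
        closed form beyond two lattice cells."""
        s = structure_of(single_atom(+1.0, 0.0, (0.05, 0.02, -0.03)))
        lat = make_lattice(10.0, 0.5)
        m = ElectrostaticModel(model="fd_lpb", eps_solute=EPS, kappa=0.0)
        phi = compute_field(s, lat, m).values
        d = np.linalg.norm(lat.points() - np.array([0.05, 0.02, -0.03]), axis=-1)
        far = d >= 2 * lat.spacing
        exact = L_VAC / (EPS * d[far])
        assert np.max(np.abs(phi[far] - exact) / exact) < 0.05

    def test_born_ion_matches_debye_huckel_closed_form(self):
        """Outside a charged sphere (radius a) in salt, the linearized-PB
        potential is l_vac e^{-kappa (r-a)} / (eps r (1 + kappa a)); the grid
        solve must be within 8%."""
        a_radius, kappa = 2.0, 0.15
        s = structure_of(single_atom(+1.0, a_radius))
        lat = make_lattice(10.0, 0.5)
        m = ElectrostaticModel(model="fd_lpb", eps_solute=4.0, kappa=kappa)
        phi = compute_field(s, lat, m).values
        r = np.linalg.norm(lat.points(), axis=-1)
        outside = r >= a_radius + 2 * lat.spacing
        exact = (
            L_VAC * np.exp(-kappa * (r[outside] - a_radius))
            / (EPS * r[outside] * (1 + kappa * a_radius))
        )
        assert np.max(np.abs(phi[outside] - exact) / exact) < 0.08

    def test_focusing_amplifies_buried_neighbour_potential(self):
        """A low-dielectric neighbour atom increases the potential of a
        nearby charge relative to pure solvent (electrostatic focusing)."""
        lat = make_lattice(8.0, 0.5)
        charged = single_atom(+1.0, 1.5, (0, 0, 0))
        bulky = single_atom(0.0, 2.5, (3.2, 0, 0), resnum=2)
        m = ElectrostaticModel(model="fd_lpb")
        alone = compute_field(structure_of(charged), lat, m).values
        with_bulk = compute_field(structure_of(charged, bulky), lat, m).values
        # probe inside the solvent volume the neutral atom displaces
        probe = np.array([2.5, 0.0, 0.0])
        idx = tuple(
            int(round((probe[a] - lat.origin[a]) / lat.spacing)) for a in range(3)
        )
        assert with_bulk[idx] > alone[idx]

    def test_nonconvergence_reports_residual(self):
        s = structure_of(single_atom(+1.0, 1.5))
        lat = make_lattice(6.0, 0.5)
        m = ElectrostaticModel(model="fd_lpb", sor_max_iter=2)
        with pytest.raises(RuntimeError, match="residual"):
            compute_field(s, lat, m)


class TestDX:
    def test_round_trip(self, tmp_path, lat8):
        rng = np.random.default_rng(0)
        field = ScalarFieldGrid(lat8, rng.normal(size=lat8.dims))
        path = str(tmp_path / "field.dx")
        write_dx(field, path, comment="test grid")
        back = read_dx(path)
        assert back.lattice.congruent(lat8)
        np.testing.assert_allclose(back.values, field.values, rtol=1e-5,
                                   atol=1e-8)

    def test_external_grid_model_resamples(self, tmp_path):
        src_lat = make_lattice(8.0, 0.5)
        pts = src_lat.points()
        field = ScalarFieldGrid(src_lat, pts[..., 0] + 2.0 * pts[..., 1])
        path = str(tmp_path / "lin.dx")
        write_dx(field, path)
        target = make_lattice(4.0, 0.25)
        m = ElectrostaticModel(model="external_grid", grid_path=path)
        out = compute_field(ChargedStructure([]), target, m)
        expected = target.points()[..., 0] + 2.0 * target.points()[..., 1]
        # trilinear resampling is exact for linear fields
        np.testing.assert_allclose(out.values, expected, atol=1e-4)
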