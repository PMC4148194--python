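"""CSG algebra, Surveyor volumes, Jaccard distances and resampling."""

import numpy as np
import pytest

from isovol import (
    Lattice,
    SolidRegion,
    TriangleMesh,
    csg,
    difference,
    intersection,
    jaccard_distance,
    resample_to,
    union,
)
from isovol.solids import (
    mesh_is_closed,
    mesh_volume,
    occupancy_from_mesh,
    occupancy_from_rle,
    occupancy_to_rle,
)

from conftest import make_lattice, sphere_solid


def lens_volume(r: float, d: float) -> float:
    """Intersection volume of two equal spheres of radius r at distance d."""
    return np.pi * (4 * r + d) * (2 * r - d) ** 2 / 12.0


def _resolved_sphere_pair(rng, r_lo=3.5, r_hi=5.0, min_feature=1.5,
                          box_half=None):
    """Random sphere pair whose every CSG output has features thicker than
    ``min_feature`` Å (lens and both caps), i.e. resolvable on the 0.5 Å
    lattice rather than sub-voxel slivers.  With ``box_half`` set, both
    spheres stay strictly inside the box (no boundary clipping)."""
    while True:
        r1, r2 = rng.uniform(r_lo, r_hi, size=2)
        c1 = rng.uniform(-1.0, 1.0, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        d = rng.uniform(1.5, r1 + r2 - min_feature)
        if d + r1 - r2 < min_feature or d + r2 - r1 < min_feature:
            continue
        c2 = c1 + d * direction
        if box_half is not None:
            if np.abs(c1).max() + r1 > box_half - 1.0:
                continue
            if np.abs(c2).max() + r2 > box_half - 1.0:
                continue
        return r1, r2, c1, c2


UNIT_CUBE_VERTS = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=float
)
# 12 triangles, outward-oriented
UNIT_CUBE_TRIS = np.array([
    [0, 2, 1], [1, 2, 3],  # z=0, normal -z
    [4, 5, 6], [5, 7, 6],  # z=1, normal +z
    [0, 1, 4], [1, 5, 4],  # y=0
    [2, 6, 3], [3, 6, 7],  # y=1
    [0, 4, 2], [2, 4, 6],  # x=0
    [1, 3, 5], [3, 7, 5],  # x=1
])


class TestSurveyorVolume:
    def test_unit_cube_is_exactly_one(self):
        mesh = TriangleMesh(UNIT_CUBE_VERTS, UNIT_CUBE_TRIS)
        assert mesh_is_closed(mesh)
        assert mesh_volume(mesh) == pytest.approx(1.0, abs=1e-12)

    def test_empty_solid_has_zero_volume(self, lat8):
        assert SolidRegion.empty(lat8).volume() == 0.0

    def test_open_mesh_volume_rejected(self, lat8):
        s = sphere_solid(3.0, lat8)
        open_mesh = TriangleMesh(s.mesh.vertices, s.mesh.triangles[:-3])
        assert not mesh_is_closed(open_mesh)
        broken = sphere_solid(3.0, lat8)
        broken._mesh = open_mesh
        with pytest.raises(ValueError, match="closed"):
            broken.volume()

    def test_surveyor_vs_voxel_oracle_on_random_csg_outputs(self):
        """Mesh volume within 5% of the spacing^3 x inside-count voxel
        oracle on 20 random CSG outputs."""
        rng = np.random.default_rng(11)
        lat = make_lattice(12.0, 0.5)
        for _ in range(20):
            r1, r2, c1, c2 = _resolved_sphere_pair(rng, 4.5, 6.0, 3.5,
                                                   box_half=12.0)
            op = rng.choice(["intersection", "union", "difference"])
            out = csg(op, sphere_solid(r1, lat, c1), sphere_solid(r2, lat, c2))
            if out.is_empty():
                continue
            assert out.volume() == pytest.approx(out.voxel_volume(), rel=0.05)


class TestCSGAlgebra:
    def test_idempotence_and_annihilation_exact(self, lat8):
        a = sphere_solid(4.0, lat8)
        np.testing.assert_array_equal(
            intersection(a, a).occupancy, a.occupancy
        )
        assert difference(a, a).is_empty()
        assert union(a, SolidRegion.empty(lat8)).volume() == pytest.approx(
            a.volume(), rel=1e-9
        )
        # self-intersection inherits the exact boundary: bit-identical volume
        assert intersection(a, a).volume() == a.volume()

    def test_disjoint_spheres(self, lat8):
        a = sphere_solid(3.0, lat8, center=(-4.0, 0, 0))
        b = sphere_solid(3.0, lat8, center=(4.0, 0, 0))
        assert intersection(a, b).is_empty()
        assert union(a, b).volume() == pytest.approx(
            a.volume() + b.volume(), rel=0.01
        )

    def test_lens_volume_analytic(self, lat8):
        """Two r=4 Å spheres 4 Å apart: intersection within 3% of the
        analytic lens pi (4r + d)(2r - d)^2 / 12."""
        a = sphere_solid(4.0, lat8, center=(-2.0, 0, 0))
        b = sphere_solid(4.0, lat8, center=(2.0, 0, 0))
        assert intersection(a, b).volume() == pytest.approx(
            lens_volume(4.0, 4.0), rel=0.03
        )

    @pytest.mark.parametrize(
        "r_lo,r_hi,identity_tol",
        [
            # spheres spanning >= 8 lattice cells: the 1% volume-identity
            # regime; smaller solids chamfer more at the operand crease and
            # degrade gracefully (bounded here at 2.5%)
            (4.0, 5.5, 0.01),
            (3.0, 4.0, 0.025),
        ],
    )
    def test_inclusion_exclusion_and_difference_identity(
        self, r_lo, r_hi, identity_tol
    ):
        """|V(A∪B) - V(A) - V(B) + V(A∩B)| <= 1% of V(A∪B), and
        V(A-B) + V(A∩B) = V(A) within the stated tolerance, on random
        sphere pairs."""
        rng = np.random.default_rng(5)
        lat = make_lattice(8.5, 0.5)
        for _ in range(20):
            r1, r2, c1, c2 = _resolved_sphere_pair(rng, r_lo, r_hi)
            a, b = sphere_solid(r1, lat, c1), sphere_solid(r2, lat, c2)
            va, vb = a.volume(), b.volume()
            vu = union(a, b).volume()
            vi = intersection(a, b).volume()
            vd = difference(a, b).volume()
            assert abs(vu - va - vb + vi) <= 0.01 * vu
            assert vd + vi == pytest.approx(va, rel=identity_tol)

    def test_noncongruent_lattices_rejected(self):
        a = sphere_solid(3.0, make_lattice(6.0, 0.5))
        b = sphere_solid(3.0, make_lattice(6.0, 0.25))
        with pytest.raises(ValueError, match="congruent"):
            csg("union", a, b)


class TestJaccard:
    def test_identical_and_disjoint(self, lat8):
        a = sphere_solid(3.0, lat8, center=(-4, 0, 0))
        b = sphere_solid(3.0, lat8, center=(4, 0, 0))
        assert jaccard_distance(a, a) == 0.0
        assert jaccard_distance(a, b) == 1.0

    def test_nested_spheres_closed_form(self, lat8):
        """Concentric r=3 inside r=4 spheres: 1 - (3/4)^3 = 37/64."""
        small = sphere_solid(3.0, lat8)
        big = sphere_solid(4.0, lat8)
        d = jaccard_distance(small, big)
        assert d == pytest.approx(1.0 - (3.0 / 4.0) ** 3, abs=0.01)
        assert d == pytest.approx(jaccard_distance(big, small), abs=1e-12)

    def test_both_empty_rejected(self, lat8):
        with pytest.raises(ValueError, match="empty"):
            jaccard_distance(SolidRegion.empty(lat8), SolidRegion.empty(lat8))


class TestResample:
    def test_same_lattice_is_identity(self, lat8):
        s = sphere_solid(3.5, lat8)
        out = resample_to(s, lat8)
        np.testing.assert_array_equal(out.occupancy, s.occupancy)

    def test_refine_preserves_sphere_volume(self):
        coarse = make_lattice(6.0, 0.5)
        fine = make_lattice(6.0, 0.25)
        s = sphere_solid(4.0, coarse)
        out = resample_to(s, fine)
        assert out.volume() == pytest.approx(s.volume(), rel=0.02)

    def test_translated_lattice_preserves_volume(self):
        lat = make_lattice(6.0, 0.5)
        shifted = Lattice(
            origin=np.asarray(lat.origin) + [0.21, -0.13, 0.08],
            spacing=0.5, dims=lat.dims,
        )
        s = sphere_solid(4.0, lat)
        out = resample_to(s, shifted)
        assert out.voxel_volume() == pytest.approx(s.voxel_volume(), rel=0.02)

    def test_too_coarse_target_rejected(self):
        s = sphere_solid(3.0, make_lattice(6.0, 0.25))
        with pytest.raises(ValueError, match="coarser"):
            resample_to(s, make_lattice(6.0, 1.0))

    def test_point_in_mesh_matches_occupancy(self, lat8):
        s = sphere_solid(4.0, lat8)
        occ = occupancy_from_mesh(s.mesh, lat8)
        # disagreement only possible in the boundary shell
        mismatch = occ ^ s.occupancy
        assert mismatch.sum() <= 0.02 * s.occupancy.sum()


class TestOccupancyRLE:
    def test_round_trip(self, lat8):
        s = sphere_solid(3.0, lat8, center=(1.0, -2.0, 0.5))
        text = occupancy_to_rle(s)
        back = occupancy_from_rle(text)
        assert back.lattice.congruent(s.lattice)
        np.testing.assert_array_equal(back.occupancy, s.occupancy)


class TestMeshIO:
    @pytest.mark.parametrize("ext", ["off", "ply"])
    def test_off_ply_round_trip(self, tmp_path, lat8, ext):
        from isovol.meshio import read_mesh, write_mesh

        s = sphere_solid(3.0, lat8)
        path = str(tmp_path / f"sphere.{ext}")
        write_mesh(s.mesh, path)
        back = read_mesh(path)
        assert mesh_is_closed(back)
        assert mesh_volume(back) == pytest.approx(s.volume(), rel=1e-6)

    def test_cube_mesh_volume(self, tmp_path):
        """A 10 Å OFF cube resampled onto a lattice keeps volume 1000."""
        from isovol.meshio import read_mesh, write_mesh

        mesh = TriangleMesh(UNIT_CUBE_VERTS * 10.0 - 5.0, UNIT_CUBE_TRIS)
        path = str(tmp_path / "cube.off")
        write_mesh(mesh, path)
        lat = make_lattice(7.0, 0.5)
        occ = occupancy_from_mesh(read_mesh(path), lat)
        solid = SolidRegion.from_occupancy(lat, occ)
        assert solid.volume() == pytest.approx(1000.0, rel=0.02)
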