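"""Extract a solid isopotential from a point-charge field.

A single -1 e charge in water (eps = 80) has the closed-form isopotential
sphere r* = l_vac / (80 |k|); comparing the extracted mesh volume against
(4/3) pi r*^3 shows the accuracy of the marching-cubes + Surveyor pipeline.
"""

import numpy as np

from isovol import ElectrostaticModel, Lattice, ThresholdSpec, compute_field, marching_cubes
from isovol.electrostatics import AtomRecord, ChargedStructure, coulomb_length

charge = ChargedStructure([
    AtomRecord(serial=1, name="X", residue_name="ION", chain="A",
               residue_number=1, insertion_code="",
               position=(0.0, 0.0, 0.0), radius=1.5, charge=-1.0)
])

k = -3.0  # kT/e
model = ElectrostaticModel()
r_star = coulomb_length(model.temperature) / (model.eps_solvent * abs(k))

lat = Lattice.from_bounds((-r_star - 2,) * 3, (r_star + 2,) * 3, spacing=0.5)
field = compute_field(charge, lat, model)
solid = marching_cubes(field, ThresholdSpec(k))

analytic = 4.0 / 3.0 * np.pi * r_star**3
print(f"threshold k = {k} kT/e -> isopotential sphere r* = {r_star:.3f} Å")
print(f"extracted solid volume : {solid.volume():.3f} ų "
      f"({solid.mesh.n_triangles} boundary triangles)")
print(f"closed-form volume     : {analytic:.3f} ų")
print(f"relative error         : {(solid.volume() - analytic) / analytic:+.2%}")
# The mesh volume should sit within a fraction of a percent of the sphere:
# the remaining deficit is the curvature the 0.5 Å lattice cannot see.
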