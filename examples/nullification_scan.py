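"""Find the residues that create electrostatic differences or drive
interface complementarity, by per-residue charge nullification.

Each residue's charges are zeroed in turn (atoms stay, preserving solvent
displacement), the relevant fields are rebuilt, and the residue is labelled
if its removal changes the volumetric statistic past the half-reduction
prediction thresholds.
"""

from isovol import (
    ElectrostaticModel,
    ThresholdSpec,
    compute_field,
    scan_cavity,
    scan_interface,
)
from isovol.fixtures import opposing_complex, planted_cavity_pair

model = ElectrostaticModel()

# -- cavity scan: which residue makes the test pocket different? ------------
test, ref, C_test, C_ref, planted = planted_cavity_pair(seed=1)
ref_field = compute_field(ref, C_test.lattice, model)
res = scan_cavity(test, ref_field, C_test, C_ref, ThresholdSpec(-2.5), model)
print(f"cavity scan at k = {res.k_used} kT/e: baseline difference "
      f"v0 = {res.baseline:.3f} ų, threshold T = {res.T:.3f} ų")
for rec in res.records:
    if rec.label != "none":
        print(f"  predicted {rec.residue_id}: v_r = {rec.statistic:.3f} ų "
              f"({rec.label})")
print(f"  planted ground truth: {planted}")

# -- interface scan: which residue holds the complex together? --------------
a, b = opposing_complex(seed=1)
res = scan_interface(a, b, side="A", k=1.0, model=model)
print(f"\ninterface scan at k = {res.k_used} kT/e: reference EC = "
      f"{res.baseline:.3f} ų, thresholds T_u = {res.T_u:.3f}, "
      f"T_l = {res.T_l:.3f} ų")
for rec in res.records:
    if rec.label != "none":
        print(f"  predicted {rec.residue_id}: ΔEC = {rec.statistic:.3f} ų "
              f"({rec.label})")
# A ΔEC of -EC means nullifying that residue erases all complementarity:
# it is the electrostatic anchor of the interface.
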