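# Methods

This note records the models behind isovol, the parameters that matter, the
numerical choices, and what the synthetic test systems do and do not show.

## Solids on a lattice

Every region — isopotential, cavity, molecular surface, interface region,
CSG output — is a `SolidRegion`: a signed per-lattice-point "insideness"
field s (inside ⇔ s ≥ 0, ties inside so solids are topologically closed)
plus a lazily extracted closed triangle mesh.  The lattice is cubic, in the
PDB frame, with the resolution (edge length) defaulting to 0.5 Å; all
production analyses here use that default, and the convergence tests halve
it to 0.25 Å where stated.

### Marching cubes

The boundary mesh is built per lattice cube from a 256-entry lookup table
indexed by the corner inside/outside pattern, with vertices on
inside↔outside lattice edges at the linearly interpolated crossing
t = (k − φ₁)/(φ₂ − φ₁).  The table is generated at import time by tracing
the chords of the inside region across the six cube faces and chaining them
into boundary loops.  Two choices differ from the textbook table and are
deliberate:

- **Ambiguous (saddle) faces** are resolved by a fixed, face-local pairing
  (the chords that keep the inside corners connected).  Because the decision
  depends only on the shared face, adjacent cubes always agree and the
  assembled surface is watertight for all 256 configurations — a property
  the classical complemented table does not have.  No asymptotic decider is
  used; at ≤ 0.5 Å spacing the affected cubes contribute negligibly to
  volumes, which are the only downstream quantity.
- **Loop triangulation** avoids interior diagonals that lie on a cube face
  (they could be duplicated by the neighbour) via a minimal-cost interval
  DP, and the loop is canonicalised over rotation/reflection first so the
  same geometric polygon is always triangulated identically.  Shared
  boundary pieces of complementary solids (e.g. A∩B and A−B) then cancel
  exactly in volume sums.

Solids that reach the lattice boundary are clipped and capped: the signed
field is padded with an outside ghost layer 10⁻⁹ spacings beyond the box,
which closes the mesh with faces essentially on the boundary plane
(relative volume perturbation < 10⁻⁸).  A warning is logged, since a field
exceeding its box usually means the box was sized too small.

### Volumes and the voxel cross-check

Volumes use the Surveyor's (divergence-theorem) formula over the closed
mesh, |Σ det[v₁v₂v₃]|/6, cached per solid.  An independent estimate,
spacing³ × (inside-point count) with half-open voxel ownership, is used as
an oracle in tests.  The voxel count is unbiased only for boundaries in
generic position: a boundary lying exactly on a lattice plane shifts it by
up to one voxel layer, which the test geometries avoid (mid-voxel plane
offsets).

### CSG

Boolean operations act on the signed fields pointwise (min, max, min with a
nudged negation), making output occupancy the exact boolean of the inputs.
For results expressible as a flat min or max of operands (intersections,
unions, differences of primitives — and, via De Morgan, difference by a
union), the boundary crossing on an edge is solved exactly from the
per-operand linear interpolants; edges owned by one operand inherit its
crossing bit-exactly, so A∩A reproduces A's mesh identically.  Deeper mixed
nestings fall back to interpolating the combined field, which degrades only
crease cubes.  Where the set algebra allows (cavity-field differences with
both operands clipped to I), differences are flattened to intersections
with complements to stay on the exact path.

**Accuracy regime.**  Marching cubes cannot represent the sharp ridge where
two operand surfaces cross inside one cube; both adjacent solids lose the
ridge wedge (chamfering), an O(h²)-per-unit-crease-length, systematically
negative volume error.  Measured on sphere pairs at 0.5 Å: volume identities
(V(A−B) + V(A∩B) = V(A)) hold to ≤ 1% for solids spanning ≥ 8 cells
(r ≥ 4 Å) and to ~1.6% at r = 3 Å; inclusion–exclusion is exact to float
precision because the union and intersection chamfer identically.  Features
thinner than ~3 cells (near-tangent operands, sub-voxel slivers) are below
the lattice's resolving power and their volumes are only indicative; tests
and the acceptance measurements draw geometries with ≥ 2.5–3.5 Å minimum
feature thickness, and analyses needing sub-percent partition identities
should run at 0.25 Å.

### Resampling

Point-in-solid tests against a closed mesh use axis-aligned ray parity with
ray origins nudged by an irrational sub-voxel offset to dodge edge/vertex
hits.  Resampling to a lattice more than 2× coarser is refused.

## Electrostatic models

All potentials are in kT/e at the model temperature (default 298.15 K).
The unit bridge is the vacuum Coulomb length
l_vac = e²/(4πε₀ k_B T) ≈ 560.47 Å at 298.15 K, derived from CODATA
constants, so φ of a unit charge in a uniform dielectric ε is
l_vac/(ε d) kT/e.

- `debye_huckel` (default): screened-Coulomb superposition
  φ(p) = Σ l_vac qᵢ e^{−κdᵢ}/(ε_s dᵢ), dᵢ clamped below half a lattice
  spacing (configurable) to keep grids finite.  Exact for uniform
  dielectric; linear in the charges, so nullification differences obey
  superposition exactly.  ε_s defaults to 80 (water), κ to 0.
- `fd_lpb`: linearized Poisson–Boltzmann on the lattice,
  ∇·(ε∇φ) − ε_s κ² m φ = −4π l_vac ρ, with ε = ε_solute (default 4) inside
  the union of atom balls and ε_s outside, κ² active in solvent only (m),
  harmonic-mean face dielectrics, 7-point stencil, red-black SOR (ω = 1.8),
  Debye–Hückel Dirichlet boundaries, convergence at max update < 10⁻⁵ kT/e
  (error raised with the residual otherwise).  The potential is split as
  φ = φ_c + ψ with φ_c the analytic Coulomb field in the solute dielectric;
  the grid solves only the smooth reaction/screening correction ψ.  This
  removes the point-source discretisation error (the raw spread-charge
  stencil is ~7% wrong two cells from a charge; the split scheme is exact
  there in the uniform limit and within 4% of the Born/Debye–Hückel closed
  form outside a charged sphere).  Charges are assumed to sit inside their
  own atom balls.  Nullification changes the source term only — the
  dielectric mask is built from atoms, which nullification preserves — so
  electrostatic focusing by a nullified residue's bulk is retained.
- `external_grid`: an OpenDX scalar grid (APBS dialect) used directly when
  congruent with the working lattice, else trilinearly resampled
  (extrapolation refused).  This is the injection point for potentials from
  full nonlinear PB solvers; the built-in models are linear-response
  stand-ins, and absolute volumes at a given k depend on the solver, grid
  and salt settings used.

The PQR path is canonical for charges; the PDB fallback assigns formal
side-chain charges (Asp/Glu −0.5 per carboxylate oxygen, Lys +1, Arg +0.5
per NH, His 0, flagged termini ±1) with Bondi-style radii and is logged as
approximate.

## Regions

- Interface residues: any-atom within 5.0 Å of the partner (hydrogens count
  if present); no solvent-exposure filtering, so buried hot spots stay in.
  The interface region is the union of 5.0 Å spheres on every atom of those
  residues.  Both radii are parameters (`RegionParams`).
- Molecular (solvent-excluded) surface: morphological closing of the
  union-of-balls at the probe radius (default 1.4 Å), implemented as an
  exact dilation (inflated radii) followed by an Euclidean-distance-
  transform erosion with a half-voxel debias; the result is clamped to
  contain the union-of-balls, so SES ⊇ van der Waals solid always holds at
  occupancy level.  Accurate to the lattice regime, not an analytic
  rolling-probe surface.
- Cavities are inputs (sphere-union text specs or closed OFF/PLY meshes);
  no cavity detection is attempted, and structures must be pre-aligned by
  the caller.

## Scans and thresholds

The cavity statistic is v_r = V((E_test,r ∩ I) − (E_ref ∩ I)) — the
difference direction follows the test-minus-reference convention (a
symmetric-difference flag exists).  The thresholds are reconstructions of
verbal rules: T = (v₀ + min_r v_r)/2 ("at least half the best achievable
reduction"); T_u = max_r D_r/2 and T_l = min_r D_r/2 for interfaces, each
applied only when fewer than 10% of scanned residues cross it.  The label
set deliberately carries no ranking: two predicted residues' statistics are
not comparable measures of their relative influence.  All residues of the
designated structure are scanned, not only interfacial ones, because
long-range field effects are the point of the method.

Multi-threshold drivers sweep k ∈ {−2.5, −5, −7.5, −10} kT/e (cavities) or
{1, 3, 5, 7, 9} kT/e (interfaces) and keep the k with the largest
per-residue response spread — the most discriminating calibration — since
fields are threshold-independent and can be re-cut cheaply.  A side facing
an already-calibrated partner can reuse that partner's k.

## Clustering

UPGMA merges the closest pair at height d/2 with size-weighted arithmetic
mean updates; ties break deterministically toward the pair containing the
smallest original label.  Output matches SciPy's average linkage to 1e-9
(cophenetic comparison; SciPy heights are full distances, twice ours).
A pair of identically empty fields gets Jaccard distance 0 with a warning
(the 0/0 ratio is otherwise undefined).

## Synthetic test systems

The generators build the smallest point-charge systems that exercise the
inference paths with unambiguous planted truth.  `planted_cavity_pair`:
a shared 4 Å spherical cavity ringed by a neutral scaffold, with one −1 e
residue buried 5.2 Å below the cavity centre in the test copy only and 11
neutral decoy residues ≥ 16 Å out; at k = −2.5 kT/e the planted charge
carves a ~11 ų cavity field the reference lacks.  `opposing_complex`: +1 e
and −1 e residues facing each other across a seeded 6–10 Å gap, each
extending a neutral tip atom to 1.5 Å from the midplane so the 5 Å contact
rule fires; 11 neutral decoys per side keep one true positive under the 10%
suppression rule (12 scanned residues).  Decoys are kept ≥ 15 Å from the
cavity/interface so ground truth is unambiguous at the default thresholds.

What passing these recovers and what it does not: the scans provably wire
fields, CSG, thresholds and labels together correctly, and the planted
residue is recovered with zero false positives across seeds.  Real
structures differ in every hard way — thousands of partially charged atoms,
correlated charge networks, conformational error, protonation ambiguity,
cavity-definition sensitivity and nonlinear PB effects — so recovery here
validates the machinery, not expected accuracy on experimental complexes.

## Known limitations

- Volumes inherit the lattice accuracy regime: sub-voxel features are
  unresolved, crease chamfering costs up to a few percent on small
  intersection-bounded solids at 0.5 Å (quadratically less at 0.25 Å).
- The built-in electrostatics is linear-response; strong-field nonlinear
  saturation near highly charged sites needs an external grid.
- Nullification models charge silencing, not mutation: side chains are
  never rebuilt, and no free energies are estimated.
- Structures are compared in the caller's alignment; no structural
  alignment is performed.
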