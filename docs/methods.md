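# Methods

## Wavefunctions

Everything is computed from a closed-shell single determinant over
contracted cartesian Gaussians (6d convention, Molden component order).
Readers exist for Molden, AIM `.wfn`/`.wfx`, and a compact JSON fixture
format; only doubly-occupied determinants are accepted, and spin-polarized
or spherical-harmonic-d input is rejected with an explicit error rather
than silently converted.  All internal quantities are in atomic units.
Parsed orbitals must satisfy ‖C†SC − I‖∞ < 1e−6 against the analytically
computed basis overlap; JSON fixtures store coefficients rounded to five
significant digits and are symmetrically re-orthonormalized on load (a
rotation within the occupied span, which leaves every density-derived
quantity unchanged at the 1e−7 level).

The packaged Ph–X wavefunctions are B3LYP/6-31G(d) (the Gaussian-style
B3LYP with VWN3 correlation) at geometries optimized at the same level
(max nuclear gradient ≤ 4e−4 hartree/bohr).  The generating engine is
external tooling behind the pluggable driver contract in
`elfiqa.qmdriver`; its cached outputs ship as data so the analysis is
reproducible without any quantum-chemistry engine installed.

## ELF and the grid protocol

The ELF kernel is the standard closed-shell total-density form
χ = D/D₀ with D = τ − |∇ρ|²/(8ρ), D₀ = (3/10)(3π²)^{2/3} ρ^{5/3} and
τ = ½Σᵢ nᵢ|∇φᵢ|²; η = 1/(1+χ²).  Where ρ < 1e−10 e/bohr³ the point is
treated as vacuum (η = 0).  Tiny negative D from round-off in one-orbital
regions is clamped to zero, which makes η exactly 1 there.

The protocol grid has 150 points per axis.  The box places 3 bohr of
margin beyond the nuclei on the two largest-extent axes — which are then
expanded to equal length, so the in-plane mirror planes of a planar ring
coincide with grid planes and symmetry-equivalent basins receive
numerically identical treatment — and 5 bohr on the smallest-extent axis
(the π-system normal, whose density tails reach further).  The 3-bohr
margin is a grid-convergence choice: at 150 points the aromatic-bond
kinetic energy per electron is converged only for voxels ≲ 0.105 bohr,
which a 5-bohr margin cannot deliver; the box-truncation loss is ≤ 0.03 e
for every system analyzed here and is reported by the conservation check.

## Basin construction

1. **Discrete ascent.** Every non-vacuum voxel follows its steepest uphill
   neighbor over the 26-stencil, maximizing (η_neighbor − η)/|step| (the
   step length matters on an anisotropic grid), with zero-slope moves
   allowed only toward a lower linear index so that exact plateaus — the
   field is quantized to 1e−8 first — drain deterministically.  Pointer
   jumping compresses paths to attractors.
2. **Attractor merging.** Attractors are merged transitively when closer
   than 0.2 bohr with η differing < 1e−3 (grid-split point maxima), or
   when their basins touch and the boundary ridge reaches the lower
   attractor value within 1e−3 (ring-shaped or plateau maxima, which have
   no ELF barrier between them).
3. **Boundary refinement.** The discrete ascent misplaces boundary voxels
   with a grid-orientation bias (axis-aligned vs oblique bonds).  A
   two-voxel frontier is therefore re-ascended from voxel centers along
   the trilinearly interpolated gradient, and the remaining one-voxel
   frontier is split into 3×3×3 sub-points whose independent ascents give
   fractional basin weights, used by all integrators.  In benzene this
   reduces the spread of the six symmetry-equivalent V(C,C) populations
   from ~0.09 e (raw discrete ascent) to ~0.003 e.
4. **Optional core refinement** (`core_refine=True`): around heavy-atom
   cores the η variation is too sharp for trilinear interpolation, leaving
   a residual few-milli-hartree orientation bias in basin kinetic
   energies.  This option re-evaluates η from the wavefunction on a local
   2×-finer grid (radius 1 bohr per heavy atom) and ascends the near-core
   sub-points there, restoring the benzene t/n degeneracy to ~0.003 au.
   It is off by default because grid-native reference values (TopMod-class
   codes at the same resolution) embed the coarser core treatment: with
   refinement the benzene aromatic t/n moves from 1.166 to 1.176 au
   (a 200³ grid converges to ~1.173).  Choose the default to compare with
   grid-native literature numbers; choose `core_refine` for internally
   consistent symmetry behavior.

Synapticity: a basin whose attractor lies within 0.6 bohr of a Z > 2
nucleus is that atom's core; valence basins are classified by the distinct
core basins their boundary touches, with hydrogens (which own no core)
granted through attractor proximity ≤ 1.5 bohr or by containing the proton
(the protonated-basin rule).  Basins below 0.05 e are flagged spurious and
reported, never silently merged; with the ridge-merge rule above the only
spurious basins seen in practice are milli-electron tail fragments at the
box edge.  Ring labeling walks the 6-cycle of carbons connected by
disynaptic V(C,C) basins, anchored at the carbon bonded to the substituent
(for benzene, any marked hydrogen serves); the two walk directions are
equivalent under the mirror averaging used downstream.

## Integration and descriptors

Populations, kinetic energies and domain overlap matrices S^Ω are plain
voxel Riemann sums (with the fractional boundary weights); refinement is
by grid density, not boundary-aware quadrature.  Quality metrics asserted
by the test-suite on every analyzed system: Σn_Ω within 0.05 e of the
electron count, ΣT_Ω within 0.1% of the integrated τ, ‖ΣS^Ω − I‖ < 5e−3,
n_Ω = 2 tr S^Ω to machine precision, and the delocalization sum rule
λ(A) + ½Σδ(A,B) = n_A within 0.05 e.

Delocalization indices use the closed-shell reduction
δ(A,B) = 4 Σᵢⱼ S^A_ij S^B_ij, λ(A) = 2 Σᵢⱼ (S^A_ij)², verified on toys
against a brute-force pair-density covariance oracle to 1e−6.  Mirror-pair
ring quantities (b23/b56, b34/b45, b12/b61) are averaged, with the
intra-pair spread reported and flagged above 0.1 e.  Pattern
classification uses ε = 0.01 e on the averaged populations
(inductive decay: q12 > q23 > q34; mesomeric: q23 maximal) and ε = 0.005
on ΔDI signs for orientation ((+,−,+) → ortho/para; negative o and p →
meta; anything else indeterminate).  Δ-quantities are exact differences
against a benzene reference computed with identical settings (enforced by
a settings hash); the packaged reference is regenerable by running the
pipeline on the packaged benzene wavefunction.

## IQA terms

Inter-basin energetics use a deliberately coarse direct quadrature: the
fine grid is aggregated into cells of 6 voxels per edge carrying the cell
charge, charge centroid, and the orbital-product integrals P_ij = ∫φᵢφⱼ.
Coulomb terms are centroid double sums (cell self-terms approximated by a
uniformly charged equal-volume sphere); nuclear attraction/repulsion enter
only for basins that own a nucleus (cores), so a bond–bond interaction is
purely electron–electron by construction, and E_inter = V_Coul + V_x,
E_intra = T + V_Coul + V_x hold identically.  Exchange is the
single-determinant exchange-only form
V_x^{AB} = −2 Σᵢⱼ Σ_{a∈A,b∈B} P^A_ij P^B_ij / r_ab ≤ 0 (both orderings
counted; −1× ordered sum for A = B).  The accuracy class is "ranks and
signs, few-percent energies", recorded in every output; the rank
correlation of |V_x| with δ across vicinal ring pairs is the tested claim.

## Synthetic toys

`make_toy_wavefunction` provides determinants with closed-form behavior:
`one_orbital_bond` (one doubly-occupied two-center σ MO; ELF ≡ 1 where
dense, δ = 4s(1−s) for any bipartition), `two_orbital_model` (4 electrons
in g/u pairs; at large separation δ between the halves vanishes), and
`atomlike` (tight + diffuse shells giving a core/valence ELF shell).
These exercise every invariant the real molecules rely on, but they have
no ring topology, no heavy-atom cores with sharp interfaces, and no π
system — so the toy-level exactness tests say nothing about grid-bias
effects, which is why the benzene degeneracy checks exist.

## Known limitations

- Basin *voxel counts* are not a converged observable: basins extend to the
  rectangular box boundary, whose corner volumes cannot be shared six-fold
  symmetrically among benzene's bond basins, and integer labels quantize the
  refined boundary.  Benzene's V(C,C) counts consequently spread by ~5%
  while every charge-weighted degeneracy (populations, DIs, kinetic
  energies) holds to 0.1–0.3%.  Boundary voxels carry their sub-voxel
  majority label, so label cubes follow the refined partition as closely as
  an integer map can.
- Grid-native absolute populations carry ~0.01–0.03 e method dependence
  (attractor-merge and core-radius conventions differ between codes); Δ
  quantities against the matched benzene reference are much tighter.
- The 150³ protocol leaves a ~0.009 au orientation spread in benzene's
  V(C,C) t/n under the default boundary treatment (see core refinement
  above for the trade-off).
- Anions are analyzed with the same 6-31G(d) basis as the neutral systems
  (no diffuse functions), matching the generation protocol of the
  packaged wavefunctions.
- Spin-polarized ELF, correlated pair densities, and ELF bifurcation
  trees are out of scope.
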