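# Methods

This note records the models, numerical schemes and design choices behind
iqakit, in the package's own words. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The energy decomposition

A closed-shell QM energy is partitioned over the topological atoms of the
electron density (QTAIM basins Ω_I, the attraction basins of ∇ρ):

    E = Σ_I E_net^I + Σ_{I<J} E_int^IJ

`E_net^I` collects the kinetic energy integrated over Ω_I, the attraction
of Ω_I's electrons to their own nucleus, and the intra-basin
electron–electron repulsion. `E_int^IJ` collects the nuclear–nuclear,
nucleus–electron (both directions) and electron–electron terms between the
two basins. The pair density of a single determinant is used,
ρ₂(1,2) = ρ(1)ρ(2) − ½ρ₁(1,2)², which splits every electron–electron term
into a classical Coulomb part and an exchange part, so that
`E_int = E_ele + E_xc` holds exactly by construction. For DFT densities the
same Hartree–Fock-like exchange is built from the Kohn–Sham ρ₁ and all
intra- and inter-basin xc terms are subsequently multiplied by one global
factor κ chosen so that the reconstructed total equals the SCF energy
exactly; κ is recorded in the term-matrix metadata. A per-term scaling
scheme exists in the literature; the global factor is a documented
simplification, not a claim of equivalence.

Additive atomic energies are `E_add^I = E_net^I + ½Σ_J E_int^IJ` plus
either half (the `half_share` convention, with the other half booked to the
MM side) or all (`qm_full_qmmm`) of the QM–MM pairwise terms. Their sum
reproduces the total exactly — this is bookkeeping, independent of
quadrature error, and is asserted to machine precision in the tests.

### QM/MM coupling

With electronic embedding, the QM–MM electrostatic energy decomposes over
(basin, MM site) pairs:

    E_ele^IJ' = −q_J' ∫_{Ω_I} ρ(r)/|r−R_J'| dV + Z_I q_J'/|R_I−R_J'| ,

whose sum over pairs equals the unpartitioned Coulomb integral identically
on the same grid (asserted as a closure test). The vdW coupling is the
Amber-convention Lennard-Jones pair energy ε_IJ[(r_min/R)¹² − 2(r_min/R)⁶]
with arithmetic r_min/2 and geometric ε combination. Bond/angle/torsion MM
energies are split to atoms as ½, ⅓ and ¼ shares per participating atom;
covalent QM–MM cuts are capped with H-link atoms, and MM sites bonded
directly to a QM atom are excluded from QM electrostatics (the link H takes
over their role). A relative-energy mode drops purely-MM terms.

### Dispersion

Pairwise third-generation dispersion with Becke–Johnson rational damping is
added to the diatomic terms: E = −Σ_{I<J} [s₆C₆/(R⁶+f⁶) + s₈C₈/(R⁸+f⁸)]
with f = a₁√(C₈/C₆)+a₂, coordination-number-interpolated C₆ (Gaussian
weights, k₃=4; counting function with k₁=16, k₂=4/3-scaled covalent radii)
and C₈ = 3√(Q_I Q_J)C₆. No three-body term. The packaged reference table
(`d3_reference_synthetic.json`) is a *synthetic surrogate*: one reference
point per element with free-atom C₆ values and tabulated ⟨r⁴⟩/⟨r²⟩ factors,
because the original coordination-resolved reference dataset is not
redistributable here. Absolute dispersion energies therefore differ from
the original parameterization; the implementation of the functional form is
verified by an independent scalar-arithmetic re-implementation to 1e-8
hartree and by the asymptotic, symmetry and invariance properties.

### Implicit solvation

Polar: two finite-difference solves of ∇·ε∇φ = −4πρ_q on the same cubic
lattice (7-point stencil, trilinear charge spreading, Dirichlet screened-
Coulomb boundary values, diagonally preconditioned CG) — one with the
solvated dielectric map, one with uniform solute dielectric — give the
reaction-field potential Φ_RF as their difference at the atoms (the grid
self-energy cancels). The dielectric boundary is the union of spheres at
the atomic radii plus the probe radius (an accessible-surface-type
boundary; a molecular-surface reconstruction is not attempted). The polar
energy uses the linear-response convention ½Σq_IΦ_RF(R_I), recorded in the
output metadata. Defaults: 0.33 Å spacing, ε 1/80, probe 1.4 Å, null ionic
strength (pure Poisson). The Born closed form is reproduced within 2% at
the default spacing and the error falls monotonically under refinement.

Nonpolar: the cavity term is p·V_I over solvent-accessible volumes (voxel
union assigned by deepest burial, so ΣV_I is the union volume exactly); the
attractive term integrates the solute–solvent r⁻⁶ interaction (water-oxygen
LJ site, solvent number density 0.03343 Å⁻³) over the solvent region via
the divergence theorem as a surface sum over Shrake–Rupley-style SAS
elements (deterministic Fibonacci lattice): G^IJ = −C_I ρ_w Σ_s σ_s
(r̂_Is·n_s)/(3r_Is⁵), symmetrized as G′=(G+Gᵀ)/2 (total conserved exactly).
The pressure parameter p and solvent constants are configuration values.

ESP-fitted charges for the QM region use a cubic lattice in the shell
between per-element exclusion radii and 2.8 Å, the analytic one-electron
potential integrals of the density, and constrained least squares (the
total-charge constraint holds to machine precision).

Per-atom solvation is G_solv^I = polar_I + p·V_I + Σ_J G′^IJ; the atomic
terms sum to the total solvation energy exactly.

### Fragments and scores

Atomic terms regroup exactly over any atom→fragment map (asserted to
machine precision for random maps). Rigid formation energies decompose as
ΔE_form = ΣE_def + ΣE_int^AB with E_def the net-energy change of a fragment
between complex and isolated reference at identical internal geometry
(checked to 1e-4 bohr). Binding scores follow
ΔG = G(cmplx) − G(rec*) − G(lig*) with G = E^QM/MM + G_solv (+3RT); the
3RT term (six external degrees of freedom) is off by default so component
sums reproduce tabulated scorings, and on for absolute G values.

## Numerics

**Basins and grids.** Critical points are located by Newton search with
analytic density Hessians, classified by Hessian signature; a bond CP's two
steepest-ascent paths must reach distinct attractors. Nuclei that are not
density attractors (possible in a Gaussian basis under strong charge
transfer, e.g. the hydrogen in HeH⁺) carry no basin; all their density
belongs to the engulfing neighbor, and the nuclear-attraction integrals of
such an off-center nucleus are computed on an auxiliary nucleus-centered
spherical grid to tame the Coulomb singularity.

Each basin is integrated on its own atom-centered spherical grid: a
β-sphere segment (radius 60% of the distance to the nearest bond CP,
falling back to 60% of half the nearest-neighbor distance, capped at
1.5 bohr) with a cusp-adapted radial map, plus an outer segment in which
every angular ray is radially truncated at the basin boundary located by
bisection on a steepest-ascent ownership test (Heun steps on the normalized
gradient — plain Euler steps hop across thin basins — with capture inside
any β-sphere, step size limited by the clearance to the nearest capture
sphere, and stalled near-separatrix points resolved by the side of the bond
CP's surface; the public assignment op re-integrates stalled points with a
fine fixed-step scheme). Every stored node therefore belongs to its atom
and the basins tile space once. Angular quadrature is a Gauss–Legendre ×
uniform-φ product grid realizing at least the preset's requested point
count; Lebedev tables are not available in this environment and the product
rule is an accuracy-equivalent substitution at slightly higher point
counts. Radial quadrature is Gauss–Legendre per segment (a pure-accuracy
substitution for trapezoidal Euler–Maclaurin rules at equal counts). Basin
construction is deterministic: identical inputs give bit-identical grids.

**Electron–electron integrals.** No analytic two-electron integrals are
used. Intra-basin Coulomb and exchange double integrals use the
single-center Laplace expansion of 1/r₁₂ up to the preset's λ_max. The
basin-restricted sources are sampled on a product mesh (dense common radial
mesh × the fine angular rays), per-ray cumulative integrals are evaluated
*exactly at each ray's boundary cap* (cubic-spline cumulative quadrature
with a local end correction), assembled into radial potential kernels
U_lm, W_lm, and splined in premultiplied form (U/r^{l+1}, r^l·W) so that
spline leakage at small radii is never amplified by negative powers; a
leading-run zero guard removes cumulative-quadrature roundoff where the
genuine channel content is ~r^{l+3}. The resulting expansion potential is
accurate (~1e-5) at any point *interior* to its source region but converges
slowly just outside a basin boundary. Inter-basin terms therefore come in
two flavors: for basins sharing an interatomic surface (bonded, R < 5 au),
the pair integral is the difference of three self-integrals,
S_IJ = ½(S_{I∪J} − S_I − S_J), where the union basin is built on a single
center with its own exact ray caps — every potential evaluation is then
interior to its source, which removes the near-boundary convergence
problem; for separated basins the direct expansion potential of one basin
evaluated on the other's nodes (symmetrized) is already essentially exact.
A multipolar mode (basin multipole moments, refused below 5 au) serves
long-range pairs, and interatomic exchange is neglected beyond 17 au.
Direct six-dimensional double-grid sums over pair node sets are retained as
the brute-force oracle route for tests; for touching basins that oracle
itself converges only to a few 1e-4 hartree at tractable node counts, so
the binding accuracy check for bonded pairs is the reconstruction residual
against the SCF total (an exact external anchor), while the 1e-4 dual-route
comparison runs on separated-cloud systems where the oracle is converged.

The kinetic energy uses the positive-definite (gradient) form; for exact
basins it integrates to the Hamiltonian value, and any difference on
numerical basins is part of the reported reconstruction residual, which is
always surfaced and never absorbed.

**Orbital handling.** Pipek–Mezey localization (Jacobi sweeps on Mulliken
charges from analytic overlaps) is available; all physical terms are
invariant under it (asserted at 1e-6 hartree). Per-basin orbital subsets
keep MOs whose diagonal basin overlap exceeds 1e-6 (configurable); an MO
dropped by every basin is reattached to its largest basin so sum rules
survive screening.

**Grid presets.** `paper` stores the published protocol verbatim (5810/974
angular points outside/inside β-spheres for heavy atoms, 3890/590 for H;
512/384 and 384/256 radial; r_max 15/10 au; λ_max 10/6). `desk` is the
working preset for the packaged fixtures: 974/194 angular (heavy),
590/110 (H), 96/64 radial, r_max 12/9 au, λ_max 12, with a coarser
194/110-point pair node set for the oracle route. `mini` is a smoke-test
preset. Problem sizes in the tests (desk/mini on 1–5 atom fixtures) are the
package's own choice of fixture scale; at `desk` the reconstruction
residual on the packaged two- and three-atom systems is below 1e-3 hartree
and population sums are good to ~1e-4 e.

**Separatrix ties** go to the lowest atom index. Non-nuclear attractors are
not promoted to pseudo-atoms in this release: ascent trajectories that
terminate at a non-nuclear stationary point are logged and assigned to the
nearest nucleus (none of the packaged systems has an NNA; sum rules remain
exact either way because every node is assigned exactly once).

## The synthetic systems

The spherical-Gaussian model systems give closed-form populations and
inter-cloud Coulomb energies (error-function formula), exercising the whole
pipeline without an SCF engine. The hydrated-ion cluster generator emits a
metal ion with an octahedral first shell and quasi-uniform outer shells of
rigid three-site waters (TIP3P charges on MM waters; shell radii chosen for
packing feasibility), reproducing the cumulative quantum-region series
6, 18, 42, 90, 186 waters; it produces geometry and charges only — no
wavefunctions for these clusters. The toy host–guest complex couples the
packaged embedded water wavefunction to its generating point-charge cage
for end-to-end decomposition and scoring runs.

What the fixtures do not emulate: large QM regions, protein environments,
diffuse or cuspy (Slater-type) densities, open-shell states, conformational
ensembles. Passing tests demonstrate the correctness of the partitioning,
bookkeeping and solvers at fixture scale, not production accuracy on
100+-atom complexes — on such systems the published protocol itself reports
numerical IQA uncertainties of a few kcal/mol.

## Packaged wavefunctions

The wfx/molden fixtures were generated once by `scripts/make_fixtures.py`
with the small self-contained RHF/RKS engine under `scripts/scfgen/`
(McMurchie–Davidson integrals, B3LYP = 0.20 HF + 0.80 LSDA + 0.72 B88
exchange with 0.19 VWN5 + 0.81 LYP correlation, sympy-derived consistent
potentials, Becke-partitioned quadrature, DIIS). Each fixture ships a JSON
manifest (SCF/kinetic/nuclear energies, dipole, density samples) used as
test oracles. The triple-zeta basis labelled `tz-synthetic` uses published
correlation-consistent primitive exponents with contraction coefficients
re-derived by spherically averaged atomic HF in the same primitives (no
basis-set library is distributable here); the hydrogen-atom energy in this
basis, −0.49981 hartree, matches the published correlation-consistent
triple-zeta value, and the engine is also validated by the water HF total
in the same basis. The embedded-water fixture was converged in the field of
six TIP3P point charges (electronic embedding).

## Known limitations

- Closed-shell single determinants only; no correlated pair densities.
- One global xc-scaling factor for DFT (per-term schemes not implemented).
- No Ewald/periodic electrostatics, no polarizable MM, no salt (nonlinear
  Boltzmann) term, no molecular-surface dielectric boundary.
- Union-basin construction assumes the union is radially contiguous along
  rays from its center (true for bonded pairs; the far-separated case uses
  a different route).
- The dispersion parameter table is a labelled synthetic surrogate (see
  above); absolute dispersion energies are indicative only.
- Cuspy densities would degrade the union-route radial quadrature across a
  partner nucleus; the packaged Gaussian-basis fixtures are smooth there.
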