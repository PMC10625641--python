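# Methods

`dnadyn` simulates the equilibrium and non-equilibrium dynamics of
structured DNA assemblies (origami-scale objects built from bundled double
helices) with a coarse-grained finite-element model: one rigid body per base
pair, six degrees of freedom each, coupled to an implicit viscous solvent
through a configuration-dependent hydrodynamic operator and driven by
thermal noise. This note records the model, its parameters, the numerical
choices, and what the synthetic test structures do and do not probe.

## Structural model

Each base pair is a node with a position (nm) and a right-handed orthonormal
triad (stored as a unit quaternion; local z along the helical axis).
Connections are typed finite elements:

- **step** — intrahelical base-pair step. Its configuration is measured by
  the six step parameters (shift, slide, rise; tilt, roll, twist) computed
  with the CEHS/mid-step-triad construction used by 3DNA: the relative
  rotation is split into a bend Γ about the hinge axis z_a × z_b and a
  twist about the mid-step z axis; tilt and roll are the components of the
  bend vector on the mid-step x/y axes; the displacement is expressed in
  the mid-step frame. The element energy is E = ½ Δqᵀ K Δq in the deviation
  Δq from the element's intrinsic geometry, with angle deviations wrapped
  to (−180°, 180°] and taken in radians.
- **crossover** — interhelical strand exchange, same energy form with a
  softer stiffness table.
- **ssdna** — single-stranded connection, an isotropic entropic spring
  E = ½ k (|r| − ℓ₀)² with k = 3k_BT/(2 L_p L_c), persistence length
  L_p = 1 nm and contour length L_c = 0.7 nm per nucleotide. This is the
  simplest defensible model for a short unstructured tether; multi-arm
  vertex junctions are known to be more complex and are out of scope.
- **stacking** — blunt-end coaxial stacking, a breakable Morse bond on the
  distance between the two node reference points (below).

### Default elasticity table

Sequence-dependent stiffness tables derived from all-atom simulation exist
but are not reproducible here; the package ships a sequence-averaged B-DNA
table derived from bulk moduli, kept in one place
(`dnadyn.constants.DEFAULT_PARAMS`) so a measured table can be dropped in:

| quantity | value | origin |
|---|---|---|
| rise / twist | 0.34 nm / 34.3° | canonical B-DNA |
| stretch & shear stiffness | S/h = 1100/0.34 ≈ 3235 pN/nm | stretch modulus ≈ 1100 pN |
| bend stiffness (tilt, roll) | k_BT·L_p/h ≈ 609 pN·nm/rad² | persistence length 50 nm |
| twist stiffness | k_BT·L_t/h ≈ 1218 pN·nm/rad² | torsional persistence 100 nm |
| crossover softening | ×0.1 on the whole 6×6 | see below |
| node mass | per-residue masses, both strands (A 313.2, C 289.2, G 329.2, T 304.2 Da) | nucleotide-monophosphate averages |
| node inertia | rigid cylinder r = 1 nm, h = 0.34 nm | geometric estimate |

Crossovers are softened uniformly, translations included, not only in
rotation. A crossover is a strand junction, not an intact duplex step, and
it spans the ~2.5 nm inter-helix pitch: giving that lever full duplex shear
stiffness creates spurious rotational modes near 8×10³ rad/ns whose only
effect is to cap the stable time step far below anything the junction's
real mechanics would demand. One scalar softening factor (10) keeps the
table honest about what is actually known — crossovers are substantially
softer — without inventing per-component numbers.

Adjacent helices are represented with parallel frames; antiparallel strand
routing is carried by the crossover topology, not by flipping frames (a
180°-twisted intrinsic geometry sits exactly on the mid-step bisector
degeneracy of the CEHS construction, where the kernel raises instead of
returning garbage).

## Forces

Elastic element forces are the exact negative gradients of the element
energy with respect to the twelve nodal coordinates, computed as follows:
the energy is differentiated by central differences (step 10⁻⁶ nm/rad) in
the six *relative-pose* coordinates (local displacement, left rotation
increment of the relative rotation), and mapped to nodal forces/torques by
the exact kinematic relations

    F_B = −R_A g_d,  F_A = −F_B,
    τ_B = −R_A g_ψ,  τ_A = −Δx × F_B − τ_B.

Newton's third law and zero net force/torque about any point therefore hold
to machine precision by construction; finite-difference error only
perturbs the magnitude of the (internal-coordinate) gradient, and the
gradient-consistency contract (forces vs central differences of the total
energy over the nodal coordinates, relative 10⁻⁵ over random states) is
enforced in the tests. The inner loop is a compiled (numba) kernel with a
bit-compatible numpy fallback.

Screened electrostatics reduces each node to a point charge q_eff = 2e ×
0.24 (counterion condensation) with Debye–Hückel energy E(r) = q_eff² l_B
k_BT exp(−κr)/r, Bjerrum length l_B = 0.714 nm, Debye length κ⁻¹ =
0.304/√I nm with the ionic strength I over Mg²⁺, Na⁺ and the balancing
Cl⁻, cutoff 3κ⁻¹, neighbour list with a 1 nm skin. Pairs joined by any
element are excluded. Changing the ion condition changes only this term.

Base stacking uses Π(r) = ε[1 − exp(−a(r−r₀))]² − ε with ε = 42.79 pN·nm,
a = 2.668 nm⁻¹, r₀ = 0.3742 nm, values fitted to a molecular-dynamics
potential of mean force of blunt-end stacking distances. A bond is reported
"stacked" when r < r₀ + ln2/a ≈ 0.634 nm — the maximum-force point of the
Morse curve, beyond which the contact yields. The per-bond stacking *free
energy* (42.2 pN·nm ≈ 6.07 kcal/mol) is a distinct reported number and is
kept separate from the fitted well depth ε. The PMF machinery treats the
stacking distance as a one-dimensional reaction coordinate (no 4πr² shell
factor): Π_PMF = −k_BT log g(r) from a histogram, empty bins masked, and
`fit_morse_to_pmf` does a count-weighted least-squares fit of the Morse
form plus an additive offset over the valid window.

## Hydrodynamics

The grand mobility Ξ is the generalized Rotne–Prager–Yamakawa operator for
identical spheres of hydrodynamic radius σ = 1.1 nm in water at η = 0.89
pN·ns/nm² (890 μN·s/m²), including rotation–rotation and
translation–rotation coupling blocks; overlapping spheres use the
regularized expressions, continuous at r = 2σ, and the operator remains
positive definite for every configuration (verified by Cholesky at each
assembly). The friction matrix is Z = Ξ⁻¹; the Cholesky factor of Ξ is
retained so random forces with covariance 2k_BT Z/Δt can be drawn by a
triangular solve. Rotational blocks are evaluated in the lab frame; the
single-sphere contracts D_t = k_BT/(6πησ) = 0.2245 nm²/ns and D_r =
k_BT/(8πησ³) = 0.139 rad²/ns pin the convention. Dense assembly and
factorization are used throughout (target sizes ≤ ~10⁴ nodes).

## Time integration

The Langevin equation M V̇ = F − ZV + R is integrated with a modified
Grønbech-Jensen–Farago (GJF) scheme. With A = M + (Δt/2)Z and s₁ = A⁻¹Mv,
s₂ = A⁻¹f(x), s₃ = A⁻¹β, where β is Gaussian with covariance 2k_BT Z Δt:

    Δu = Δt s₁ + (Δt²/2) s₂ + (Δt/2) s₃
    v' = (2s₁ − v) + (Δt/2)(2s₂ − M⁻¹f) + s₃ + (Δt/2) M⁻¹ f_eff

The modification is the treatment of the internal force in the velocity
update: a mid-step configuration is formed by applying half the coordinate
increment (half-time stepping), the force is evaluated at the start,
midpoint and end of the step, and the Simpson combination
S = (f + 4f_mid + f_new)/6 replaces the trapezoid average via
f_eff = 2S − f. The scheme has three hard contracts, all tested: (a) it
reduces exactly to published GJF when the force is constant over a step;
(b) for linear forces the interpolated midpoint makes S equal the
trapezoid, so the GJF property of exact Boltzmann configurational sampling
at any stable Δt is preserved (verified to <2% at Δt = 5 ps and 20 ps on
the thermal oscillator); (c) stability is that of GJF, ωΔt < 2 for the
stiffest harmonic mode. Rotations are updated multiplicatively in the lab
frame and quaternions renormalized each step; inertia is retained (not
overdamped Brownian dynamics), with the scheme stable deep in the
overdamped regime m/ζ ≈ 0.06 ps ≪ Δt.

**Choosing Δt.** The protocol default Δt = 5 ps is appropriate for soft or
heavy systems (the acceptance oscillator, free-node diffusion). For the
stiff default elasticity table the stiffest coupled step modes reach
ω ≈ 2.5×10³ rad/ns, so structure simulations here use Δt = 0.4–0.5 ps;
quantitative equilibrium statistics additionally carry an O(Δt²)
configurational bias from the rotational-manifold discretization (the
largest effect is a few percent on the twist variance at 0.5 ps), so runs
that assert distribution widths use Δt = 0.2 ps. These are accuracy
choices of this implementation, documented here so they can be revisited
if the element formulation changes.

Friction is refreshed from the current configuration every
`friction_update_interval` steps (default 1000; the switch protocol uses
4000), velocities are initialized Maxwell–Boltzmann (variance k_BT/Mᵢᵢ),
and every run is exactly reproducible from its seed.

## Analysis

RMSD/RMSF use least-squares (Kabsch) superposition; the RMSF reference is
the iteratively superposed mean. The overlap coefficient is the normalized
dot product of two RMSF profiles. Quasi-harmonic (PCA) analysis follows the
mass-weighted fluctuation matrix construction Σ = M^½σM^½ on superposed
position trajectories (positions only), with ω_i = (k_BT/Λ_i)^½ and mode
shapes M^−½φ_i; rigid-body/zero-variance modes are flagged, never
inverted. NMA differentiates the total internal force for K (central
differences over nodal coordinates) and solves Kφ = ω²Mφ in vacuum; a free
structure shows exactly six rigid modes, and PCA and NMA frequencies agree
on harmonic systems — the consistency contract used in the tests. The
Pearson map uses the 3-D vector convention (trace of the cross-covariance
over RMSF products); the generalized map is r_MI = √(1 − e^(−2I/3)) with a
Kraskov k-nearest-neighbour MI estimator (k = 6; Gaussian-copula fallback
for small samples). Step-parameter distributions aggregate the CEHS kernel
over frames and elements; angle observables (opening, interior vertex,
out-of-plane) come from least-squares axis fits through annotated node
sets.

## Desk-scale test structures

The parametric builders generate structures small enough to simulate in
minutes while exercising every mechanism:

- **duplex** — straight B-form helix; the equilibrium workhorse
  (equipartition, step-parameter statistics).
- **bundle** — parallel helices on a square/honeycomb lattice joined by
  crossovers every `crossover_spacing` bp (stress-free as built).
- **wireframe polygon** — 3/4/6 bundle edges joined by ssDNA vertex
  springs; checks ideal interior angles and planarity.
- **switch toy** — two rigid multi-helix arms facing across a 2.4 nm seam,
  hinged by six crossovers at one end, latched by Morse stacking bonds
  bridging the seam through short blunt-end tether nodes built at the
  Morse equilibrium distance (the as-built closed state is stress-free).
  Each arm is a single chain of bundle-slice nodes: a slice carries the
  mass and inertia of a 12-helix bundle cross-section and a composite
  stiffness (stretch/shear scaling with the helix count, bending/torsion
  with the parallel-axis composite ≈ count²/2), but only ~2 base pairs of
  effective seam charge, since deeper helix rows are screened out of the
  seam interaction. The default latch is distributed like the real
  device's: one bond at the arm tip plus a ladder of bonds climbing from
  the hinge, with a mid-arm rung bridging the gap. At low salt the
  electrostatic lever unzips the latch from the tip inward (the delayed
  stacking response) and the arms swing to an open branch near 10–15°;
  restoring high salt re-engages the ladder from the hinge outward, each
  captured bond pulling the next into its Morse capture range until the
  tip re-latches. Design features that turned out to be essential, not
  cosmetic: (i) arm rigidity — flexible arms bulge away from the seam and
  bank the electrostatic relief without ever loading the latch; (ii)
  full-stiffness tethers — a soft tether lets a broken blunt end dangle
  inside the Morse capture range and re-latch before the arms can move;
  (iii) the distributed ladder — a single distal bond can never be
  recaptured because its capture cone (≈1 nm over a ~21 nm lever) is
  narrower than the thermally-open high-salt resting angle. These failure
  modes were diagnosed by comparing rigid-rotation energy landscapes
  against zero-temperature descents and scissor-mode force projections;
  the static landscapes systematically overstate both drives because
  thermal wobble inflates the convex screened repulsion, so the final
  geometry was validated by direct simulation of the full salt protocol.

**What the toys do not show.** They are orders of magnitude smaller than
real origami designs, use the averaged elasticity table, ignore sequence,
and the switch seam/latch geometry is engineered rather than derived from
a strand routing. Passing tests demonstrate that the mechanics,
hydrodynamics, thermostat, stacking model and analysis chain are mutually
consistent and reproduce the governing physics at this scale — not that
any specific experimental structure is predicted quantitatively.

## Numerical details and edge cases

- Step-parameter kernel: bend angle via atan2 (stable near Γ = 0);
  antiparallel frames and 180° twist raise `StepGeometryError`.
- Static minimization: Barzilai–Borwein gradient steps with backtracking on
  the 6-DOF manifold (multiplicative rotation updates), default tolerance
  10⁻³ pN max-norm force residual; non-convergence reports the final
  residual (mutually repelling unconnected bodies are the canonical
  diagnostic case).
- Morse-bond Boltzmann checks sample the bond as a 1-D reaction coordinate
  with a reflecting wall at r₀ + 1.5 nm bounding the (otherwise
  non-normalizable) flat tail; the probability mass near the wall is
  ~10⁻⁴ of the well.
- Rotational diffusion is fitted over 0.15 ns so the finite-rotation
  saturation of ⟨|Δφ|²⟩ stays below the percent level.
- The friction refresh uses a Cholesky-diagonal condition estimate
  (error above 10¹²).
- PMF bins with zero counts are masked (NaN), never zero-filled; a fit is
  refused when no interior minimum with a left wall and right plateau
  exists.

## Known limitations

- The elasticity table is sequence-averaged; crossover softening is one
  scalar; base-pair breakage at crossovers is not modelled.
- The integrator's stability is that of GJF; it does not enlarge the
  stable time step for stiff elastic modes, so simulations of structures
  with the default table run at sub-picosecond Δt.
- Electrostatics is pairwise Debye–Hückel with condensed-counterion point
  charges; no Poisson–Boltzmann, no explicit ions, no salt-dependent
  stacking.
- The caDNAno importer reads the plain square/honeycomb dialect only;
  loops (insertions) and skips (deletions) are rejected.
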