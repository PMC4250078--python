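# Methods

## Local stress on a grid

The Cauchy stress is accumulated per voxel and frame from two contributions
and time-averaged. The **kinetic term** −mᵢ vᵢ⊗vᵢ of each particle is spread
onto its eight neighbouring voxels by cloud-in-cell (trilinear) weights. The
**potential term** f_ij⊗r_ij of each interacting pair (force on i from j,
r_ij = x_j − x_i under the minimum image) is spread along the i–j segment in
proportion to the segment length inside each voxel (a line-integral bond
function). Both weightings deposit unit total weight, which makes the
conservation identity

    Σ_vox σ_vox · V_vox = global virial stress

hold to machine precision for any grid spacing — this is the invariant the
test suite leans on, together with analytic oracles (ideal gas for the
kinetic term, a static stretched harmonic dimer for the potential term).

Sign convention is tension-positive: pressure = −tr σ/3; a stretched bond
contributes positive (tensile) σ_xx. Units are bar on the grid
(1 pN/nm² = 10 bar). Streaming velocities are assumed zero: all target
systems are equilibrium ensembles at rest in the mean, so raw velocities
enter the kinetic term. Multibody interactions are limited to three-body
harmonic angles, reduced to central pair forces by the exact three-body
central-force decomposition (solved per term in least squares; the residual
is zero for any zero-net-force, zero-net-torque triple away from collinear
geometry), which keeps every pair contribution a symmetric dyad.

The Gaussian filter interprets its *width* parameter as the kernel standard
deviation σ (in nm) and convolves each tensor component periodically;
width 0 is the identity and the volume integral of every component is
preserved exactly. Defaults: grid spacing 0.1 nm, stress filter width
0.8 nm, density filter width 0.2 nm. Electrostatics are out of scope — the
toy topologies are neutral by construction.

## Density isosurface and traction

The protein surface is the marching-cubes isocontour of the time-averaged,
filtered mass-density field of the protein selection. The default iso-level
is 50% of the mean interior density, "interior" meaning voxels above half
the field maximum; the level is exposed (absolute or relative) because no
principled universal choice exists. Vertex normals come from the analytic
gradient of the trilinear density interpolant, oriented along the negative
gradient (outward from the dense body); face winding is made consistent
with them.

Per vertex, σ is interpolated trilinearly from the (filtered) grid and the
traction decomposed: t = σ·n̂, t_n = t·n̂, t_t = t − t_n n̂. The surface
integral of the traction uses **per-face normals with the vertex-mean
stress** rather than averaged vertex normals: the vector area of a closed
triangulated surface telescopes to exactly zero, so a uniform stress
produces a net force at machine precision instead of mesh-resolution noise
— the divergence-theorem check then genuinely probes stress inhomogeneity,
not triangulation quality. Meshes export to legacy-VTK or ASCII PLY with
t, t_n and ‖t_t‖ as per-vertex fields; the writers print 17 significant
digits so a write→read round trip is lossless at double precision.

## Lipid-binding analysis

Hydrogen bonds use the common MD-analysis convention: donor–acceptor
distance ≤ 0.35 nm and H–donor–acceptor angle ≤ 30°. The coarse fixtures
carry no explicit hydrogens, so the census falls back to the distance-only
criterion (logged). A lipid is **tightly bound** iff (a) its H-bond
occupancy to any cytoplasmic lysine is ≥ 0.7 over the analysis window and
(b) one tail's terminal-segment centroid (last two tail beads) stays within
0.5 nm of a protein hydrophobic site for at least the same fraction of
frames; the inserted tail is the tail satisfying (b). Both thresholds are
configuration parameters; the defaults keep planted-recovery sensitivity
and specificity at 1.0 on the synthetic fixture.

Per-molecule volumes come from a grid-sampled radical (power) Voronoi
diagram: each sample of the box is assigned to the particle minimising
|x − xᵢ|² − rᵢ², with radii defaulting to half the Lennard-Jones σ where
declared. Sampling (default 0.02 nm, coarser in the bundled demos) was
chosen over an exact tessellation deliberately: assignment of every sample
exactly once makes volume conservation exact by construction and handles
radii and periodicity with simple, testable code. The k-nearest-neighbour
shortcut is made exact by a fallback ball query whenever the power bound of
the k-th candidate cannot exclude farther particles.

The FWHM estimator is a Scott's-rule Gaussian KDE evaluated as a fine
histogram smoothed with the kernel (identical to the direct kernel sum at
the grid resolution used, but O(n) instead of O(n·grid)); half-max
crossings are located by linear interpolation. On Gaussian input the KDE
bandwidth inflates the width by ≈ (1 + h²/σ²)^½ − 1, under 2% for n ≥ 10⁴.

Unbinding events on pulling traces are sudden sustained jumps: baseline =
median of the first 10% of the trace, event = first time the distance
exceeds baseline + 1.0 nm and stays above for ≥ 100 ps; shorter spikes are
ignored and traces that never sustain the jump are censored.

## Unbinding kinetics

Event times at each force give the empirical unbound fraction P_u(t)
(right-continuous; censored observations enter the at-risk denominator
only). The per-force rate is a least-squares fit of P_u(t) = 1 − e^(−kt) at
the event times with midpoint plotting positions (i − ½)/n; confidence
intervals come from a seeded bootstrap over events (1000 resamples by
default). The Bell parameters are then a weighted linear regression of
ln k on f — slope x_β/kT, intercept −ln τ₀ — with weights 1/se(ln k)².
Fitting in log-rate space instead of the rate law directly keeps the
problem convex and deterministic. The barrier is ΔG = ln(τ₀/τ_D) in kT,
evaluated at both ends of the attempt-time range (default 1–20 ps); the
interval width equals ln(τ_D,max/τ_D,min) identically. kT at 310.15 K is
fixed to 4.2821 pN·nm throughout the kinetics modules.

τ₀ is an extrapolation of the regression far outside the sampled force
range (530–1000 pN), so its estimate is intrinsically noisier than x_β:
at the default generator settings, x̂_β recovers within a few percent while
τ̂₀ scatters by tens of percent across seeds.

## Pulling-force geometry

Per lipid, the pull direction is the in-plane unit vector from the protein
centre of mass to the free-tail centre of mass. At polar angle θ the force
is F(cos θ · e_radial + sin θ · n̂_leaflet): θ = 0 is a purely lateral pull,
θ = 90° purely perpendicular, and the vertical component is F sin θ — the
convention under which the leaflet counterforce has magnitude n·F·sin θ
exactly. The counterforce cancels the summed vertical pull identically, and
any radially symmetric plan has zero net in-plane force.

## The synthetic-data generator

The generator produces the study conditions directly rather than
simulating them:

* **Oracles.** Ideal gas (uniform positions, Maxwell–Boltzmann velocities)
  pins the kinetic stress to −(NkT/V)·I; a static stretched dimer pins the
  potential stress to the closed-form virial dyad.
* **Fixture.** A coarse five-fold cylindrical "protein" (labelled lysine-N,
  polar-O, hydrophobic-cavity and pore-ring sites) surrounded by two
  leaflets of 50 coarse lipids. Planted truth: 10 tightly-bound lipids
  (2 per monomer) holding a P–N distance of N(0.4 nm, 11.04 pm) to an
  assigned lysine with one tail's terminal beads inside an assigned cavity
  (8 short / 2 long); a per-frame hydrogen-bond census of exactly 40
  cytoplasmic and 21 periplasmic lipids with 85% of the cytoplasmic bonds
  lysine-mediated; the remaining lipids random-walk at radius ≥ 3 nm,
  outside any bonding cutoff. The 11.04 pm spread makes the Gaussian FWHM
  equal 26 pm (FWHM = 2√(2 ln 2)·σ). Default window: 500 frames at 100 ps.
* **P–N traces.** Two-state telegraph processes: Gaussian about the median
  while bound, a reflected walk above a 0.6 nm floor while unbound, with a
  Markov chain tuned to the requested stationary occupancy.
* **Unbinding times.** Exponential draws from k(f) = (1/τ₀)e^{f·x_β/kT} at
  forces {530, 660, 830, 910, 1000} pN, 10 lipids × 5 replicates per force.
  Defaults τ₀ = 441 ns and x_β = 35 pm; 441 ns is the midpoint of the
  interval [20 ps·e¹⁰, 1 ps·e¹³] ≈ [440.5, 442.4] ns jointly consistent
  with a 10–13 kT barrier at 1–20 ps attempt times.

Because frames are constructed ensembles, not integrated dynamics, the
fixture has no thermal noise beyond what is injected, no lipid exchange
between the planted classes, no force-field physics and no correlation
structure in time (bound-state distances are i.i.d. per frame). Passing the
planted-recovery tests therefore demonstrates that the analysis chain is
correct and self-consistent — not that the classifier thresholds would
transfer unchanged to an atomistic trajectory, where occupancy is noisy,
classes mix, and the H-bond geometry involves real hydrogens.

## Numerical choices and degenerate inputs

* Grids tile the box exactly (spacing rounded to a divisor of each box
  length); voxel centres at (i + ½)·spacing, 0-based indices, periodic
  wrap everywhere, minimum image for all pair vectors.
* Zero-separation pairs, collinear angle terms, in-plane coincident
  centres of mass and out-of-range iso-levels raise typed errors; empty
  isosurfaces are explicit empty results and refuse export.
* Zero-area triangles (e.g. at a parametrised pole) carry zero normals and
  drop out of surface integrals.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  (configuration, seed) pairs give bit-identical outputs.
* Problem sizes in the bundled tests and the acceptance script (10³
  ideal-gas particles × 100 frames, 500-frame fixtures, 20 seeds, 5 × 10⁵
  pooled trace samples) are chosen so the whole suite runs on one CPU in a
  few minutes while keeping every statistical tolerance comfortably
  resolved.

## Known limitations

* No long-range electrostatics, no multibody terms beyond three-body
  angles, no thermostatted dynamics.
* The stress weighting functions are one concrete conservative choice
  (cloud-in-cell + line segment); other members of the family differ at
  sub-voxel scale while satisfying the same conservation identity.
* `lateral_tension` assumes a diagonal-dominated profile and only warns
  otherwise.
* The kinetics fits pool replicates at each force; per-replicate fitting
  would expose replicate-to-replicate variance but needs more events per
  replicate than the default protocol provides.
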