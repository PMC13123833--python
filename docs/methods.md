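# Methods

This note documents the models and algorithms implemented in `knotsol`,
the parameters that matter, the synthetic structures the test-suite runs
on, and the design decisions taken where more than one reasonable choice
existed.

## Knot typing of open chains

A protein backbone is an open curve, so its knot type is defined
probabilistically. `knotsol.knots.classify_open_chain` closes the C-alpha
trace many times (default 200): each terminus is first extended radially
along the centroid-to-terminus direction out to a sphere of radius
10 x (maximal centroid distance), and the two extensions are then joined
at a single point drawn uniformly on that sphere. The radial
pre-extension cannot sweep through the structure, so closure artifacts
are limited to genuinely ambiguous geometries; without it we measured the
closure "sliver" untying an open trefoil in ~15% of closures.

Each closed polygon is simplified by KMT triangle elimination (a vertex is
removed when no other segment passes through the triangle formed with its
neighbours; all tolerance decisions are conservative, i.e. in doubt the
vertex stays) and typed by two evaluations of the Alexander polynomial.
The determinant of the Alexander-matrix minor equals ±t^k Δ(t) with an
unknown monomial factor. |Δ(-1)| is free of it; |Δ(-2)| is recovered
through the palindromic symmetry Δ(1/t) = ±t^-deg Δ(t), which gives
|det M(-2)|·|det M(-1/2)| = Δ(-2)²/2^deg, matched against a fixed lookup
(unknot (1,1), 3_1 (3,7), 4_1 (5,11), 5_1 (5,31), 5_2 (7,16), 6_1 (9,20);
anything else reports "other"). Degenerate projections (near-tangent
crossings, ties in depth) are detected and re-drawn with a fresh random
rotation.

A chain is assigned the dominant closure type only when it wins more than
half of the closures (KnotProt-style convention); otherwise it reports
unknotted/ambiguous. Chirality comes from the sign of the mean projected
writhe of the dominant-type closures (threshold |mean writhe| >= 0.5; the
crossing-sign convention was validated against the Gauss linking
integral). The Alexander polynomial itself is mirror-blind.

The knot core is found by trimming residues one at a time from the
N-terminus until the dominant type is lost, then independently from the
C-terminus, re-using the same closure seed at every step; boundaries are
reported in author numbering. A knot is "deep" when both tails exceed 10
residues. Slipknots are detected on an (i, j) subchain grid (default step
5): the flag fires when the whole chain is unknotted but some subchain is
knotted.

## Synthetic structures

`knotsol.synthetic` generates every fixture the package is tested on.

*Parametric knots.* `make_torus_knot(p, q)` samples the (p, q) torus
curve uniformly in parameter, rescales to a 3.8 Å virtual bond, adds a
0.01 Å seeded jitter (the perfectly symmetric curve has degenerate
projections) and optionally removes trailing points to open the chain.
The standard parametrisation of the (2, 3) curve is the right-handed
trefoil (Gauss writhe +3.3).

*Ideal beta-solenoids.* Coils are planar polygons (`sides` x
`residues_per_side` residues, circumradius set by the 3.8 Å bond) stacked
along +z with an axial rise of 4.8 Å per coil. One rise is distributed
across each junction by a fixed intra-coil ramp (the last three residues
climb 0.1/0.3/0.5 of a rise, the first three descend mirror-wise), so
z(i + residues_per_coil) - z(i) is exactly one rise anywhere inside a
contiguous stack. The coil start angle is chosen so every coil crosses
the -y direction at its junction: the minima of the smoothed lateral
profile then fall on coil boundaries and minima-delimited segments
coincide with single coils.

The knotted variant uses the order-shifted level sequence (0, 1, 3, 2).
Three routing elements turned out to be essential for the closed chain to
be a trefoil (each was verified by classifying candidate routings):

1. the connector bridging the skipped level runs through the channel
   interior (0.6 x inradius), so the backtracked coil wraps around it;
2. the long linker leaves the top coil, orbits the outside of the barrel
   (radius +9 Å) in the coil winding direction while descending to the
   skipped level — its angular sweep is sized so `linker_length` residues
   trace it at ~3.5 Å per bond. The +9 Å stand-off matters for the
   folding model: a tighter orbit leaves a threading corridor narrower
   than twice the excluded-volume radius, making the native basin
   kinetically unreachable;
3. the C-terminal thread doubles back beneath the linker's landing,
   climbs between the wall and the orbiting linker — piercing the opening
   the linker frames — crosses over the rim and descends into the channel
   interior, capping it. Ending inside the channel makes the thread's
   native contacts unreachable without threading; with a radially exiting
   tail the folding model reached Q = 0.96 while unknotted, a perfect
   topological trap. Wrapping the tail further around the axis instead
   ties a 5_1, which the build-time validation rejects.

The raw routing traces a left-handed knot; the final coordinates are
mirrored so the generated trefoil is right-handed (+3_1). Connector,
linker and thread waypoints are Chaikin-smoothed and resampled at uniform
arclength, then a gentle bond-equalisation relaxation (coil residues held
fixed) pulls every virtual bond into 3.5-4.0 Å. Build-time validation
classifies the chain by stochastic closure and rejects the construction
unless it is a dominant right-handed 3_1 (the regular variant must
classify unknotted); self-intersections below 2.0 Å are rejected with a
diagnostic. Skip-and-backtrack routing supports the canonical four-coil
architecture; more coils would collide with the linker and raise a
RoutingError.

*Dimers.* The second copy is a 180-degree rotation about an axis parallel
(parallel mode) or perpendicular (antiparallel) to the solenoid axis,
then translated laterally until the nearest inter-copy C-alpha distance
equals `separation`. We read "separation" as the surface gap: a literal
centre offset of 10 Å would interpenetrate two ~13 Å barrels.

What the generator does *not* emulate: side chains, hydrogen-bond
geometry, sequence-dependent energetics, crystallographic disorder.
Passing tests on these fixtures demonstrates the analysis chain is
correct on idealised geometry; on real structures the same code paths run
but tolerate coordinate noise only as far as the stochastic-closure and
smoothing parameters allow.

## Coordinate profiles and the skip detector

For a given axis the profile is z (axial projection) and y (projection on
a deterministic perpendicular), each smoothed by centred moving averages
of window 6 then 3 with shrinking windows at the edges. Minima of the
smoothed lateral profile are strict local minima with plateau ties broken
leftmost; profile endpoints count as minima when the profile strictly
rises away from them (otherwise coils touching the chain ends lose their
boundary). Periodicity is the mean minima spacing.

The axis is found by scoring `n_orientations` random directions (plus the
principal inertia axis and the summed local-curvature normal) and
refining the best by Nelder-Mead. The score multiplies minima-spacing
regularity by the monotonicity of the smoothed axial profile — spacing
regularity alone cannot reject a tilted axis because any oblique
projection of circular winding stays periodic. The reported axis sign
makes the N-to-C displacement positive. We interpret the "200 random
placements" of the original profile protocol as this orientation search:
translations cannot change a profile's shape.

Coil segments are the residue stretches between successive minima;
`coil_mean_z` uses the central half of each segment (residues near the
boundaries belong to arcs and connectors and dilute the coil height).
The skip-and-backtrack detector fires when some coil-to-coil rise exceeds
1.85 x the median of the *other* positive rises AND a later rise is
negative. An ideal skipped level sits at exactly twice the regular rise
and segment boundaries push the measured ratio slightly below 2, so a
strict factor-2 threshold would never fire on an ideal construction; the
backtrack requirement alone silences monotone steep stacks, and the
1.85 threshold admits the ideal case while keeping regular solenoids and
4-sided pentapeptide-repeat-like fixtures silent.

## Interface analysis

Inter-chain contacts are all C-alpha pairs within 8 Å. Interface residues
are classified terminal (before the first / after the last coil) or
central. Hydrophobicity uses the eight Kyte-Doolittle-positive residues
(ALA, CYS, PHE, ILE, LEU, MET, VAL, TRP). Orientation takes the sign of
each chain's axis-projected N-to-C displacement (undetermined below 30%
of the displacement length). The composite knotted-solenoid-dimer rule is
a pure conjunction: both chains 3_1; parallel; hydrophobic interface
fraction >= 0.5; each chain's mean axial rise within 4.5-5.1 Å; more than
half of the interface contacts central; inter-copy RMSD after optimal
superposition <= 2 Å (the "symmetric dimer" operationalisation). The 0.5
thresholds are explicit stand-ins for what was originally a manual
inspection.

## The structure-based folding model

Reduced units: epsilon = 1, bead mass = 1, k_B = 1, lengths in Å.
Harmonic bonds (k = 100 eps/Å^2) and angles (k = 20 eps/rad^2) at native
values; dihedrals K[1-cos(phi-phi0)] + K/2[1-cos 3(phi-phi0)] with
K = 1 eps; native contacts use the Gaussian well

    G(r) = eps[(1 + (r_ex/r)^12)(1 - exp(-(r-r0)^2/2w^2)) - 1]

with r_ex = 4 Å, exactly -eps at the native distance; non-contact pairs
get the bare (r_ex/r)^12 repulsion (truncated and shifted at 2.5 r_ex).
Contact epsilons are uniform (1.0) with no chain-length rescaling.
Contact maps: the shadow map (6 Å atom cutoff, 1 Å shadowing radius,
atom pairs collapsed to residue pairs, intra-chain sequence separation
>= 4) for heavy-atom structures, or a C-alpha cutoff map (7.5 Å) for
backbone-only input such as the generated solenoids.

Dynamics is the impulse Langevin leap-frog: v' = e^(-gamma dt) v + F dt +
sqrt((1 - e^(-2 gamma dt)) k_B T) xi, x' = x + v' dt, with dt = 0.0005
tau and inverse friction 1.0 tau. With gamma = 0 and T = 0 the scheme
reduces to plain symplectic leap-frog (the validation mode for energy
conservation). Gaussian noise comes from numpy's generator in chunks, so
a run is fully determined by its seed. Excluded-volume pairs use a Verlet
neighbour list with a 4 Å skin rebuilt every chunk (per-step
displacements are ~10^-3 Å, so this is conservative by orders of
magnitude). Dimer runs add a soft spring between the two centres of mass
(force constant = bond constant x 0.00005, reference length = native COM
separation).

Observables: Q counts native contacts formed at r < 1.2 r0, reported per
chain and for the interface set; RMSD is per chain after optimal
superposition; the topology monitor re-classifies each sampled frame's
chains by stochastic closure (reduced closure count) and flags slipknots
on a coarse subchain grid. A chain counts as folded at Q > 0.8 and
knotted once 3_1 persists for 3 consecutive samples.

Free-energy surfaces come from temperature-WHAM: samples are binned
jointly over the order parameters and the potential energy, the density
of states is iterated to |Δf| < 1e-6 and re-weighted to the target
temperature; a single window short-circuits to the exact Boltzmann
inversion F = -k_B T ln P. 1D projections Boltzmann-sum the remaining
axes.

## Scaled-down folding campaigns

The folding-mechanism experiments run on the reduced knotted solenoid
(4 residues per side: 76 beads, ~213 contacts) with a widened contact
well (w = 1.5 Å instead of the 0.5 Å used for stability analysis): with
the narrow well an expanded chain almost never finds the native basin on
accessible timescales, while the widened well preserves the native
minimum and the -eps contact depth exactly. Unfolded, topologically
trivial starting conformations are harvested from a high-temperature
unfolding run (frames with Q < 0.2 that classify unknotted). The
campaign protocol first locates the model's own folding temperature by
scanning for the highest temperature at which the native state survives
a fixed observation window, then folds at a fixed fraction of it.
Trajectory counts and lengths are chosen to fit a single-CPU run; the
methods the campaign exercises (outcome taxonomy, first-passage times,
slipknot-before-knot ordering) do not depend on those sizes.

Knot formation by C-terminal threading is the slowest step of this
system's folding by a wide margin — trajectories reach a fully formed
solenoid body (chain Q ~ 0.8 of which the threading contacts are the
remainder) long before the tail pierces the linker opening. The
campaign therefore reports the folded-and-knotted fraction within its
time budget, and the slipknot flag is checked against the knot flag in
every successful run.

## Known limitations

- Absolute folding times in tau depend on every model constant and are
  not comparable across implementations; only orderings (e.g.
  interface-assisted folding faster than independent folding) are
  meaningful.
- The skip detector assumes at least two positive coil-to-coil rises; a
  two-coil fragment cannot fire it.
- Composite knots, links and lasso topologies are out of scope; the
  invariant lookup reports them as "other".
- The shadow map treats all heavy atoms as points; no per-element radii.

## Numerical notes

- The on-step kinetic energy reported with each frame is the product of
  the two half-step velocities (0.5 v(t-dt/2) v(t+dt/2)), which cancels
  the O((F dt)^2) bias of the naive average and makes the frictionless
  energy-conservation check clean.
- Straight beta-strand sides put native virtual angles near 180 degrees,
  where the harmonic angle force has a coordinate singularity; thermostated
  runs are unaffected in practice, but energy-conservation validation uses
  a curved fixture for this reason.
- The geometry report derives the coil repeat for the axial-rise
  measurement from the smallest of the first few lateral-minima spacings:
  the N-terminal coils of this fold family are regular, while the linker
  and the C-terminal thread distort later spacings.
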