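# Methods

This note records the models, defaults and numerical choices behind
`nanoreax`, and what the desk-scale setup does and does not demonstrate.

## Units and geometry

All quantities use one internal system: Å, fs, K, amu, kcal/mol, with
k_B = 0.0019872041 kcal/(mol·K) and 1 kcal/mol = 4.184×10⁻⁴ amu·Å²/fs².
Cells are orthorhombic (every protocol implemented here uses cubic boxes;
triclinic support is out of scope). All distances follow the minimum-image
convention. Neighbor searches dispatch to a cell-linked-list algorithm
above 200 atoms and a brute-force O(N²) scan below; the two paths are
required — and tested — to agree bitwise. Cutoffs larger than half the
shortest periodic edge raise by default; callers that understand the
consequences (descriptor sums and the toy potential in small boxes) opt
into minimum-image-only lists explicitly.

## Builders

The bootstrap seed library holds exactly nine molecules — C2, H2, N2, O2,
NH3, CH4, CO2, H2O, C2H2 — with idealized gas-phase geometries (tetrahedral
CH4, bent H2O at 104.5°, linear CO2 and C2H2, …). Geometries are fixture
data constrained by a 0.7–1.8 Å bonded-distance invariant, not fitted
values. CO, needed by the Miller-experiment mixture, lives in a separate
auxiliary table because it is not an active-learning seed.

**Random carbon boxes** insert atoms one at a time at uniform random
positions, accepting a proposal only if it keeps at least `min_distance`
(default twice the 1.7 Å carbon van der Waals radius) from every placed
atom. Pure sequential insertion saturates near an exclusion-sphere volume
fraction of ~0.38, while a 200-atom box at 0.5 g/cc with a 3.4 Å exclusion
needs ~0.52; when insertion stalls, the builder therefore places the
remaining atoms at random and opens space with an iterative pairwise
push-apart relaxation (reliable below random-close-packing; requests
beyond a volume fraction of 0.60 raise a feasibility error up front). The
distance guarantee is re-verified on the final configuration either way.

**Molecule packing** places rigid molecules with uniform random rotations
(unit-quaternion sampling) and translations, requiring every
inter-molecular atom pair to keep `min_separation` (default 2.0 Å), with
the same relaxation fallback operating on whole-molecule translations.
Initial packing above ~1 g/cc is geometrically infeasible under the 2 Å
rule, so random nanoreactor systems are packed at the density schedule's
starting value (kept at or below 1.0 g/cc by the default policy) and reach
condensed-phase densities dynamically through the schedule.

## Schedules

Temperature and density follow the same functional form — linear ramp plus
`amp·sin²(t/t_per)` with the argument in radians. Densities are clamped
below at 0.05 g/cc (near-gas-phase sampling is both unphysical to compress
toward and useless as training data). The default draw ranges (T start
300–3000 K, amp up to 1000 K; ρ start 0.3–1.0 g/cc, end up to 2.0 g/cc,
amp up to 0.5 g/cc; period scale 50–500 fs) are declared configuration
chosen to straddle typical reactive-MD conditions; they are not inferred
from any published table.

## MD engine

The integrator is the BAOAB splitting of Langevin dynamics at dt = 0.5 fs
by default; with zero friction and zero temperature it reduces *exactly*
(bitwise) to velocity Verlet, which is how the microcanonical tests pin it.
Friction is expressed in fs⁻¹, and the conventional protocol value "0.01"
is read as 0.01 fs⁻¹. Density programs are applied by an affine rescale of
cell and positions once per step before the force evaluation; fractional
coordinates are preserved exactly and velocities are left unscaled (the
thermostat re-equilibrates kinetic energy; a config toggle could rescale
them, default off). The nanoreactor driver monitors committee disagreement
every `monitor_interval` steps (default 25, the midpoint of the 5–50 step
convention; drawable per simulation) and ends the run at the first
threshold exceedance, returning the flagged configuration.

## Toy reactive potential (the desk labeler)

A pairwise Morse well per element pair, `D[(1−e^{−a(r−r0)})²−1]`,
multiplied by a cosine taper that takes energy and force smoothly to zero
at 4 Å. Equilibrium lengths roughly match the seed-molecule bonds (H–H
0.74, C–H 1.09, O–H 0.96, C–C 1.30 Å, …) — mismatched r0 values would put
every packed box on a steep wall and poison the learning problem — and
depths are plausible bond-energy magnitudes (60–110 kcal/mol). Because
every pair interacts through a bond-depth well, the toy chemistry is far
more reactive than any real system: molecules fuse on contact and release
tens of kcal/mol. That is intentional (it exercises the reactive
machinery), but it means raw toy MD needs gentle settings (dilute boxes,
dt ≤ 0.25 fs) to integrate stably for long runs, and the committee-driven
nanoreactor runs flag long before such events become violent. Atom pairs
closer than 0.1 Å raise a labeling error — the desk analogue of a
non-converged reference calculation — and batch labeling records such
failures per item without aborting.

## Descriptors

Atomic environments are ANI-style symmetry functions: element-resolved
radial terms `Σ exp(−η(r−R_s)²)f_c(r)` below a 5.2 Å cutoff and
element-pair-resolved angular terms
`2^{1−ζ}(1+cos(θ−θ_s))^ζ·exp(−η((r_ij+r_ik)/2−R_s)²)f_c f_c` below 3.5 Å,
with the angle computed as `arccos(0.95·cosθ)` so its gradient stays
finite at 0 and π (the TorchANI convention). The default radial grid is a
three-tier set — a dense narrow tier (η = 32 Å⁻², centers 0.45–1.45 Å)
that resolves repulsive walls and stiff bonded wells, a mid tier
(η = 12 Å⁻², 1.6–3.2 Å) and a broad tail tier (η = 6 Å⁻², 3.5–4.8 Å) —
with four angular sections; 104 features over the CHNO element set. The
short-range resolution matters: with a coarse grid, committee members fit
stiff wells with split-dependent compromises and their force disagreement
at the well bottom alone exceeds the selection threshold. Analytic
position-gradients of every term are assembled alongside the descriptor
matrix so forces are exact derivatives.

## Committee model and training

Each member maps descriptors to atomic energies through a feature map φ —
the identity by default ("linear"; random Fourier features are available
for nonlinearity — the committee architecture is shared across members, as
is usual for MLIP ensembles, so that disagreement reflects data rather
than architecture — and per-member feature maps can be enabled for
diversity studies) — followed by per-element linear weights. Forces are
analytic. Members ride on a fixed short-range repulsive prior (a C¹ inner
wall below 0.8× the covalent-radii sum, stiffness 200 kcal/mol): delta
learning on a physical baseline, standard practice for reactive MLIPs,
which keeps early-generation dynamics integrable where no data exists yet
and cancels exactly out of the committee disagreement.

Training uses the 16-block cross-validation scheme: member m validates on
block 2m, tests on block 2m+1, trains on the remaining 14 — eight members,
all splits distinct. The loss is per-atom-normalized energy MSE plus force
MSE (weights 1.0 and 0.2; force components carry most of the information
per structure), minimized by full-batch Adam with column whitening (an
exact reparametrization of the linear-in-weights model), gradient
clipping, a small ridge penalty in whitened coordinates (1e-3 — it keeps
weights of rarely-activated features bounded, which otherwise explode on
un-whitening), learning-rate annealing (×0.5 on a 60-epoch validation
plateau or every 150 epochs, whichever first) and convergence when the
learning rate drops below 1e-5. Structures with any force component beyond
300 kcal/mol/Å are held out of the fits — a single such outlier in one
member's training split destabilizes that member and its inflated
disagreement then dominates the committee — mirroring both force-capping
practice in MLIP training and the exclusion of non-converged reference
data. Per-element baseline energies are pre-fit by least squares on
compositions before gradient training. Warm-starting members from the
previous generation is available; the default retrains from scratch.

## Uncertainty and selection

ε_E is the population (÷M) standard deviation of member total energies
divided by √N; ε_F is the per-atom Euclidean norm of the per-component
member force standard deviation, *averaged* over atoms — the
atom-normalized convention of ensemble-disagreement selection in the ANI
family. (A max-over-atoms mode exists; with an eight-member desk committee
it sits permanently at the force-threshold scale for ordinary thermal
configurations, so the published threshold values are only meaningful with
the averaged metric.) Selection is strict exceedance of either threshold;
the final values are 1.85 kcal mol⁻¹ N^(−1/2) and 6.92 kcal mol⁻¹ Å⁻¹,
ramped linearly from 50% to 100% over the first six generations (later
generations tolerate more uncertainty, trading exploration for
exploitation).

## Active-learning campaign and the desk-scale conditions

One generation trains the committee, runs a batch of nanoreactor
simulations on freshly drawn systems and schedules, labels every flagged
configuration (label failures are recorded and skipped) and appends the
results. Convergence is a mean simulation time — flag time, or full length
for unflagged runs — reaching the configured target.

Bootstrap cells are packed with a per-cell separation drawn from 1.0–2.0 Å
and rattled by a 0.06 Å normal jitter before labeling. Both choices shape
the information content of the initial dataset: frozen template geometries
at a fixed 2 Å separation leave the thermal neighborhood of every bond and
the whole intermolecular approach region (1.3–1.9 Å) unsampled, and a
committee trained on such a measure-zero manifold flags every simulation
at the first monitored step forever.

The end-to-end test campaign runs 96 bootstrap cells of 14–24 atoms, six
1 ps simulations per generation for nine generations, with temperature
schedules starting at 300–900 K and ramping to 1500–3000 K. These sizes
are the package's scaled analogue of a production campaign (hundreds of
cells, ~100-atom boxes, up to 1 ns per simulation, dozens of iterations);
the learning signal at this scale is a severalfold growth of the mean
time-to-flag across generations, not full convergence to flag-free
sampling — covering CHNO reactive space takes orders of magnitude more
labeled data than a desk campaign collects.

## MolFind

Bond perception: atoms are bonded iff their minimum-image distance is
strictly below the sum of covalent radii plus a 0.02 Å buffer. Carbon's
radius is 0.85 Å, making the C–C cutoff exactly 1.72 Å; hydrogen uses the
classic 0.37 Å value (the smaller modern 0.31 Å radius would leave the
0.74 Å H–H bond unbonded); N and O use standard values, all configurable.
Species are connected components of the bond graph; canonical keys come
from Weisfeiler–Lehman label-refinement hashing with an exact isomorphism
check separating hash collisions, and carry a version prefix so censuses
from different releases are never silently compared. Rings are the
minimum cycle basis per component, tallied for sizes 3–7, with an optional
element filter (carbon-only for graphene-style analyses; heteroatom rings
count by default). The ignition delay time is the mean over CO, CO2 and
H2O of the first time each count reaches five molecules (NaN if any never
does); a replicate-mean helper aggregates over trajectories.

## Known limitations

* The toy labeler has no barriers between bonded states and no
  many-body terms; passing tests demonstrate the *machinery* (selection,
  labeling, retraining, analysis), not chemical accuracy of any potential.
* Linear members on a finite descriptor basis cannot represent genuinely
  many-body reference energies; they are exact in principle for the
  pairwise toy, which is the point of the desk pairing.
* Orthorhombic cells only; no barostat; energies carry no charge or spin
  information.
* The external-labeler adapter specifies the exchange format and the
  reference-engine settings but is exercised only against the toy
  potential in tests.
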