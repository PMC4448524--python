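# Methods

## Scope and data model

`crowdmd` analyzes trajectories of systems with several copies of the same
globular protein in a periodic cubic box.  The internal model is minimal:
a `Topology` (ordered atoms with chain, 1-based residue index, element,
mass, partial charge) and a `Trajectory` (frames × atoms × 3 in Å, strictly
increasing times in ns, optional cubic `box_edge`).  Multi-model PDB is the
mandatory trajectory dialect — MODEL/ENDMDL blocks are frames — because it
is text, diffable and bit-exactly testable; binary formats can be adapted
behind the same reader contract.  Charges enter only from PQR files or the
synthetic generator.  A plain PDB yields zero charges, and dipole-dependent
analyses then warn and emit NaN rather than silently producing zero-dipole
geometry.  When a trajectory carries no times, frames are spaced 0.1 ns
apart (configurable); this matches the sub-nanosecond granularity at which
encounter traces are usually inspected and is a package decision, not a
property of any input.

## Imaging conventions

Inter-chain center-of-mass distances use the minimum-image convention.
Intra-chain geometry (gyration radius, dipole vectors, superpositions) uses
whole-molecule coordinates: chains are kept whole across the periodic
boundary, which is the only convention under which Rg and μ are meaningful.
The synthetic generator therefore wraps *by chain COM* — the COM is always
inside [0, L)³ while atoms may protrude up to one molecular radius past a
box face.  COM time series are unwrapped (jump removal at L/2) before any
MSD analysis.

## Pair metrics

- **Contacts.** An inter-copy contact count at cutoff c (default 4 Å) is
  the number of heavy atoms of A within c of any heavy atom of B *plus* the
  symmetric B-side count — atoms, not atom pairs, each counted once.  A
  pair-counting variant exists for sensitivity checks.  Distances are
  KD-tree queries, periodic when a box is present; tests pin the
  implementation to a brute-force all-pairs oracle.
- **Per-residue profiles** attribute every counted atom to its residue and
  accumulate over frames and chain pairs (so the profile total equals the
  summed contact counts), then average over replicas.  Totals are reported
  together with a per-frame normalization column, since either convention
  is found in the literature.  The running residue average uses a centered
  5-residue window (odd, configurable; truncated at the termini) — the
  scale that visually smooths single-residue noise without erasing
  interface peaks.
- **Profile comparison** reports Pearson r plus a peak-overlap score: the
  Jaccard index of the residue sets above each profile's own 75th
  percentile.  Percentile-based peaks make the score insensitive to overall
  scaling between, e.g., simulation totals and crystallographic contact
  counts or NMR chemical-shift-perturbation profiles supplied as CSV.
- **Orientation angle** centers both copies on their mass-weighted COMs,
  finds the optimal rotation by Kabsch superposition (all heavy atoms by
  default; the selection is configurable) and reports its rotation angle in
  [0°, 180°].  Collinear or sub-3-atom selections are rejected as
  degenerate.

## Diffusion from MSD

MSD(τ) is computed with the FFT-based time-origin-averaged algorithm
(O(N log N)), requiring uniform frame spacing.  D is the slope/6 of a
least-squares line on a lag window.  The time-averaged MSD of a single
finite trajectory carries relative noise that grows roughly as √(τ/T), so
long lags are useless for fitting: the default window spans **0.5–5 % of
the analyzed span** (falling back to 1–10 % when that window holds fewer
than 10 lag points), and `msd_diffusion` accepts several COM series at
once, averaging their MSD curves before the fit.  Pooling the three copies
of the default study box across three generator seeds (9 walks of 10⁴
steps) recovers the input D within a few percent; a single walk can be off
by 20 % or more at any window choice, which is a property of Brownian
statistics, not of the estimator.  A negative fitted slope clamps D to 0
with a warning.  D is reported per chain; a population of chains/replicas
is summarized by its range, not a single number.

## Events and oligomer states

A pair is *bound* when its contact count stays ≥ `c_on` (default 10 atoms)
for at least the persistence time (default 5 ns); binding *completes* at
the first frame where the COM distance is within 10 % of the configured
gyration diameter (compact-dimer criterion) or where the rolling-mean
contact count changes by < 5 % over a persistence window (plateau
criterion).  Unbinding requires contacts ≤ `c_off` (default 0) sustained
for the same persistence, so events alternate bind/unbind by construction.
Bound pairs show contact plateaus of order 10² atoms, so 10 atoms is a
conservative onset threshold; all three thresholds are configuration
values, and verbal event timings read off plots in the literature depend on
exactly such thresholds.

Per-frame oligomeric state is the connected-component partition of the
chain graph with edges where pairwise contacts ≥ 1 atom.  Three-chain
components are split by edge count: 2 edges = linear trimer (middle chain
bridges), 3 edges = compact trimer.  The state timeline also reports a
transition-count matrix between whole-frame state labels, which makes
claims like "compact trimers never revert to linear ones" directly
checkable.

## Dipole electrostatics

The scalar continuum form `E = μₐμ_b(1 − 3cos²θ)/(4πε₀ D r³)` with a single
inter-dipole angle θ and water dielectric D = 78, and the radial force
magnitude `|F| = |dE/dr| = 3|E|/r`, converted to pN per molecule.  All
quantities are per molecule; molar forms (a factor N_A applied and later
removed) cancel exactly and are never exposed.  The two dipole magnitudes
may differ; equal magnitudes reproduce the single-|μ|² special case.
Constants (e, ε₀, N_A, k_B, 1 D = 3.33564×10⁻³⁰ C·m) live in one table
(`constants.py`).

Limitations worth knowing: the single-angle scalar form is an approximation
of the full two-angle dipole interaction tensor — it changes sign at the
magic angle (54.74°), so a 70° geometry evaluates as repulsive in this form
even when the full tensor for the actual vector geometry would attract.
The package reports magnitude plus an attractive/repulsive flag and leaves
tensor electrostatics out of scope.

`arrhenius_timescale` converts a barrier ΔG (kcal/mol) at temperature T
into τ = exp(ΔG/RT)/k₀ with a default attempt frequency k₀ = 1 µs⁻¹ — the
standard order of magnitude for protein–protein dissociation attempts.

## PCA landscapes

The reference frame is a PCA of the covariance of flattened Cα coordinates
over a user-supplied structural ensemble, default residue range 2–70 (the
ordered core of a ubiquitin-sized protein, excluding the mobile tail).
Members are iteratively superposed on the *running mean* (converged at
mean shift < 10⁻⁶ Å, ≤ 10 iterations) rather than on any single member, so
the frame has no input-order dependence.  Snapshots are superposed onto the
mean and dotted with the leading eigenvectors; projections are exactly
invariant to rigid transforms of the input.  The landscape is a 2D
histogram (default 40×40 bins over the padded data range) valued
`−k_BT ln(Nᵢ/N₀)` in kcal/mol with N₀ the maximum count: the most populated
bin(s) sit at exactly 0, empty bins are masked.  Serialized frames keep the
full eigenvalue spectrum but only the leading eigenvectors (10 by default).

The curated ensemble of crystal structures that a real study would use for
this frame is not shipped and its composition is a user decision; tests and
drivers use synthetic ensembles built by displacing the template Cα set
along random orthonormal modes with chosen variances, whose PCA fractions
are known by construction.

## Synthetic generator

`make_template` builds a deterministic compact pseudo-protein: 70 residues
on a golden-angle spherical spiral (radius ∝ n^(1/3), constant density), 8
heavy atoms + 2 hydrogens per residue (560 heavy atoms), gyration diameter
≈ 23 Å — i.e. ubiquitin-sized.  Backbone N/+q, O/−q charges are neutral per
residue, held in a fixed lab orientation so per-residue dipoles add
coherently, and scaled once so the total dipole hits the target (default
250 D, the middle of the 200–300 D range typical of such proteins).

`generate` runs overdamped rigid-body dynamics: per 0.1 ns step each free
copy translates by Gaussian steps of variance 2·D_trans·dt per axis
(default D_trans = 3×10⁻¹¹ m²/s) and rotates by a Gaussian rotation vector
of variance 2·D_rot·dt per component (default 4×10⁷ rad²/s, ~4 ns
tumbling).  Initial placement resamples until all COM pairs are ≥ 30 Å
apart (error after 10³ tries).  Scripted pairs switch at their scheduled
time to a deterministic mutual approach (default 1 Å/ns closing speed) and
are *docked* once ≥ 30 heavy atoms are in 4 Å contact; docked groups then
diffuse as one rigid unit without internal rotation, and an approach
involving an already-docked copy drags its whole group.  The ground-truth
sidecar records the input D values, dipole, seed and the scheduled and
realized (dock) event times.

What the generator does **not** emulate: internal flexibility, forces
(beyond the scripted approach), hydration, realistic binding energetics or
interface specificity.  Consequences for interpreting green tests: event
detection, diffusion recovery and oligomer bookkeeping are validated
end-to-end, but docking orientation is random — replica contact profiles
therefore *decorrelate* between seeds (the replica-comparison driver
reports low Pearson r), unlike real trajectories where an energetic
preference concentrates contacts on specific residues.  Profile
*machinery* is validated by construction-based tests, not by synthetic
replica agreement.

## Numerical choices and degenerate inputs

- Kabsch superposition via quaternion-free SVD (`scipy`'s
  `Rotation.align_vectors`); test oracles use an independent Kearsley
  quaternion implementation.
- Dipole reference point is the coordinate centroid; for neutral systems
  the dipole is reference-independent (tested), for |Σq| > 0.01 e a warning
  flags origin dependence.
- Degenerate PCA ensembles (all members identical) and collinear
  superposition inputs raise instead of returning noise-driven axes.
- Contact counting at exactly the cutoff distance is inclusive (≤ c).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  trajectories and byte-identical pipeline outputs.

## Problem sizes

Default driver/test sizes — 3 copies, 35–70-residue templates, 250–600
frames, 10⁴-step diffusion runs on reduced templates — were chosen so the
full suite and every driver run in well under a minute each on one CPU
while leaving all estimators in their asymptotic regime (hundreds of
residues and thousands of frames change nothing structurally; they only
scale linearly).
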