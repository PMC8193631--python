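# Methods

This note documents the models, estimators and numerical choices behind
`dnanchor`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reasonable choice
existed.

## Units and conventions

Lengths are Å, times ns, forces pN throughout; work is reported both in
pN·Å and kcal/mol using 1 kcal/(mol·Å) = 69.479 pN. Atom indices are
0-based internally; residue numbers are 1-based (PDB convention). All Z
coordinates used by the anchoring and membrane metrics are relative to
the *instantaneous* bilayer midplane, so the membrane center sits at
Z = 0 by construction.

## Data model and I/O

Structures (PDB) and trajectories (DCD, XTC) are read and written
through MDAnalysis; the package keeps its own minimal containers
(`Topology`, `TrajectorySet`) so that analyses are plain vectorized
numpy over an (n_frames, n_atoms, 3) array. A line-by-line pre-scan of
PDB ATOM records produces parse errors that name the offending line and
catches duplicate atom serials; DCD truncation is detected by comparing
the frame count promised in the header (NSET) with the frames actually
readable. DCD round-trips coordinates at float32 precision (~1e-5 Å
relative), XTC at its fixed 0.001 nm precision (0.01 Å): tests assert
round-trip fidelity at these documented levels, not exact equality.

Selections use a deliberately small grammar — `name`, `resname`,
`resid` (single values or `i:j` ranges), `chain`, `element`, combined
with `and`/`or`/`not` and parentheses — rather than a full MD-package
selection language. The subset covers every selection the analyses need
(belt nucleotides, whole DNA, lipid C2 atoms, water oxygens, terminal
base pairs) and is simple enough to be exhaustively testable.

## Synthetic systems

The generator produces systems with *known ground truth*, not
physically realistic ones. What it emulates, and what it does not:

* **Duplex** (`gen_bdna`): a fiber-model helix of coarse proxy
  nucleotides (three atoms each: backbone P at radius 9.4 Å, C1′ at
  5.2 Å, and one Watson–Crick proxy nitrogen at 1.4 Å from the pair
  center, N1 on the purine strand and N3 on the pyrimidine strand).
  Consecutive base-pair centers are spaced by exactly the requested
  rise (default 3.32 Å) with a fixed twist (default 36°/step); the two
  C1′ atoms of a pair are diametrically opposed so their midpoint lies
  exactly on the helix axis. An intact pair has an N1–N3 distance of
  2.8 Å, a typical heavy-atom hydrogen-bond length. No sequence
  dependence, grooves, sugar pucker or backbone connectivity is
  modeled; downstream metrics only need pair centers and the
  donor–acceptor pair, and all-atom inputs reach the same code via
  selections.
* **Fraying** (`fray_terminal_bps`): the chain-B residue of each
  affected terminal pair is translated along its pair-opening direction
  so the donor–acceptor distance becomes exactly 2.8 Å + displacement —
  strictly monotone in the displacement, which the broken-pair
  monotonicity test exploits.
* **Bilayer** (`gen_bilayer`): one C2 atom per lipid on two planes at
  z = ±19 Å with independent per-frame Gaussian z-noise (default SD
  1 Å), uniformly random in xy. An optional thinning disk moves both
  planes inward by δz inside a lateral radius, which reproduces—as a
  constructed ordering, not a physical prediction—membrane thinning
  near an embedded DNA. No lipid packing, tails, tilt or area
  constraints.
* **Water slab** (`gen_water_slab`): exactly n_inside oxygens with
  |z| < half-width and n_outside beyond it, with a 0.5 Å margin so no
  atom sits within rounding distance of the boundary; slab counts are
  therefore exact by construction.
* **Anchored trajectory** (`gen_anchored_trajectory`): the duplex is
  translated rigidly along z so that its belt-segment mass-weighted
  CoM follows the exact discrete Ornstein–Uhlenbeck update
  Z(t+dt) = μ + (Z(t) − μ)e^(−dt/τ) + N(0, σ²(1 − e^(−2dt/τ))),
  with Z(0) drawn from the stationary law (no burn-in bias). The OU
  process was chosen because the anchoring analysis only constrains the
  stationary distribution's SD; OU is the simplest stationary Gaussian
  process that adds a realistic correlation time. The default
  relaxation time is 1 ns — nanosecond-scale decorrelation is what one
  expects for the CoM of a lipid-anchored segment, and it leaves a 1 µs
  trajectory with ~400 effective samples, enough statistical power for
  percent-level SD recovery. The default trajectory is 1 µs at
  20 ps/frame (50 000 frames); the frame interval is a free choice
  exposed in the config, as production MD frame-saving intervals vary.
  All draws come from a single seeded generator, so trajectories are
  bit-reproducible.
* **SMD records** (`gen_smd_record`): z(t) = z_start + v·t on an exact
  uniform grid including both endpoints, with force profiles (constant,
  linear, Gaussian barrier) whose work integrals have closed forms —
  the oracle for the trapezoidal integrator.

Passing tests on these systems demonstrate that the *estimators* are
correct (they recover known ground truth, respect invariances, and
handle degenerate inputs); they do not demonstrate anything about the
physics of real membrane-DNA systems.

## Anchoring analysis

`com_z_trace` computes the mass-weighted CoM Z of a selection per frame
(masses from an element table, 1.0 for unknown elements), unwraps the
selection along z by the minimum-image convention about its first atom
before averaging, and subtracts the instantaneous midplane.
`block_average` takes non-overlapping block means (default 20 ns),
stamps them at block centers, and drops a trailing partial block; a
block is complete when the sampled span (last − first time + one frame
interval) covers it.

`fit_gaussian` discards the first 200 ns, histograms the remainder in
fixed 0.2 Å bins aligned to multiples of the bin width, and fits
A·exp(−(z−μ)²/2σ²) to the raw counts by unweighted nonlinear least
squares (scipy `curve_fit`, moment-based initial guesses, |σ|
reported). Requirements: ≥ 100 analyzed frames and non-degenerate
variance. The raw sample SD is reported next to the fitted σ: for
unimodal, weakly correlated data the two agree within a few percent,
while heavily correlated traces (relaxation time ≫ frame interval, few
effective samples) can show >10 % disagreement because the lumpy
histogram pulls the least-squares fit — the pair is a useful
convergence diagnostic. Whether one quotes the fitted σ or the sample
SD is ambiguous in common practice, which is exactly why both appear
in every output.

`escape_time` returns the start of the first excursion with
|Z| > threshold lasting at least the dwell time (defaults: leaflet
position + 10 Å, 10 ns — no standard criterion exists, so both are
config-exposed; an excursion running to the end of the trace counts
only the observed duration).

## DNA structure analysis

Rise is the Euclidean distance between consecutive base-pair centers,
each center being the midpoint of the paired C1′ atoms. This is
deliberately simpler than a 3DNA-style helical-frame rise: the two
coincide on ideal helices (where the package's generator/analyzer
self-consistency oracle demands agreement to 1e-6 Å), and the simple
definition stays well defined on strongly distorted or frayed duplexes
where a local helical frame is ill-conditioned. It is exactly rotation-
and translation-invariant.

A pair is broken in a frame iff its Watson–Crick donor–acceptor proxy
distance (purine N1 to pyrimidine N3) exceeds 4.5 Å. The cutoff is a
judgment call documented here: heavy-atom hydrogen-bond distances are
2.8–3.0 Å, and the extra ~1.5 Å absorbs thermal fluctuation without
flagging intact pairs; it is config-exposed. Counts are raw per-frame
values — no hysteresis or smoothing — and can be block-averaged with
the same machinery as the Z trace. Analysis windows: all pairs, the
last k pairs (`terminal:k`), or any explicit pair-index set.

## Membrane analysis

The midplane of a frame is the midpoint of the two leaflets' mean C2 z
positions, leaflets being partitioned by the sign of z after centering
on the global C2 mean. (The alternative — midpoint of the density
peaks — differs negligibly on synthetic data; the mean-based definition
is smooth in the atom positions and needs no histogram.)

Local thickness: per frame, C2 atoms whose minimum lateral (xy,
minimum-image) distance to any DNA atom is ≤ 15 Å contribute their
midplane-relative z to per-leaflet histograms (0.5 Å bins); after
frame-averaging, each leaflet's peak is the argmax after a 3-bin
moving-average smoothing, and thickness is the peak separation. Ties in
the smoothed maximum (which arise when the density is a spike narrower
than the kernel) are broken by the raw density, then by closeness to
the leaflet's mean z. Beyond-cutoff atoms give a bulk profile for
comparison. With 0.5 Å bins the noise-free constructed systems give
exact expected thicknesses (38.0 Å bulk, 28.0 Å inside a 5 Å-thinned
disk); on noisy data the peak is quantized to the bin width, which is
the dominant uncertainty.

Water penetration: waters are counted by their oxygen atoms within
10 Å of the instantaneous midplane (instantaneous rather than
trajectory-averaged — the choice matters only when the membrane
drifts); the mean is over frames after the 200 ns discard and the
quoted SD is the population SD over 2 ns block means.

## SMD analysis

Records are TSV (time_ns, z_A, force_pN) with strictly increasing
times; force is positive away from the membrane. `bin_force` averages
samples in contiguous 2 Å bins aligned to multiples of the bin width
(half-open [edge, edge+bin)); empty bins are dropped rather than
reported as zero force. `work_curve` integrates W(z) = ∫F dz by the
cumulative trapezoidal rule over the *CoM z* coordinate (the quantity
plotted against z, not against the pulling-template position — the two
differ when the spring stretches). A constant-velocity pull's z should
be monotone up to thermal noise: non-monotone records are re-checked
after a 1 ns moving-average smoothing and rejected if still
backtracking, since work against a backtracking coordinate is
ambiguous. Trapezoidal work matches closed-form integrals to ≤ 0.1 %
at ≥ 1000 samples (exactly, for affine force profiles).

`rank_constructs` orders curves by total work (largest = rank 1), with
exact ties broken by the work at the midpoint of the common z range and
remaining ties sharing a rank. Ranking is qualitative by design:
constant-velocity pulling work exceeds equilibrium free-energy
differences, so only the ordering, not the magnitudes, carries meaning.

## Pipeline

One YAML config drives a run; every tunable defaults to the standard
protocol value (20 ns blocks, 0.2 Å histogram bins, 200 ns discard,
15 Å near-DNA cutoff, 10 Å water half-width, 2 Å force bins, 2 ns SD
blocks, 0.5 Å/ns velocity). Outputs are per-metric TSV files plus a
`report.json` whose provenance block (config echo + hash, seed,
package and numpy versions) suffices to reproduce all numbers exactly.
`combine_reports` refuses to tabulate runs whose analysis tunables
differ, because cross-construct comparisons (e.g. of fitted σ) are
meaningful only under identical protocols.

## Problem sizes and statistical expectations

The validation suite uses 1 µs / 50 000-frame synthetic trajectories
for the anchoring-SD recovery checks (the full-size protocol) and
hundreds-of-frame systems elsewhere; the whole suite runs in about half
a minute on one CPU. For an OU trace of length T with relaxation time
τ, the SD estimate carries a relative standard error of roughly
1/√(T/τ), i.e. ~7 % per 1 µs trajectory at τ = 5 ns; recovery checks
therefore average the fitted σ over 5 (or 10) seeded replicates, which
brings the Monte-Carlo error of the mean to the few-percent level that
the assertions test. The estimate's small negative bias from serial
correlation (≈ τ/T, well under 1 %) is left uncorrected.

## Known limitations

* The proxy duplex cannot exercise atom-name conventions of specific
  force fields; users of real data must supply selections that resolve
  C1′ and N1/N3 (or adapt the pairing table).
* Thickness is a 1-D density-peak measure; no 2-D thickness maps,
  order parameters or pore detection.
* The broken-pair criterion is a single heavy-atom distance, not a
  hydrogen-bond enumeration with geometry.
* `rank_constructs` compares single pulls; no multi-replica work
  averaging or Jarzynski-style free-energy estimation.
* Escape detection is threshold-based and reports only the first
  qualifying excursion.
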