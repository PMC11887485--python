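# Methods

## Optical response quantification

A plate well holds one baseline spectrum (F₀, read before analyte
addition) and timed reads after addition; the 30 min read is used as F
by default (configurable). Blank wells (buffer + vehicle) are averaged
per plate and subtracted pointwise from baseline and timed reads;
negative intensities after subtraction are kept, since clipping would
bias integrals. Spectra are integrated trapezoidally, either over the
full grid or restricted to one chirality's emission window, and the
response is ΔF/F = (F − F₀)/F₀. Replicates (n = 3 wells) are aggregated
as the mean of per-well ΔF/F; normalization divides by the same plate's
dopamine mean, so the reference is exactly 1.00. A ratio-of-means
aggregation (mean F over mean F₀) is available as an option; for
noise-free data the two coincide.

Response categories relative to dopamine: I ≥ 1.00, II [0.75, 1.00),
III [0.15, 0.50], IV < 0.10. The intervals (0.10, 0.15) and
(0.50, 0.75) are not covered by any category definition; values there
return `unassigned` rather than silently extending a bin, so the
ambiguity stays visible downstream.

Because no wavelength window for the (9,4) emission is fixed by the
assay description, the window is a configuration value; the synthetic
generator's default places the (9,4) Gaussian at 1101 nm with a
±4σ window of 1053–1149 nm.

## Structure–activity statistics

Pearson r is computed with the two-sided p from the t transform plus
the least-squares line. Joins between response and descriptor tables
are on analyte id; records missing a descriptor are dropped pairwise
and counted (`n_dropped`), not imputed — the analyses operate on
overlapping compound subsets. The unpaired t test defaults to Student's
equal-variance form with Welch available by flag. No multiple-testing
correction is applied by default. The response heuristic — vicinal
hydrogen-bond donors on a π-conjugated scaffold — is implemented as a
boolean necessary-condition rule and documented as not sufficient.

## pH / microspecies model

Each ionizable site follows Henderson–Hasselbalch; a molecule's 2^k
microstates get the product of per-site protonated/deprotonated
fractions (independent-site approximation; site coupling is not
modelled, and pKa values are inputs, not predictions). Fractions sum to
1 at every grid point by construction; a guard rejects k > 12. The
default pH grid is 2–13 in 0.1 steps, matching the experimental range.
The overlay statistic correlates measured ΔF (not ΔF/F, matching how
the pH comparison is presented; ΔF/F by flag) against a selected
microspecies curve interpolated to the measured pH values. This
correlation is an explicit operationalization of a comparison that was
originally visual.

## SASA and contact areas

Shrake–Rupley SASA with golden-spiral sphere points (default 256 for
trajectory series, more for oracle-grade checks; < 32 rejected). The
default radii convention adds a 1.4 Å probe to Bondi per-element radii;
a strict-literal mode (all radii 1.4 Å, probe 0) is exposed for
comparison with tools that treat 1.4 Å as the atomic radius itself —
the literal reading would make carbon smaller than water, so it is not
the default. SASA of a selection is computed **in isolation** (only the
selection's own atoms occlude); under that convention
(s_A + s_B − s_AB)/2 is the standard buried interface area. Tiny
negative residues are clipped to zero, and overlapping selections are
rejected.

Per-frame contact series exploit rigidity: when the target
(nanotube/corona) does not move across frames, its per-atom SASA is
cached and only atoms within occlusion range of the analyte are
recomputed each frame, with their own target neighbors as occluding
context. The decomposition is exact (validated against the direct
union computation to 1e-13) and makes 10⁴-frame series tractable on
one core.

## Binding metrics

* **Bound percentage**: frames with contact area > 1 Å² (a proximity
  criterion — the analyte is at the conjugate rather than in bulk),
  per molecule and pooled.
* **Events**: maximal runs of frames with contact > 30 Å²; for
  molecules carrying amine/ammonium groups the group COM must also be
  within 10.5 Å of the nanotube surface. Predicates are strictly
  frame-wise (one failing frame ends an event); an optional gap
  tolerance exists but defaults to 0, since any smoothing window would
  be an undocumented parameter.
* **Residence time**: mean event duration pooled over the six
  molecules, τ_R = Σ tᵢnᵢ / Σ nⱼ = 1/k_off. Durations are counted as
  (run length × dt), so estimates are quantized by the frame interval
  and all time-dependent checks are expressed in frames × dt.
* **Surface distances**: d = (perpendicular distance to the fitted
  axis) − r, with the axis from the principal component of the
  (unwrapped) nanotube coordinates and r the mean perpendicular
  distance. Stacking distance averages the aryl-ring COM distance over
  frames within 10 Å (distance-only criterion), then over molecules; a
  molecule with no qualifying frame is undefined (NaN), distinct
  from 0.
* **Polar-group distributions**: normalized histograms (0.1 Å bins) of
  group-COM surface distances at ≤ 10.0 Å (closed bound); the area
  under the curve below 4.0 Å summarizes close interaction, summed over
  groups when a molecule has several of one class.
* **g(r)**: minimum-image pair histogram normalized by ideal-gas shell
  counts at the B-set box density; self-pairs are excluded when the
  sets overlap.
* **Hydrogen bonds**: D···A ≤ 3.5 Å and D–H···A angle within 30° of
  linear, per frame, from explicit (D, H) donor pairs.
* **Binding modes**: per-frame states from explicit thresholds
  (contact > 30 Å² "in contact", aryl COM < 5 Å "stacking",
  ammonium COM beyond a 6 Å DNA-shell distance for insertion), with the
  molecule's mode the state above 50 % of bound frames; an even
  DNA/nanotube stacking split is "both", other splits "mixed", never
  bound "unbound". The original assignment was by visual inspection;
  this classifier is an operationalization validated against synthetic
  ground truth only.

## Synthetic world

The generator is kinematic, not physical: positions are sampled
conditional on a per-molecule Markov state, because the analysis layer
consumes only geometry. The scaffold is a rigid (9,4) cylinder lattice
(radius from the roll-up closed form, 40 Å long, atom spacing chosen to
approximate the graphene areal density) plus three helical strands of
backbone pseudo-atoms (tags P, O1P, O2P, O3', O4', O5'; 3.3 Å above the
wall, near-axial pitch so that exposed wall lanes exist between
strands). Six analyte molecules carry a hexagonal aryl ring, two
vicinal hydroxy pseudo-atoms and an amine/ammonium pseudo-atom.

States place the molecule as follows: `free` — uniform in the box at
≥ 12 Å from the wall; `stack_swcnt` — aryl COM at N(3.4, 0.2) Å above
the wall in a lane between strands; `stack_dna` — atop a strand at the
DNA shell + 3.2 Å; `inserted` — aryl on the wall beneath a strand with
the ammonium pushed beyond the shell. An anchor (azimuth, axial
position) is redrawn on each state entry and jittered within an event,
so events are spatially coherent. The discrete chain uses
p = rate × dt and rejects dt × (fastest exit rate) > 0.1. Defaults
mirror the study conditions (10⁵ frames at dt = 0.06 ns ≈ 6 μs; six
molecules; (9,4) tube; three strands); tests and the acceptance script
use smaller budgets (≤ 9 × 10³ frames, chosen to still pool ≥ 10³
binding events for estimator checks) with dt = 1 frame, since all
estimators are expressed in frames × dt.

What the generator does **not** emulate: solvent and force-field
energetics, DNA conformational dynamics, diffusive approach paths
(free positions are resampled independently each frame), rotational
correlation, and state-dependent spectroscopy. Passing tests therefore
demonstrate estimator correctness (segmentation, averaging,
normalization, geometry) — not that the estimators are robust to the
noise structure of real MD or real plate data.

## Numerical choices

* Trapezoidal spectral integration on the native grid; integration
  windows are closed intervals of grid points.
* Golden-spiral Shrake–Rupley points; the isolated-sphere case is exact
  by construction.
* Cylinder fitting requires the principal eigenvalue to be at least
  twice the next (otherwise the cloud is declared degenerate).
* Histogram conventions: left-closed bins via `np.histogram`; the
  distance-distribution upper bound 10.0 Å is included by filtering
  before binning.
* Classification thresholds are compared with IEEE floating-point
  semantics; boundary values (1.00, 0.75, 0.15, 0.50) belong to the
  categories as printed, and 0.10 falls in the unassigned gap.
* Seeds: every generator takes an explicit seed; sub-seeds are drawn
  from `numpy.random.default_rng(seed)` below 2³¹.

## Known limitations

* The independent-site microspecies model ignores pKa coupling between
  sites of one molecule.
* The binding-mode classifier's thresholds are config values with no
  experimental calibration; only synthetic round trips validate them.
* Residence times are biased slightly downward by events truncated at
  trajectory boundaries; at the tested budgets (events ≈ 25 frames,
  runs ≥ 2 × 10³ frames) the effect is well under the sampling error.
* Packaged descriptor values other than those explicitly printed
  (pKa 4.96/9.31, the isomer-pair responses 0.208/−0.056) are
  placeholders awaiting transcription from supplementary tables.
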