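# Methods

This note records the models, estimators, numerical choices and known
limitations behind each module, and what the synthetic-data generators
do and do not emulate.

## Kinetic transient fitting

Transients are modeled as sums of one or two exponentials plus a
constant, `y(t) = Σᵢ Aᵢ e^(−kᵢ t) + c`, with rate constants in s⁻¹ and
amplitudes/offsets in instrument units. Replicates measured under one
condition are fitted **globally**: the rates are shared, the linear
parameters are free per replicate, and all replicates are weighted
equally (no per-point weights are applied).

The fit uses variable projection: for any trial rate vector the optimal
amplitudes and offsets are an ordinary linear least-squares solution, so
the nonlinear optimizer searches only the (log-)rate space. The search
is multi-started from a log-spaced grid spanning
`[1/(10·t_span), 10/Δt_min]` — the resolvable rate window of the
sampling — which makes the result deterministic for a given input and
robust to local minima without hand-picked initial values. Rates are
clamped to `[10⁻¹², 10⁹] s⁻¹` inside the residual function purely to
keep wandering trust-region steps finite. The reported rate standard
errors come from the profiled finite-difference Jacobian
(`s²(JᵀJ)⁻¹` in log-rate space, converted to the rate scale), with the
residual variance estimated at `RSS/(n − p)` counting all linear
parameters in `p`. The two-exponential convention is `k₁ ≥ k₂`, with
amplitudes permuted to match.

**Model selection.** Choosing between one and two exponentials by
"inspection of residuals" is subjective; the reproducible surrogate
used here accepts the two-exponential fit only when all three hold:

1. corrected-AIC improvement > 10 (default, configurable);
2. rate separation `k₁/k₂ > 3` (default, configurable);
3. each component's median |amplitude| ≥ 10% of the median signal span.

Condition 3 exists because with thousands of samples a phantom
fast phase of vanishing amplitude (fitting one or two noisy leading
points) can clear an information-criterion bar while being invisible —
and unacceptable — in a residual plot. All three thresholds are keyword
arguments of `select_model`.

## t50 extraction

`t₅₀` is the first time, at or after the global signal minimum, at
which the trace crosses halfway between that minimum and a horizontal
baseline, located by linear interpolation between the bracketing
samples. The baseline is the mean of the trailing fraction of samples;
the length of that "final section" is not standardized anywhere, so the
default is the trailing 10% (`baseline_fraction = 0.1`, configurable) —
appropriate for traces that have visibly plateaued. Taking the *first*
crossing matches the "time taken to reach" reading and makes the result
well defined when noise produces multiple crossings. `t₅₀` is invariant
under positive affine transforms of the signal and scales linearly with
the time axis. Failure modes are explicit: a baseline at or below the
minimum (e.g. a decreasing trace) and a signal that never reaches the
half level both raise, rather than returning a number.

Lag-phase traces can additionally be fitted with a 4-parameter logistic
(`fit_sigmoid`) for display; the specific sigmoidal form used in the
original analyses is not documented, and the logistic was chosen as the
minimal sigmoid with two asymptotes. Its midpoint is constrained to the
observed time window so traces without a genuine inflection remain
interpretable. No quantitative conclusion is drawn from this fit — all
half-times come from `extract_t50`.

## Summary statistics and fold changes

`summarize` reports mean, sample SD (ddof = 1; defined as 0 for n = 1)
and s.e.m. = SD/√n. `batch_rate_summary` implements the between-batch
error convention: replicates sharing a liposome batch are globally
fitted together and the s.e.m. is computed across batch-level rates.
Fold changes use `δR = |R|·√((δX/X)² + (δY/Y)²)`; the reciprocal
property `R(X,Y)·R(Y,X) = 1` holds exactly.

## Hill binding analysis

The Hill equation as printed gives `K_D` units of concentrationⁿ. The
fit is therefore parameterized directly by the half-saturation
concentration `K_d,app` (molar), with `K_D = K_d,app ⁿ` reported
alongside, so affinities are comparable across different Hill
coefficients; both forms are emitted because published "apparent K_d"
values do not always state which convention they use. Initialization:
unbound/bound signals from the lowest/highest-concentration points,
`K_d,app` from the concentration nearest half signal range, n = 1.
Zero-concentration points are excluded from this log-scaled
initialization but included in the fit. The fit is bounded
(`K_d,app` within 10⁴× of the measured concentration range,
n ∈ [0.05, 10]) and carried out with lmfit/least-squares. A
"saturation-not-approached" warning is attached when the fitted bound
plateau lies outside the observed signal range by more than half the
dynamic range. The residual sum of squares is reported so free-n and
n-fixed fits can be compared directly.

The titration simulator produces the descending ladder
`top/factorⁱ`, i = 0…n−1; the default 16 two-fold dilutions from
100 μM end at 100/2¹⁵ μM ≈ 3.05 nM.

## Gel and CD calculators

`fraction_folded = folded/(folded + unfolded)` from the unboiled lane
is the default; dividing by the boiled-lane intensity is available as
an explicit mode for samples where the unboiled total decays over time.
MRE uses `MRW = M/(N−1)` and `[θ] = MRW·θ_λ/(10·d·c)` with the
concentration in g/mL by default; because the unit of `c` in this
formula is a recurring source of confusion, a `mg_per_ml` flag converts
explicitly rather than guessing.

## Membrane analysis

All systems are planar bilayers, so the bilayer normal is fixed to z
and no local-normal estimation is attempted. Distances use the minimum
image in x/y only (the membrane plane is periodic; the solvent
direction is not).

* **Leaflets**: lipids are split by phosphate z relative to the mean
  phosphate z; an all-on-one-side configuration is rejected as "not a
  bilayer".
* **Annular selection**: a lipid belongs to the annulus of an anchor
  residue when its PO4 bead is within the cutoff (default 12 Å,
  inclusive) of any bead of that residue. Whether historical scripts
  used the phosphate bead or the whole lipid for this criterion is not
  documented, so a `use_whole_lipid` switch is exposed; the phosphate
  default matches the bulk criterion, which is explicitly
  phosphate-based. **Bulk**: PO4 strictly farther than the bulk cutoff
  (default 30 Å) from every protein bead; with no protein, all lipids
  are bulk.
* **Thickness**: mean upper-leaflet PO4 z minus mean lower-leaflet
  PO4 z over the selection. No standard local-thickness estimator
  exists for annular patches; this selection-restricted leaflet-mean
  estimator is the simplest phosphate-based one. Frames in which either
  leaflet has fewer than `min_per_leaflet = 3` selected lipids yield a
  missing value for that frame (logged, excluded from averages) rather
  than a noisy estimate.
* **Order parameters**: `S = ½(3cos²θ − 1)` per bond, with bonds G-1
  (each glycerol bead to the first bead of its chain) and consecutive
  chain-bead bonds; the two chains are pooled, matching the convention
  of reporting one value per bond label. Only bonds present at the
  system's chain length are reported (2-bead chains: G-1 and 1-2;
  3-bead add 2-3; 4-bead add 3-4). Zero-length bond vectors are skipped
  and logged.
* **Aggregation**: per replica, observables are time-averaged over the
  post-burn-in frames (`burn_in_fraction = 1/6` by default, i.e. the
  final 2.5 μs of a 3 μs run); across replicas, mean ± sample SD
  (n−1; a single replica reports SD = 0). Frames are weighted equally.
  Replicas with differing bond sets are rejected.

## Synthetic bilayer generator

The generator emulates the *geometry and statistics* of a CG
protein-in-bilayer system, not its physics: frames are i.i.d. jittered
configurations, not time-correlated dynamics, and there are no steric
interactions, solvent, or real lipid chemistry. Defaults (~450 lipids
in a 112 Å box, 30 frames, 5 replicas, 4-bead chains, 38 Å
phosphate-phosphate bulk thickness) match the system scale of typical
multi-replica CG studies while running in seconds.

Two design choices make ground truth analytic:

* **Chains at a fixed cone angle.** Acyl chains are grown bead-by-bead
  with a fixed polar angle θ_c from the normal and a uniform random
  azimuth per bond, so *every* bond's order parameter is exactly
  `½(3cos²θ_c − 1)`, with zero sampling variance. Disorder is imposed
  deterministically rather than drawn from a distribution precisely so
  recovery tests compare against an exact value.
* **Plateau-shaped perturbation field.** The local leaflet separation
  is `T(r) = bulk − Δ·g(r)` with r the in-plane distance from the seam
  anchor and g(r) = 1 inside a plateau radius (default 13 Å, slightly
  larger than the 12 Å annular cutoff) decaying as a Gaussian shoulder
  (width 4 Å) beyond; the cone angle interpolates with the same g(r).
  A plateau rather than a bare Gaussian is used so that *every* lipid
  inside the annular selection experiences the full imposed contrast —
  the recovered annular mean is then directly comparable to Δ instead
  of to a selection-weighted average of a radially varying field, which
  keeps recovery tests interpretable. The imposed field is emitted as a
  ground-truth record with `thickness_at(r)` / `order_at(r)`.

The protein stand-in is a cylinder of bead columns, one residue per
azimuthal column with beads stacked through the membrane. Real barrel
residues sit at one height; columns are used so that "within 12 Å of
residue X" behaves as the radial annulus criterion it is in a real
barrel, where neighboring strand residues fill the column. The seam
anchor column (author-style residue number 808 by default) sits at
azimuth 0, the opposite anchor (613) diametrically across; with the
default 20 Å barrel radius, the opposite annulus is ≥ 28 Å from the
seam and feels < 2% of the imposed field. The only noise is per-lipid
rigid-body Gaussian jitter (default 0.8 Å), so the expected error of an
annular thickness mean is jitter/√(selected lipids), and passing
recovery tests demonstrates correctness of the estimators — not that
real MD thinning values are reproduced, which requires real force
fields and sampling.

## Kinetic/titration generators

Transient models are the exponential forms above plus a logistic
lag-then-rise; noise is multiplicative Gaussian
(`y·(1 + f·ε)`), reflecting the roughly signal-proportional noise of
fluorescence detection. The default study conditions used in tests —
600 s at 1 s sampling, 3 replicates, 2% noise, observed rate
14.9 × 10⁻³ s⁻¹; 16-point two-fold titrations at 1% of the dynamic
range from K_d,app = 1.8 μM, n = 1.5 — correspond to the measured
conditions the package is built to analyze. Generators are
bit-reproducible for a fixed seed (`numpy.random.default_rng`).

## Units and conventions

Internal units: Å for lengths, seconds for kinetic time, μs for
trajectory time, molar for concentrations; converters live only at file
boundaries (GRO files are nm on disk). Lipid/protein indices are
0-based internally; residue anchors are accepted in author numbering
via the coordinate files.

## Problem sizes in the test suite

Seeded simulation counts in the tests (30–200 seeds depending on the
check, 5 × 30-frame bilayer replicas) were chosen so each suite
finishes in well under a minute while leaving the statistical criteria
(95% coverage rates, median errors) stable across re-runs; they are the
package's own verification conditions, and larger runs only tighten the
same comparisons.

## Known limitations

* No photobleaching, drift, or inner-filter corrections; least-squares
  only (no Bayesian fitting).
* Thermophoresis physics is not modeled; the titration signal is a
  generic binding readout.
* No MD engine features: no lateral-gate detection, diffusion analysis,
  or atomistic back-mapping; XTC/TRR binary trajectories are out of
  scope (GRO text frames only).
* The local-thickness estimator is selection-restricted leaflet means;
  it does not pair leaflet patches within an annulus and will be biased
  for strongly curved membranes (none occur here).
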