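# Methods

## The two-stage influx model

Short-term nitrogen influx into roots is modelled as the sum of two
saturable transport phases. Below an activation threshold `T` (mM) only the
high-affinity system (HATS) operates and influx follows a single
Michaelis–Menten curve `V1·S/(Km1+S)`. At and above `T` the low-affinity
system (LATS) contributes a second, shifted Michaelis–Menten term while the
HATS contribution is frozen at its value at `T`:

```
v(S) = V1·S/(Km1+S)                                S <  T
v(S) = V1·T/(Km1+T) + V2·(S−T)/(Km2+S−T)           S ≥  T
```

The second branch is evaluated exactly in this printed form; continuity at
`S = T` is structural (the LATS term vanishes at `S = T`), so no numerical
continuity constraint is ever imposed. The curve is nondecreasing in `S`
and bounded above by `V1 + V2`. Phase identity follows the convention
`Km1 ≤ Km2` (phase 1 is the high-affinity one); parameter sets violating it
are normalised by swapping the phase pairs, with a warning, since the
piecewise form implicitly assumes that ordering.

Assumptions worth stating: the two phases are independent and additive; the
LATS switches on sharply at `T` rather than gradually; there is no
substrate inhibition, temperature or pH dependence, and no gene-level
transporter resolution. A LATS that rises "almost linearly" over the assay
range is represented by the same MM form with `Km2` far above the largest
tested concentration — in that regime the data constrain the initial slope
`V2/Km2` much better than `V2` and `Km2` individually (see *Ridge
behaviour* below).

Units are mM for concentrations and μmol/g DW/h for rates throughout. The
model layer is unit-agnostic beyond consistency: converting a 10-minute
tracer incubation into an hourly rate (×6) is the data producer's
responsibility, and the simulator works natively in per-hour units.

## Estimation

**Why profiling.** The SSE is non-smooth in `T`: as `T` moves past an
observed concentration, that observation switches branches. Gradient-based
joint optimisation over all five parameters is therefore unreliable.
Instead `T` is profiled over a finite candidate set — by default the
observed concentrations plus the midpoints between consecutive ones — and
the four rate constants are fitted at each fixed `T`. The candidate with
minimal SSE wins; SSEs within `1e-12·Σv²` of each other are treated as
ties, broken toward the smallest `T`. The tie tolerance matters: on
noise-free data several candidates reach SSE ≈ 0 at float precision, and a
strict comparison would let rounding noise pick an arbitrary one.

**Inner solver.** For fixed `(Km1, Km2, T)` the model is linear in
`(V1, V2)`, so the inner problem is solved by variable projection:
`scipy.optimize.least_squares` runs over `(log10 Km1, log10 Km2)` and the
nonnegative amplitudes are recovered by a closed-form 2×2 least-squares
solve (with edge cases pinned at zero) at every residual evaluation. This
is the same objective as a plain four-parameter bounded solver but much
better conditioned, which matters on the LATS ridge, and several times
faster, which makes dense bootstrap calibration studies practical. The
optimiser runs the compiled Levenberg–Marquardt path first (log-space keeps
the constants positive by construction) and falls back to the bounded
trust-region solver in the rare case the solution leaves the box. All
parameters are constrained to (1e-6, 1e4) in native units.

**Initialisation.** `Km1` starts from a Hanes–Woolf linearisation (`S/v`
regressed on `S`) of the records below the candidate threshold; `Km2` from
the exact two-point solution of the shifted MM through the two largest
mean rates (plateau-corrected), with a fallback of `2·max(S)` when the
two-point system is inconsistent (as it routinely is under noise).

**Candidate admissibility.** A candidate needs at least two distinct
concentrations below it to identify the HATS pair. A candidate with fewer
than two distinct concentrations above it is fitted with the LATS disabled
(`V2 = 0`) instead of being rejected — so the two-stage family nests the
single-phase model within any candidate set that reaches past the data.
The fit refuses datasets with fewer than five distinct concentrations, or
where no candidate has two distinct concentrations on each side.

**Replicate-level fitting, unweighted loss.** All replicate-level records
enter the SSE individually (not concentration means): this preserves the
degrees of freedom that AICc and the bootstrap rely on. The loss is
unweighted (homoscedastic); there is deliberately no default weighting
because the measurement-error structure of IRMS-derived rates is not
identifiable from a single assay.

**Model selection.** Mono vs two-stage is decided by small-sample-corrected
Akaike information, `AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1)` with k = 2
or 5; smaller wins and exact ties go to the simpler model. AICc rather
than an F-test because the comparison is made routinely on fits that may
sit on parameter-space boundaries, where the F-test's nesting assumptions
fail. With n ≤ k+1 the correction term blows up and the comparison raises.

**A degeneracy worth knowing.** The two-stage family contains every mono
MM curve *exactly*, for any threshold: take `Km2 = Km1 + T` and
`V2 = V1·Km1/(Km1+T)` and the two branches reassemble the single
hyperbola. On purely single-phase data the two-stage SSE therefore ties
the mono SSE across thresholds, the smallest-T tie-break picks an
arbitrary-looking but exactly equivalent parameterisation, and only the
AICc penalty identifies the simpler truth. This is a property of the
printed model family, not an artefact of the optimiser.

**Ridge behaviour.** When `Km2 ≫ max(S)` (the ammonium LATS: Km2 ≈ 81 mM
against a 10 mM assay ceiling) the likelihood surface has a long flat
ridge along which `V2` and `Km2` trade off at nearly constant `V2/Km2`.
Point estimates of `V2` and `Km2` individually are then noise-sensitive,
but the initial LATS slope `V2/Km2` is recovered tightly (tested at ≤ 5 %
relative error under 2 % measurement noise), and noise-free data still
identify the pair exactly.

**Bootstrap.** Uncertainty comes from case resampling stratified within
concentration levels — each concentration's replicates are resampled with
replacement, preserving the assay design. A residual bootstrap was
rejected because the heteroscedasticity of real assays is unknown.
Intervals are percentile intervals; refits warm-start from the point
estimate and re-profile the threshold over a local candidate set (the
estimate and its immediate profile neighbours) rather than the full grid —
the threshold lives on a discrete candidate grid, so distant candidates
only re-enter when the resample changes the fit grossly, and the local set
keeps a 500-simulation × 200-resample calibration study inside minutes of
CPU. Full re-profiling is available by passing an explicit candidate set.
If more than 20 % of refits fail, intervals come from the successful draws
and a warning flag is set.

**Calibration.** The suite runs a coverage study (5 % noise, 4 replicates,
95 % level, 500 simulated assays × 200 resamples) targeting empirical
coverage of `V1` within 95 % ± 5 points. The study measures ≈ 86 %: the
estimator is unbiased, but resampling within strata of only 4 replicates
shrinks the bootstrap variance by the classic (n−1)/n = 3/4 factor
(bootstrap sd 0.041 against a true sampling sd 0.047), and the 200-draw
percentile quantiles narrow the interval further. This is the documented
small-sample behaviour of the percentile bootstrap, not an optimiser
artefact — re-profiling the threshold over the full candidate grid with
cold starts reproduces the same bootstrap spread. Treat the default
intervals as mildly anticonservative at 4 replicates per concentration;
for calibrated inference either increase replication or inflate the
within-stratum draws externally.

## Simulators

**Influx.** The generator draws one record per grid concentration ×
replicate from the two-stage curve. Defaults mirror the standard tea-root
assay: the 13-concentration grid 0.01–10 mM, 4 replicates, 10-minute
incubation reported per hour. The default noise model is multiplicative
normal, `v = max(0, rate·(1+ε))`, ε ~ N(0, cv) with cv = 0.05 — IRMS-derived
rates scale roughly with signal, and 5 % is a realistic between-plant plus
instrument CV for short-term labelling; additive noise and noise-free modes
exist. Draws are truncated at zero. Provenance (generating parameters,
design, noise, seed) is embedded in every dataset and written as a JSON
sidecar next to CSV exports.

**Metabolites.** The generator draws a tidy treatment × organ × replicate ×
analyte table around user-declared cell means, truncated-normal at a given
CV (default 0.10; truncated-normal rather than lognormal for direct moment
control — at these CVs the truncation bias is negligible). The built-in
default design emulates a five-treatment ammonium:nitrate experiment
(100:0 … 0:100 at 2.86 mM total N, 6 replicates, two organs, a small FAA
panel dominated by theanine) with qualitative patterns typical of tea:
theanine and arginine rising with the ammonium share, glutamine peaking at
the 25:75 treatment.

What the simulators do **not** emulate: growth and allocation dynamics,
organ-to-organ transport, natural-abundance ¹⁵N background (the
`ape_to_influx` conversion is the minimal isotope-dilution formula —
background subtraction is the caller's job), correlated noise across
analytes, batch effects, or gene expression. Passing tests therefore
demonstrate correctness of the estimators *given* the model family and
independent truncated-normal noise; they do not validate the biological
model against real plants.

## Metabolite analytics

Ratios (e.g. Gln:Glu) are computed per replicate and then summarised —
matching per-replicate plotting conventions — rather than as ratios of
means; a nonpositive denominator yields a flagged NaN record, never a
silent drop. Totals are per-sample sums over a declared analyte set.

The log₂ fold-change matrix divides each analyte's treatment mean (and,
in the per-sample long form, each individual value) by the analyte's grand
mean. The grand mean is the mean of the per-treatment means, so treatments
are weighted equally regardless of replicate counts, and the non-log
treatment-mean fold changes of every row average to exactly 1 — an
identity the tests assert to machine precision. Dividing by the mean over
all samples instead is available via `grand_mean="sample"`; the two
coincide for balanced designs. Rows with a zero grand mean are emitted as
NaN with a warning. Group-difference testing (e.g. Tukey's HSD letters) is
deliberately out of scope: the module emits tidy tables any standard
implementation can consume.

## Numerical and design choices, in brief

- Threshold candidates default to observed concentrations + midpoints;
  ties toward smallest `T`; tie tolerance `1e-12·Σv²`.
- Parameter box (1e-6, 1e4); optimisation in log10-Km space; LM first,
  bounded fallback; tolerances 1e-12, max 100 residual evaluations per
  candidate.
- `brute_force_fit` is an optimizer-independent grid oracle (closed-form
  amplitude scan per Michaelis-constant/threshold triple, ≤ 1e7 points),
  used in tests for equivalence checks.
- Dataset identity for model comparison is enforced by record count plus
  an order-invariant SHA-256 fingerprint of the (S, v) pairs.
- CSV dialects are fixed-header, '.'-decimal; readers fail loudly with
  line numbers rather than coercing.
- Problem sizes used in the shipped studies: 13 × 4 = 52 records per
  assay; the bootstrap calibration runs 500 simulated assays × 200
  resamples (≈ 10 min on one CPU), sizes chosen to estimate a 95 %
  coverage proportion to roughly ± 1 percentage point Monte-Carlo error.

## Known limitations

- Exactly two phases; no gradual LATS activation, no ≥3-phase models, no
  hierarchical (multi-plant) kinetics, no Bayesian estimation.
- Percentile bootstrap intervals undercover at the default 4 replicates
  per concentration (≈ 86 % empirical at nominal 95 %; see *Calibration*);
  they tighten toward nominal as replication grows.
- `V2`/`Km2` are reported individually even deep in the ridge regime;
  consult their bootstrap intervals (or the `V2/Km2` slope) before
  interpreting them separately.
- The threshold estimate lives on the candidate grid; its resolution is
  the grid's, and its bootstrap interval inherits that discreteness.
- The metabolite simulator's independence assumptions make it a tool for
  validating analytics, not for power analysis of real designs.
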