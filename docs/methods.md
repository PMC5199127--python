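# Methods

## Model and assumptions

The sensor is modeled at steady state as three chained, non-cooperative
Hill relationships (Hill coefficient fixed at 1 throughout; no
cooperativity knob is exposed):

1. input miRNA → activator knockdown: `[Act] = Act_MAX·IC50_miR/(IC50_miR + [I])`
2. activator → miR-FF4 induction: `[FF4] = FF4_MAX·[Act]/(K_d + [Act])`
3. miR-FF4 → output knockdown: `[Out] = Out_MAX·IC50_FF4/(IC50_FF4 + [FF4])`

The cascade is strictly feed-forward, so a single evaluation pass is the
fixed point of the system; the test suite verifies this against an
independent fixed-point iteration. The model deliberately omits:
time-dependent dynamics (steady state only), resource competition between
plasmids, transfection-dosage effects, and basal (leaky) expression of the
inducible promoter inside the cascade itself — stage 2 has no additive
basal term, matching the three relations above exactly. Basal leakage
*is* represented in one place where it changes an observable: the
output-plus-cassette control condition of the simulated screen (below).

All concentrations are molecules/cell; `molecules_to_nm` converts with
1,000 molecules/cell ≈ 1 nM. Interaction constants (`ic50_mir`,
`ic50_ff4`, `kd`) must be strictly positive because they sit in
denominators; pools (`act_max`, `mirff4_max`, `out_max`) may be zero,
giving degenerate but well-defined flat sensors (a zero output pool is
summarized as dynamic range 1). The theoretical On state is returned
analytically as `out_max` rather than evaluated at a large finite input.

### Default parameters

The canonical basic set is `IC50_miR = 20`, `IC50_FF4 = 20`,
`K_d = 10,251`, `Act_MAX = 9,755`, `FF4_MAX = 3,000`, `Out_MAX = 30,000`
molecules/cell, with the practical On state evaluated at 3,000 input
molecules/cell (a highly expressed endogenous miRNA).

## Sensor IC50 extraction

Input-output curves are generated on a log-uniform grid, by default 61
points (10 per decade) over 1e-1–1e5 input molecules; the range is fixed
by the study design, the density is this package's choice. Two estimators:

- **Hill-with-leakage fit** `y = b3 + b1·x/(b2 + x)` by bounded
  trust-region least squares; `b2` is the sensor IC50. Initialization:
  `b3 ←` min response, `b1 ←` response span, `b2 ←` geometric mean of the
  positive dose range; all bounded below by zero. Responses are rescaled
  to unit maximum inside the fit (restored afterwards), which makes `b2`
  numerically invariant to linear output rescaling such as output-pool
  changes. The `converged` flag requires both optimizer success and a
  relative residual norm ≤ 1e-3 (configurable). For the three-stage
  cascade this fit is *exact*: the composition of the three first-order
  Hill stages is a Möbius function of the input, which is precisely of
  the `b3 + b1·x/(b2+x)` form — residuals on model curves are at
  floating-point level.
- **Inverse mapping**: on a percent-normalized curve, scan in increasing
  dose for the first segment bracketing 50%, take the three-point
  vicinity (bracketing pair plus the neighbor on the side of the closer
  endpoint, so at least one point lies above and one below 50%), and
  interpolate linearly between the bracketing pair. Only the bracketing
  pair enters the estimate; the wording of the three-point rule is
  ambiguous about whether the third point carries weight, and the
  pair-only reading was adopted as the one that is exact on piecewise
  linear data. With multiple crossings (noisy data) the first in
  increasing-dose order is used, matching how a monotone transfer curve
  is read left to right.

Normalization conventions: knockdown and induction curves set their
maximum response to 100% (induction curves are assumed to saturate);
`output_with_control` curves use an externally measured control value as
100%, with no saturation assumption. The two estimators agree on
single-Hill data to grid resolution; on full sensor curves they differ by
a few percent (8% at the basic set) because the observed maximum of a
finite-range curve sits below the asymptote `b1 + b3` — the package
treats the Hill-fit `b2` as the canonical sensor IC50.

## Parameter exploration

Sweeps default to ±2 decades around the basic value on a 25-point log
grid. Inside sweeps the sensor IC50 uses the Hill fit on the default
61-point curve; a non-converged or non-positive fit falls back to inverse
mapping on a 1,000-point curve and is flagged in `ScanResult.ic50_method`.
`find_optimal_kd` maximizes the practical dynamic range by a dense
log-grid search (121 points by default) followed by bounded golden-section
refinement on the log axis (relative tolerance ~1e-3), reporting three
significant figures; a boundary maximum raises a `NarrowRangeWarning`
rather than an error, since a flat or monotone landscape (e.g. a zero
miR-FF4 pool) is a legitimate degenerate answer. At the basic set the
optimum is K_d ≈ 9,760 ≈ Act_MAX: the activating stage should operate
far from saturation, but not so weakly that miR-FF4 never accumulates —
and the maximizing K_d scales with the activator pool (the "optimal
crest" at a fixed ratio of the two).

## Synthetic screen

The simulator emulates the combinatorial screening campaign: six
functional blocks with 2–3 variants each — activator promoter (CMV, UbC),
transactivator (tTA, PIT2; the miR-FF4 cassette's inducible promoter
follows automatically, TRE↔tTA, PIR↔PIT2), input-miRNA target placement
(3'-UTR, 5'+3'-UTR), miR-FF4 cassette (intron only, citrine-embedded),
output promoter (EF1A, UbC) and miR-FF4 target placement (3F, 5F,
5'+3'F) — giving 8 activator constructs and 96 compositions laid out on
an 8 × 12 plate (one activator construct per row; columns 1–6 intron-only
cassette × six output constructs, 7–12 citrine-embedded).

Each variant multiplies a whitelisted subset of the six parameters. The
**default multiplier table is a calibration stand-in**: the true
quantitative effect of each genetic part was never measured, so the
defaults encode the qualitative knowledge available — UbC ≈ 0.3× CMV on
the activator pool (0.4× EF1A on the output pool); PIT2 ≈ 100× tTA on
both expression and K_d (much stronger expression, much weaker operator
binding); 5'+3' input targets 0.3× on IC50_miR (dual-UTR targeting
strengthens knockdown); citrine-embedded cassette 0.3× on FF4_MAX;
output targets 1×/2×/1.5× on IC50_FF4 for 3F/5F/5'+3'F (3'-only near
maximal in the modeled cell context). All factors are configurable via
the library YAML; conclusions drawn from the default table are
model-consistency checks, not predictions about specific plasmids.

Measurements per composition: `on` (practical On), `off` (output at zero
input — a perfect inhibitor; a `residual_input` knob, default 0, covers
imperfect inhibition), `output_only` (the full output pool) and
`output_plus_ff4` (output with the un-activated cassette, reduced by a
`control_leakage` factor, default 0.85, for basal inducible-promoter
leakage). Replicates (default 3) draw independent multiplicative
lognormal noise with unit mean and configured CV (default 0.2, a typical
transient-transfection replicate spread); the seed is mandatory and the
table regenerates bit-identically under it. Pool normalization divides
every record by the mean `output_plus_ff4` control of the matching output
construct — the highest level a fully inhibited sensor could reach —
leaving within-composition ratios (the dynamic range) unchanged.

What the simulation does **not** emulate: well-position effects,
transfection-efficiency variation beyond the single noise term,
cross-talk between co-transfected plasmids, imaging/cytometry
discrepancies at very low signals, and any cell-line dependence beyond
what the parameter set encodes. Passing trend tests therefore show that
the analysis pipeline recovers the effects the multiplier table puts in —
not that real screens will show those exact ratios.

## Screen analysis

Per-composition summaries are replicate means and SDs (ddof = 1; SDs
omitted for single replicates) in absolute and pool-normalized units,
with the dynamic range as the ratio of means. Plate heat maps are 8 × 12
matrices in well layout; log10 transforms (used for Off and dynamic
range, to spread the low end) floor values at 1e-6 of the table maximum
so zeros stay finite. Pairwise trends compare all composition pairs
differing in exactly one block (a transactivator swap changes the matched
inducible promoter too, and still counts as one swap): with the default
library every two-variant comparison has 96/2 = 48 pairs, and any
output-target comparison (three variants) has 96/3 = 32. Trend means and
SDs are taken over raw per-pair ratios, matching the bar-chart convention
for such screens; a log-ratio option exists for symmetric averaging.
Zero-denominator pairs are excluded and counted. Ranking sorts by dynamic
range (descending), tie-broken by On state then composition id, making
the order fully deterministic.

## Pipeline and problem sizes

`run_full_pipeline` chains scans → landscape → enumeration → simulation →
normalization → summaries → heat maps → trends, writing CSV/JSON plus a
manifest with a SHA-256 hash of the canonical config and the seed.
Defaults: 25-point scans for each of the six parameters, a 13 × 13
landscape, and the full 96 × 4 × 3 screen — a few seconds end to end,
chosen because the closed-form model makes denser grids add resolution
but no new structure. The test suite's Monte-Carlo noise checks use a
handful of seeds (5–8) with 384 condition groups each, plenty to pin the
replicate-CV distribution at n = 3.

## Known limitations

- The multiplier table is qualitative; absolute trend ratios from the
  default screen are not experimental predictions.
- The Hill-fit/inverse-mapping disagreement on full sensor curves is a
  structural finite-range effect (~8% at the basic set), not an error
  estimate.
- Off states assume a perfect inhibitor unless `residual_input` is set;
  whether an experimental inhibitor-derived Off corresponds to exactly
  zero input is not knowable from the model.
- The two-sensor logic compositions built from this sensor (e.g. XOR
  networks) are out of scope; the model covers a single cascade.
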