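# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `stemwater` pipeline. It is written for a reader who
wants to know exactly what each number in the output means and what the
synthetic validation does and does not establish about real data.

## Tree water deficit and PLW_E

TWD(t) is the difference between the running maximum of stem radius and
the current radius, computed in one vectorized pass
(`np.maximum.accumulate`); the test suite verifies exact agreement with
the O(n²) prefix-max definition on random series. TWS = TWD_max − TWD
and PLW_E = 100·TWD/TWD_max.

- **TWD_max** defaults to the series' global maximum deficit. This is
  the right choice for a terminal dry-down in which shrinkage has
  ceased (complete elastic dehydration); for observational series an
  external `twd_max` override is accepted, and PLW_E values above 100 %
  raise a warning rather than being clipped.
- **Gaps**: NaN runs up to 60 min (configurable) are linearly
  interpolated; longer runs are an error naming the gap. The running
  maximum is never reset across gaps, because the deficit is defined
  against the *preceding absolute* maximum.
- **Daily extremes**: predawn window 03:00–07:00 (TWD minimum), midday
  window 12:00–18:00 (TWD maximum), both configurable; the source data
  nominate the extremes but not the windows, so these are explicit
  package choices. Diurnal shrinkage is TWD_md − TWD_pd within a day;
  nocturnal swelling is TWD_md(d) − TWD_pd(d+1). Negative swelling (net
  overnight shrinkage under severe drought) is retained by default
  (`clip_negative_swelling=False`) because it is information, not error.
- **Drought restriction**: daily-cycle analyses keep only days after the
  tree's global radius maximum (to exclude growth-driven variation) and
  normalize swelling/shrinkage to tree-specific maxima over the retained
  period. If the retained maxima are non-positive the normalization is
  flagged degenerate and the normalized values are NaN.

## Weibull loss curves

All three channels use the two-parameter Weibull survival form
rel(T) = exp(−(T/b)^c), T = |Ψ|, fitted by least squares on the relative
scale (fitting on percentages only rescales residuals). The fitplc-style
(PX, SX) parameterization is available as a read-only conversion
(`px_sx_parameterization`), not as optimizer coordinates.

- **Initialisation / multistart**: a log-linearisation
  ln(−ln rel) = c·ln T − c·ln b on interior points seeds the optimizer;
  a coarse grid over b ∈ [0.5, 20] MPa, c ∈ [0.5, 10] guards against
  local minima on flat curves (juniper-like embolism resistance).
  Optimisation is in log-parameters, so positivity is structural.
- **Preprocessing** (PLG): per tree, the minimum g_s over the last two
  campaigns (configurable; the number of "final campaigns" is not
  pinned by the source, default 2) is subtracted from the whole series
  — residual cuticular conductance plus porometer bias never lets g_s
  reach zero — and the corrected series is scaled by its maximum and
  clipped to [0, 1]. Missing/unreliable Ψ readings are replaced by the
  previous campaign's value and flagged `carried_forward`. PLC uses
  k_h/k_max per sample; PLW_E uses 1 − TWD_md/TWD_max paired with
  same-date midday Ψ (daily-cycle regressions instead use TWD_pd).
  The fitter itself does not clip rel: truncating noise around rel ≈ 1
  would bias the curve.
- **Bootstrap**: case resampling of the paired observations (pooled by
  species; mixed-effects alternatives are prone to non-convergence on
  this design, and a tree-level cluster bootstrap is available behind a
  flag). Percentile CIs use outward (floor/ceil) order statistics: with
  a few hundred replicates the interpolated percentile systematically
  narrows the interval. Calibration measured by the acceptance suite:
  at n = 30 observations, 5 % noise and 200 replicates, nominal 95 %
  CIs cover the true P50 in ≈ 94 % of 200 simulated datasets. Threshold
  estimates beyond the sampled tension range are flagged extrapolated
  and reported without CIs.
- **Species comparison**: one-way ANOVA plus Tukey HSD on per-tree 50 %
  thresholds (n = 6 trees per species), mirroring the pooled-fit CIs'
  known tendency to understate between-tree variability.

## Safety areas and sequence classification

DSA and ESA are uniform trapezoidal integrals (2001 nodes by default;
deterministic, and the integrands are smooth — agreement with adaptive
quadrature is within 0.1 %). The integration bound is the *less
negative* of the PLW_E and PLC 88 % thresholds — the first one reached
while drying — which keeps the ratio away from non-functional tension
ranges. The stomatal safety margin is Ψ(PLG=95) − Ψ(PLC=50) on the
signed axis, flagged when either threshold is extrapolated beyond its
data. Sequence labels order channels by their 50 % tension and merge
adjacent channels whose 95 % CIs overlap ("co-occurring"), e.g.
`PLG -> (PLWE ~ PLC)`.

## Segmented daily-cycle models

The continuous two-segment model
y = a + s₁·min(x, ξ) + s₂·max(x − ξ, 0) is fitted per species with the
breakpoint ξ found by profile search over a deterministic grid (default
101 candidates over the central 80 % of the predictor range) — the kink
makes gradient methods unreliable, and the grid makes refits
reproducible. Ties pin ξ to the first candidate and single-slope data
raise a degenerate flag. One breakpoint per species (tree-level
breakpoints are not identifiable at n = 6). Tree effects: a joint
linear mixed model (random intercept + pre-break slope per tree) is
attempted first; on non-convergence the package falls back to a
two-stage scheme (per-tree least squares at the shared ξ, species
contrasts over tree-level slopes) and records which path was used.
Initial-slope contrasts are Tukey-adjusted over tree-level slopes.

## Pressure–volume analysis

Transformed coordinates: x = 1 − RWC, y = −1/Ψ (positive). Saturated
weight is extrapolated from the 3–4 wettest points of the fresh-weight ~
Ψ relation to Ψ = 0 (oversaturation correction), falling back to the
maximum fresh weight when the regression is uninformative; the estimate
is floored at the maximum observed fresh weight. The osmotic line is
the largest contiguous dry-end subset with R² ≥ 0.99 (minimum 4 points,
both configurable — the linearity rule in standard PV protocols is
implementer-defined). Π₁₀₀ = −1/intercept; Ψ_tlp is the osmotic-line
value at the wettest retained point rather than a two-line intersection
(common practice; the difference is within the sampling resolution of a
bench-dry sequence). Estimates are invariant to uniform rescaling of
the weights.

## Relative expression (ΔΔCt)

ΔCt = mean target Ct (≥ 3 technical replicates) minus the arithmetic
mean of the two housekeeping-gene Ct means (equivalent to a geometric
mean on the expression scale). The control reference per species × gene
is ΔCt_ref = −log2(mean over control samples of 2^(−ΔCt)): this keeps
fold change = 2^(−ΔΔCt) *and* makes the arithmetic mean of control fold
changes exactly 1, matching the convention of setting the control-period
mean ratio to one. (Centring on the mean control ΔCt would fix the
geometric mean instead; the two coincide without noise.) Replicate
spreads > 0.5 Ct are flagged. Primer efficiency is
(10^(−1/slope) − 1)·100 from the Ct ~ log10(input) standard curve; a
perfect two-fold ladder gives exactly 100 %.

The expression ~ Ψ model is linear on the fold-change scale (a log2
option exists) with species, gene and their interactions; backward
selection removes the least significant term with p > 0.05, never
removing a main effect while one of its interactions is retained, and
may reduce to the intercept-only model under a null slope. A tree-level
random-slope mixed model is attempted for the selected structure, with
an OLS/two-stage fallback; species slope contrasts are Tukey-adjusted
over tree-level slopes.

## The synthetic experiment

The generator emulates a four-species (beech, olive, pine, juniper)
potted dry-down: 6 trees per species, 90-day campaign (15-day watered
control, then 75 days without irrigation), stem radius at 10-min
resolution. Defaults:

- **Ψ schedule**: daily mean declines logistically from −0.5 to
  −10 MPa over the drought (smooth, monotone); a diurnal sinusoid with
  midday minimum (amplitude 0.4 MPa) is superimposed, scaled by the
  surviving stomatal conductance at the daily mean with a 15 % residual
  floor — transpiration drives the diurnal swing, so stem cycles shrink
  as stomata close, which is what produces the observed biphasic decline
  of nocturnal swelling along PLW_E.
- **Radius**: R₀ + growth − twd_max·W(Ψ) + Gaussian noise (SD 1.5 µm),
  where W is the Weibull CDF of tension with the species' PLW_E
  parameters; growth is a logistic cumulative curve gated off once the
  daily-mean Ψ drops below −1 MPa (configurable).
- **Loss-curve truths**: Weibull scales are derived from the published
  species ranking of 50 % thresholds for this four-species design
  (PLG₅₀ 1.54–2.94, PLC₅₀ 2.86–14.11, PLW_E50 3.77–8.08 −MPa) with
  channel shapes 3 / 3–4 / 2.5 (juniper PLC 1.6, a flat conifer-like
  curve); per-tree lognormal jitter (SD 5 %) on scales and twd_max
  creates tree-level variation for the per-tree ANOVA.
- **Campaign sampling**: midday Ψ/g_s twice weekly during control,
  three times weekly during drought, with 0.08 MPa / 6 mmol m⁻² s⁻¹
  measurement noise and an 8 % residual conductance floor; 12-level
  vulnerability curves per tree (3 % noise); 12-point PV curves per tree
  and period from Π₁₀₀/ε truths with larger osmotic adjustment in the
  conifers; qPCR at one control and three drought dates, 3 technical
  replicates, 0.15 Ct noise, fold change declining linearly with Ψ
  (slope per species, olive shallowest).

What the generator does **not** emulate: hydraulic-network or sap-flow
dynamics, temperature-driven stem expansion, sensor drift, leaf shedding
and the resulting loss of Ψ pairings, open-vessel artifacts, or the
interspecific differences in overnight refilling capacity that the real
data attribute to xylem anatomy — in the generator the steepness of the
swelling decline follows from the ratio of stomatal to elastic Weibull
scales, so the species ordering of initial slopes is not a validation
target, only the biphasic shape and its recovery are. Passing tests
therefore demonstrate correctness of the estimators under a known,
plausible data-generating process, not field validity.

Two deliberate consequences of the default conditions mirror real
limitations: olive's elastic scale (≈ 9.3 MPa tension) exceeds the
drought's end Ψ, so its stems never fully dehydrate, the observed
TWD_max underestimates the true capacity, and its PLW_E₅₀ is biased
early — the same caveat that applies to TWD_max estimation in real
campaigns; and juniper's PLC₅₀ lies beyond any plausible measured range,
so its CIs are reported as unavailable (extrapolated).

## Determinism and problem sizes

All randomness flows from one root seed through named substreams
(`seed × stage × unit` via CRC-keyed `SeedSequence`), so repeated runs
are byte-identical, including bootstrap CIs; the acceptance script
checks this by hashing two full reports. Default problem sizes — full
pipeline at 4 × 6 × 90 d × 10 min (311 040 radius rows) with 1000
bootstrap replicates; recovery/calibration experiments at 100–200
replicates with 200 bootstrap resamples — were chosen to keep a complete
validation run in the minutes range on a single core while leaving
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- PLW_E recovery is only unbiased when the campaign reaches complete
  elastic dehydration (see olive above); the package surfaces this as a
  warning plus the external TWD_max override rather than correcting it.
- The pooled (per-species) bootstrap ignores within-tree correlation;
  the per-tree ANOVA is the compensating analysis, and a cluster
  bootstrap flag exists but is not the default.
- Backward selection's p-values are nominal, not selection-adjusted.
- The segmented model assumes exactly one breakpoint; model selection
  against 0- or 2-breakpoint alternatives is out of scope.
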