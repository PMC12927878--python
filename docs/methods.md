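# Methods

This note documents the models behind `lotic`, the defaults that matter,
what the synthetic generator does and does not emulate, and the numerical
choices a maintainer should know about. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Travel time as the master axis

All trends are modelled against cumulative water travel time (WTT), not
distance: WTT is the time over which bacterial generations accumulate, so
rates per travel-hour are directly comparable across rivers and discharge
regimes. Segment WTT is distance / velocity; the representative segment
velocity defaults to the arithmetic mean of the two endpoint velocities
(least biased when velocity changes monotonically along the segment), with
an upstream-velocity convention selectable for sensitivity checks.
Downstream order is defined by strictly decreasing river kilometre; ties are
rejected. Travel times are stored in hours and converted to days only at
presentation, to avoid double rounding.

## Production calculus

Inputs per site: bulk secondary production `BSP` (µgC l⁻¹ h⁻¹, already
converted from leucine incorporation — the radiochemistry is upstream of
this package), total cell count `TCC` (cells l⁻¹) and mean cell volume
(µm³). Derived:

* `BSP_c = BSP·1e9 / TCC` (fgC cell⁻¹ h⁻¹),
* `mBM_c` from volume. The volume→carbon conversion is an explicit,
  swappable object: default linear 310 fgC µm⁻³, which maps the observed
  0.02–0.12 µm³ riverine volumes onto the observed 6–37 fgC biomass range;
  an allometric form (scale·V^exponent) is available. The conversion label
  is recorded in every output.
* `CD_d = 24·BSP_c / mBM_c`; doubling time `= 1/CD_d`. The reciprocal
  convention (not ln2/rate) is deliberate — it counts biomass-equivalent
  division events rather than exponential e-foldings — and a ln2 variant
  exists behind a flag, labelled in output.
* Cumulative doublings over the river are reported two ways: median `CD_d`
  × total travel days (the default, comparable with survey-style reporting)
  and the per-segment integral Σ `CD_d,up`·tt/24. On constant-rate data the
  two agree exactly (tested).
* Segment cell production uses the trapezoid of the two endpoint BSP values
  and the *upstream* biomass (`aCP_h = mean(BSP)·1e9 / mBM_c,up`): the cells
  producing along a stretch are those entering it. `CP_tot` is the sum of
  segment productions for one litre traversing the whole river; its ratio
  to the median standing stock measures how much of the production must be
  lost in transit (grazing, sedimentation, die-off). Loss processes are not
  modelled — only the excess is reported.
* Atom conversion: rate(gC cell⁻¹ h⁻¹ per travel-hour) × N_A / M_C with
  N_A = 6.02214076e23 mol⁻¹, M_C = 12.011 g mol⁻¹.

## Diversity

Libraries below a read threshold (default 3155) are discarded; retained
samples are rarefied by resampling *with replacement* to a common depth in
50 repetitions, and the per-cell means are rounded half away from zero.
Rounding convention matters because it decides presence/absence at the
margin, hence it is fixed and documented. Every repetition's column sum
equals the depth exactly (a tested invariant); the rounded averages sum to
approximately the depth. Randomness flows from one master seed expanded
into per-sample substreams keyed by sample id (CRC32), so adding or
removing a sample never changes another sample's draws.

Presence/absence for beta-diversity partitioning is taken from the rarefied
table (count > 0), matching the pipeline order rarefy → partition. With `a`
shared ASVs and `b, c` uniques, Simpson turnover is `min(b,c)/(a+min(b,c))`,
Sørensen is `(b+c)/(2a+b+c)`, and nestedness is their difference; the
partition is additive by construction and is verified against exhaustive
enumeration of all (a, b, c) ≤ 5. Bray–Curtis operates on per-sample
relative abundances (columns normalized to 1, enforced at 1e-9).

Whole-river turnover defaults to the endpoint pair (first vs last site) —
the most parsimonious reading of a single per-dataset number — with the
Baselga multiple-site Simpson/Sørensen available as `method="multisite"`,
since survey reports rarely state which estimator produced a single
"turnover along the entire river" figure.

Headwater persistence: the pool is every ASV present in any of the `n_head`
(default 3) uppermost-site samples; a member persists if present in at
least `presence_frac` (default 0.9) of all downstream samples. The
statistic is monotone non-increasing in `presence_frac` (tested).

## Trend models

Simple trends are OLS with slope ± SE, two-sided t-test p-values and
adjusted R². Backward selection starts from the full candidate model and
removes predictors by AIC (default) or by a largest-p-above-α rule; the
criterion is configurable because neither is canonical. Collinear designs
raise an error naming the offending predictors. Missing values are dropped
pairwise and logged, never silently.

Ordination defaults to PCoA (double-centering + eigendecomposition,
implemented directly so that negative eigenvalues of non-Euclidean
dissimilarities are reported as-is); nonmetric MDS is available via SMACOF
stress majorization started from the PCoA configuration with a fixed
iteration cap (500) and tolerance (1e-6). PCoA is the default because the
downstream use — vector fitting — is robust to the choice and a
deterministic ordination makes results reproducible without seed juggling.
Vector fitting regresses the environmental variable on the ordination axes
and permutes the variable; p = (b+1)/(B+1).

The discharge–richness model regresses observed ASVs on log2(discharge /
minimum discharge at the site), the only functional form under which a
"per doubling" slope is scale-free.

## Phylotype growth

ASVs worth fitting are selected by three filters: max/min relative
abundance ratio ≥ 100 (a zero minimum passes by convention — bloomers grow
from effectively zero; a pseudo-minimum variant exists), maximum relative
abundance ≥ 1 % somewhere, and prevalence ≥ 20 samples. Absolute abundance
is relative abundance × TCC of the sample.

The smoother is a penalized cubic regression spline (P-spline): B-spline
basis (default dimension 10) on uniform knots extended beyond the data
range, second-order difference penalty, weight chosen by GCV (ties broken
towards the smoother fit) or fixed effective df. Uniform extended knots are
essential: they put straight lines exactly in the penalty null space, so
the smoother reproduces linear signals to machine precision and shrinks to
a line (edf → 2) under heavy penalty. Uncertainty bands are ± 2 pointwise
SE from the penalized ("Bayesian") coefficient covariance σ²(B'B + λS)⁻¹,
an approximate credible envelope. Derivatives are analytic derivatives of
the basis — not finite differences — so they integrate back to the fitted
net change (tested to 0.1 %); their envelope uses the same covariance.
Replicates at identical travel times are averaged before fitting.

Site-to-site per-capita rates are natural-log rates, `24·ln(N_down/N_up)/tt`
(per day); division-equivalents divide by ln 2 and are labelled. A
downstream zero yields −inf (washed out below detection); an upstream zero
is undefined and raises.

## Synthetic generator

The generator is the package's test bed: it plants known parameters and the
suite verifies the analysis recovers them. It emulates: linear-in-WTT
trends (TCC rising, BSP / volume / richness falling) with mean-one
lognormal noise (bias-corrected so OLS recovery is unbiased); per-segment
Bernoulli replacement of non-core phylotypes with a protected persistent
core (the simplest process yielding turnover-dominated partitions — no
claim that it is the river's true mechanism); lognormal abundance weights
(rank-abundance skew needed for realistic rarefaction behaviour); logistic
bloomer trajectories whose exponential phase runs at
`bloomer_rate_multiplier` × the bulk division rate (logistic, not
exponential, so extrema are finite and have closed forms); and multinomial
read sampling at fixed depth.

Preset parameters mirror the two survey regimes: `jds3like` (54 sites,
~2563 km, velocities 0.9–5.4 km h⁻¹, ≈49 travel days, TCC slope
+9.5 × 10⁶ cells l⁻¹ h⁻¹, richness slope −0.13 ASVs h⁻¹, persistent core
10 %) and `jds2like` (75 sites, faster water, ≈31 days, TCC slope
+0.93 × 10⁶, richness slope −0.145). Line intercepts are set so the planted
lines pass through the surveys' published medians at the median-travel-time
site (e.g. TCC 13.9 × 10⁹ cells l⁻¹, BSP 1.15 µgC l⁻¹ h⁻¹ and mBM_c
≈ 16.5 fgC for the low-flow preset, giving a median CD_d ≈ 0.12 d⁻¹). The
`strong_replacement` scenario (replacement 0.5, core 3 %) is the regime of
near-complete phylotype exchange used for whole-river turnover checks;
with a 10 % core the endpoint turnover is algebraically capped near 0.84,
which is why the high-turnover scenario pairs high replacement with the
smaller core.

Generator design choices worth knowing:

* The uppermost `n_headwater_shared` (3) sites form one headwater reach
  sharing a source pool — replacement starts downstream of it. Otherwise
  the headwater ASV pool (the union over three sites) would be inflated by
  within-reach turnover and the planted persistent fraction would not be
  the quantity the persistence analysis estimates.
* Bloomers count toward the per-site richness target wherever they are
  abundant enough to be detected, so they do not bias the planted richness
  slope.
* Read depth defaults to 50 000 per sample, chosen so detection of the
  rarest planted ASV is near-certain (expected count ≈ 17 at the smallest
  relative abundance) and the planted richness slope is identifiable from
  observed richness. Shallower, survey-like depths are exercised separately
  in the rarefaction tests.
* Expected consecutive-site turnover has the closed form
  `replacement_rate × (1 − core/richness)` (first-order in the
  within-segment richness change), exported by `truth_report` for tests.

What the generator does **not** emulate: tributary network topology and
mass effects, sequencing error and PCR bias, overdispersion beyond
multinomial sampling, local discontinuities (impoundments, sewage inputs),
and seasonal dynamics. Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated generative model, not their
robustness to every feature of real survey data.

## Numerical conventions and problem sizes

* Rounding for comparisons against published figures: half away from zero
  at the printed precision; internal computation is never rounded.
* Permutation p-values: (b+1)/(B+1).
* Backward-selection consistency is checked with the α criterion at 0.01:
  with two pure-noise candidates, AIC retains at least one noise term with
  probability ≈ 0.29 (P(χ²₁ > 2) ≈ 0.157 each) and α = 0.05 with ≈ 0.10,
  so a ≥ 90 %-pure-model criterion is only attainable at a stricter α.
* Test problem sizes: recovery checks run 100 generator seeds at 54 sites;
  rarefaction statistics use 1000 repetitions at depth 100 on a 3-ASV toy;
  permutation-null uniformity uses 200 replicates × 199 permutations. The
  end-to-end pipeline examples use 10 rarefaction repetitions (the
  repetition count affects only the Monte-Carlo error of the averaged
  counts, not any expectation).

## Known limitations

* The volume→carbon factor (310 fgC µm⁻³) is a convention; absolute
  biomass-derived quantities (CD_d, CP_tot) scale inversely with it. All
  outputs record the conversion used.
* `CP_tot` depends on the segment discretisation through the trapezoid rule
  (exact only for BSP linear within segments) and on the upstream-biomass
  convention.
* The endpoint turnover estimator is sensitive to the two endpoint samples;
  the multisite estimator is provided for robustness.
* GAM-style smooths here are single-covariate penalized splines per
  phylotype and dataset; factor-smooth interactions across datasets are out
  of scope, and fits are per-dataset independent.
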