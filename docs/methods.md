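# Methods

## Scope and design

`pbudget` implements the accounting and statistical layer of an ecosystem
phosphorus budget for a two-treatment FACE experiment.  The pipeline begins
at measured concentrations, masses and extract pairs; laboratory chemistry
(digestion, ICP-MS, colorimetry) and the upstream biomass/carbon estimation
are outside its scope — biomass, GPP and NPP enter as input columns.  There
is no mechanistic P-cycle simulation anywhere: the synthetic generator
reproduces the *statistical* structure of the measurements, and the budget
module applies deterministic accounting rules to them.

All accounting happens in `budget.compute_budget`, which both the
generator's closed-form truth and the table-reduction pipeline call.  The
mass-balance identities (demand = Σ production; uptake = demand −
resorption; layer additivity; organic + inorganic = total) therefore hold on
both paths by construction, and the pipeline-vs-truth test checks the table
plumbing, not the identities.

## Aggregation principle

Sub-replicates (litter traps, soil subplots, trees) are averaged to a plot
value per sampling date; repeated flux measurements are annualized within
calendar years from their dated intervals (interval sums rescaled by
365/covered-days, which also normalizes leap years); multi-year values are
averaged per plot; treatment means and SDs are computed across plots
(n = 3).  Aggregated variables are summed within a plot before the
cross-plot SD is taken, so their SDs reflect between-plot covariance.

## Accounting parameters

| parameter | default | unit | role |
|---|---|---|---|
| fumigation extraction efficiency k_EP | 0.4 | – | microbial P from extract pairs |
| fine-root resorption coefficient | 0.5 | – | live/dead fine roots are not separable |
| drainage water efflux | 20 | mL m⁻² d⁻¹ | leaching from lysimeter phosphate |
| atmospheric P deposition | 0.002 | g P m⁻² yr⁻¹ | openness summary only; regional-deposition scale value, configurable |
| tissue carbon fraction | 0.48 | g C g⁻¹ | C:P ratios |

Bark, twig, branch and reproductive tissue are assigned the sapwood P
concentration; coarse roots use sapwood P for pools, production and
resorption; standing dead wood uses the plot's live sapwood/heartwood
partitioning.  The mean-residence-time numerator is canopy + sapwood +
fine-root + understorey P ("standing vegetation", excluding heartwood,
coarse root, litter and standing dead); this definition reproduces a 2.7-yr
ambient residence time consistent with the published component pools.
P-use efficiency for growth is NPP/uptake (the unit g C g⁻¹ P forces this
orientation of the ratio).

Degenerate inputs are handled with flags rather than silent edits: negative
fumigation differences are clamped to zero (counted per plot), Hedley
residuals are floored at zero with a flag, senesced-above-green resorption
fractions are clamped into [0, 1] with a flag, negative uptake is retained
with a warning, and organic P (defined by difference) may go negative under
noise — flagged, but retained so the organic + inorganic = total identity
survives exactly.

## Synthetic site

The generator emulates the sampling design: monthly litterfall and frass
from 8 traps, quarterly surface soil chemistry and incubations in the first
three years, fumigation pairs in years 2–3, one deep-profile campaign
(all three layers, plus soil C) in the second-to-last year, monthly
lysimeter samples in years 1–4, annual biomass and carbon-flux records.
Dates carry no trend: treatment effects are time-constant multipliers.

Noise is multiplicative and two-level: one zero-truncated normal factor per
plot and parameter (between-plot CV as configured), and one per record at
half the plot CV (`subreplicate_cv_ratio`, a free choice — within-plot
variance is not separately constrained by the published summaries).  A
mean-preserving lognormal is available as an alternative.  Plot factors are
drawn once from a dedicated substream and shared across tables (the same
plot's labile P drives its soil chemistry, unfumigated extracts and
incubation baselines); each table's record noise has its own substream, so
generating a subset of tables never changes another table's draws.

Default parameter means are calibrated so the closed-form expected budget
reproduces the published ambient values exactly: pools of 0.23 (canopy),
0.36 (sapwood), 0.30 (heartwood), 0.24 (fine root), 0.15 (coarse root),
0.23 (understorey), 0.06 (floor litter), 0.04 (standing dead) g P m⁻²;
soil 31.8 = 25.1 organic + 6.7 inorganic; microbial 5.97; labile 1.15;
demand 0.71 = resorption 0.32 + uptake 0.39 g P m⁻² yr⁻¹; net
mineralization 0.67; frass 0.04 (14% of canopy production); canopy
resorption fraction 55%.  Where a free choice was needed the understorey
resorption fraction (29/70) closes total resorption at 0.32, and the
sapwood/heartwood contrast (0.08 vs 0.04 mg g⁻¹) sets the woody resorption
fraction to 0.5.  Between-plot CVs are back-computed from published SD/mean
ratios where available (e.g. soil P 5.7/31.8 ≈ 18%) and set to
field-plausible values elsewhere; the standing-dead CV is capped at 0.5
because the zero-truncated model is strongly biased as CV → 1 (the
truncation bias is < 0.1% at CV ≤ 0.3 and ~3% at CV = 0.5, which the
unbiasedness test at CV = 0.1 does not probe).

CO₂ multipliers are keyed by budget variable and folded into the primitive
parameter means so that mass balance survives: a `demand` multiplier scales
every production stream (resorption and uptake scale with it); an `uptake`
multiplier scales the non-resorbing production components (branch, bark,
twig, reproduction), which feed uptake one-for-one, so demand absorbs the
increment and demand = resorption + uptake still holds — one cannot move
uptake while holding both demand and resorption fixed.  When both are
targeted, demand is applied first and uptake takes precedence for its own
value.  Multipliers on variables that cannot be realized in measurements
without breaking an identity (e.g. residence time) are rejected.

What passing tests on this synthetic site do **not** show about real data:
the generator has no temporal trends or autocorrelation, no spatial
structure within plots, no correlated measurement error across variables
beyond the shared plot factors, and lognormal/truncated-normal noise may
understate field outliers.  Calibration results (coverage, null rates)
transfer to real data only insofar as plot-level values are approximately
normal.

## Statistical machinery

Effects are differences of treatment means with pooled SD
√((SD²_amb+SD²_ele)/2), SEM = SD_eff·√(1/n₁+1/n₂), and two-tailed t
intervals at 75/85/95% with n₁+n₂−2 df.  The bootstrap resamples values
with replacement within each arm (percentile intervals; the resampling unit
is whatever the caller passes — plot values in the pipeline, raw records
for sensitivity).  No multiple-testing correction is applied across budget
variables, deliberately mirroring the evidence-based, interval-centred
reporting the design calls for.  A linear mixed-effects confirmation
(CO₂ × year with plot as random effect) is not reimplemented;
`effects.lmm_long_table` emits a model-ready long table for external tools.

The coverage, null-calibration and recovery harnesses sample the
generator's *plot-level* distribution directly (plot factors only), because
thousands of simulated experiments are needed; sub-replicate noise averages
out in plot means and the full table pipeline is separately shown to be an
unbiased estimator of the same distribution.  Measured behaviour at the
design size: t intervals are nominal (95.5% at the 95% level over 400
simulations); percentile-bootstrap intervals are nominal at 50 plots per
arm but undercover at 3 per arm (~0.80 at the 95% level) — with three
values per arm there are only 3³ distinct resamples, a structural
limitation of the percentile method rather than an implementation artifact,
which is why the bootstrap is positioned as a sensitivity test, not the
primary interval.  Under no effect, ~5% of variables are flagged at 95%; a
configured +8% uptake effect is recovered in expectation (the 3-plot ratio
estimator adds a small positive bias) but detected at 95% in only ~15% of
experiments.

## Numerical choices

Closure identities are checked at 10⁻⁹ g P m⁻² (they are exact by
construction; the tolerance guards floating error in long sums).  Problem
sizes in the shipped analysis and acceptance scripts — 400 coverage
simulations, 500 null-calibration experiments, 300 recovery experiments,
300–400 bootstrap resamples inside simulations (1000 in the pipeline
default) — put binomial Monte-Carlo error near ±1 percentage point on
coverage estimates, which matches the granularity of the claims made.
Reported tables round to 3 significant figures; tests compare unrounded
values with explicit tolerances.

## Known limitations

- Organic P by difference inherits the noise of two extracts; its per-layer
  value can be negative in noisy draws (flagged).
- Depth extrapolation of net mineralization assumes proportionality to soil
  C; the deep-campaign concentration ratios for labile and microbial P are
  single-date estimates and thus noisy scalers.
- The generator's elevated arm shares no plot-pairing with the ambient arm
  (a completely randomized design); blocked designs would need paired
  factors.
- Percentile-bootstrap intervals should not be trusted at n = 3 (see above).
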