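# Methods

This note records the statistical procedures implemented in `trailcam`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer would want spelled
out.

## Events and relative abundance

Photographs of one species at one station are collapsed into *independent
events*: a photo starts a new event when its gap to the reference photo
exceeds `gap_minutes` (default 60, strictly greater).  Two readings of the
rule exist and both are implemented: the default **chained** rule measures
the gap from the immediately preceding photo of the series (the common
camera-trap convention); the **anchored** rule measures it from the first
photo of the current event.  They differ only when a burst of activity
spans more than the gap.  Independence is applied per station and per
species; a photo of species A never resets species B's clock.

The relative abundance index is RAI = 100 · n_events / effort_days, with
effort in fractional days (deployment span minus downtime) and rounding
applied only at report time.  Survey-level RAIs pool the events and the
effort of all member stations before taking the ratio; under unequal
station effort this is *not* the mean of station RAIs, and the pooled form
is the one used throughout.  Species with zero events are retained with
RAI 0 so that detected/not-detected distinctions downstream come from the
event record, not from missing rows.  `infer_effort` inverts the
definition (effort = 100·n/RAI) to recover the camera-day effort behind a
published (events, RAI) pair; applied to the bundled summary it yields
2 843 / 2 820 / 2 347 / 2 557 camera-days for the four surveys (10 567 in
total), using the median inversion across high-count species so no single
printed rounding dominates.

## Richness and composition

Sampling units are stations.  The analytic rarefaction expectation
E[S(t)] = S_obs − Σᵢ C(T−Yᵢ,t)/C(T,t) is exact for draws without
replacement and serves as the oracle for the bootstrap.  Confidence bands
come from a station bootstrap: each of B = 200 replicates draws T stations
with replacement and accumulates distinct species along the drawn order;
bands are mean ± 1.96 sd across replicates.  The mean of this procedure
converges to Σᵢ(1−(1−Yᵢ/T)ᵗ) (draws *with* replacement), slightly below
the analytic curve at interior t — both forms are exposed, and the tests
hold the bootstrap to its own closed form.  Percentile bands and an
analytic unconditional-variance band (Chao2 plug-in) are natural extension
points; mean ± 1.96 sd was preferred because 200 replicates make
percentile tails noisy.  Chao2 is the bias-corrected incidence form
S_obs + ((T−1)/T)·Q₁(Q₁−1)/(2(Q₂+1)).

The station axis is converted to camera-days by t · (total effort)/T
(mean effort per station); curves are compared at the lower of the two
surveys' total efforts, and `min_overlap_effort` reports the smallest
effort from which the 95% bands overlap continuously up to that point,
interpolating linearly between integer t.  Composition uses Jaccard
dissimilarity on detection sets and the percentage of species detected by
only one survey; the denominator of that percentage is a caller-supplied
species total (typically the overall richness across all surveys), which
can exceed the union of the two seasonal detection sets.

## Rank abundance structure

RADs are built from survey-level RAIs sorted nonincreasing (ties keep
stable input order).  Five models are fitted:

| model | form | free parameters |
|---|---|---|
| null (broken stick) | a_r = (J/S)·Σ_{k=r}^S 1/k | 0 |
| preemption | a_r = J·α(1−α)^{r−1}/(1−(1−α)^S) | α ∈ (0,1) |
| lognormal | a_r = exp(μ + σ·z_r), z_r = Φ⁻¹((S−r+0.5)/S) | μ, σ ≥ 0 |
| Zipf | a_r = J·p₁·r^γ | p₁ > 0, γ ∈ (−5,0) |
| Zipf–Mandelbrot | a_r = J·c·(r+β)^γ | c > 0, β ∈ (0,100), γ ∈ (−5,0) |

Fitting minimises the sum of squared deviations between observed and
predicted abundances — the deviance criterion — **on the log abundance
scale by default**.  Dominance/diversity curves are conventionally drawn
and fitted on log abundance; on the raw scale the criterion is dominated
entirely by the one or two most abundant species and the flexible Zipf
forms win by matching the head while ignoring the tail.  The raw scale
remains available as `scale="identity"`.  Optimisation is bounded
multi-start nonlinear least squares (trust-region reflective; α starts at
{0.05,…,0.9}, β starts spread over (0.01,…,80), Zipf forms initialised
from log–log regression); the Zipf–Mandelbrot surface is ill-conditioned
in β, hence the spread of starts.  A model that fails every start is
returned flagged with infinite deviance rather than raising.  Selection
takes the smallest deviance, ties going to the model with fewer
parameters.  The lognormal rank-quantile convention z_r uses offset 0.5;
alternative offsets differ by O(1/S).

On the bundled data the lognormal wins three of the four surveys (dry
random 0.9 against Zipf–Mandelbrot 3.3; dry trail 1.6 vs 2.8; wet trail
2.0 vs 3.2) but not the wet random survey (4.9 vs 2.8), whose RAD has a
two-species co-dominance (elephant RAI 48.8, impala 42.4 per 100 days)
followed by a steep drop to 6.1 — a shape outside the lognormal family
that the extra Mandelbrot parameter absorbs.  This holds under every
subset and fitting scale tried, so the package reports the selection as
computed rather than forcing a uniform winner.

### Species subset

Structure analyses use species robust enough to rank.  The default rule
(`detected_rule="common"`) keeps species detected by both placement types
in **every** season with at least `min_events = 5` events in each season,
giving one common species set so ranks are comparable across seasons and
placements; on the bundled data this yields 30 species (9 carnivores,
12 herbivores, 4 insectivores, 5 omnivores).  Two alternative readings are
implemented: `"season"` (detection within the analysed season, threshold
on the overall total; 35/33 species) and `"overall"` (both pooled; 37).

### Rank shifts

MARS is the mean over species of |rank difference| between the two
surveys' RAI rankings, with average ranks for ties (which makes the
statistic well-defined and symmetric; tie treatment is otherwise
arbitrary).  Departure from zero is tested with a one-sample Wilcoxon
signed-rank test applied to the absolute shifts, as the statistic is
defined; since the shifts are nonnegative, every nonzero shift is positive
and V equals the full rank sum m(m+1)/2 of the m nonzero shifts — the test
is one-sided in nature and its p-value should be read as "some shift
exists", not as a direction.

### Signed-rank test

Authored here to a single contract used by both the MARS test and the
paired comparisons: zeros dropped, average ranks on |d|, V = sum of ranks
of positive differences.  For n ≤ 15 the null distribution is exact by
enumeration of sign patterns — ranks are doubled to integers so tied
(half-integer) average ranks convolve on an integer lattice — and the
two-sided p is 2·min(P(W≤V), P(W≥V)) capped at 1.  Beyond 15, a normal
approximation with tie correction (−Σ(t³−t)/48 in the variance) and
continuity correction is used; at n = 20 it agrees with the exact value to
well under 0.01.

## Trail preference

Per species, paired differences d = RAI(random) − RAI(trail) are formed
within sampling pairs.  Zero differences are dropped (standard signed-rank
convention).  The *location shift* is the Hodges–Lehmann pseudomedian
(median of Walsh averages), with a 95% confidence interval from order
statistics of the Walsh averages at the signed-rank critical value (exact
null quantiles up to n = 25, normal approximation beyond); this is the
standard paired signed-rank CI output and matches R's
`wilcox.test(conf.int=TRUE)` on untied data.  A plain mean-difference
summary would be less robust to the heavy-tailed RAI differences.  A
species scores 1 when its interval lies entirely below zero (trail
significantly higher); fewer than 5 informative pairs flags the result
low-power and forces score 0.  No multiple-testing correction is applied
across species — each species' test is reported as its own comparison — and
the scoring step also reports whether any species was significantly higher
at *random* placements.

The binary scores are modelled with a binomial GLM (logit link, treatment
coding, first category reference) over nine candidate predictor subsets of
{trophic category, log body mass, sociality, trophic × log mass}, fitted
by IRLS via statsmodels and selected by AIC = −2ℓ + 2k (ties to fewer
parameters).  For a single categorical predictor the back-transformed
fitted probabilities equal the per-category score proportions exactly (the
saturated one-factor identity), which anchors the unit tests.  Complete
separation is detected as |coefficient| > 15 on the logit scale and
flagged rather than raised.

## Synthetic generator

The generator emulates the paired design: n_cells cells (default 54), one
random and one trail deployment per cell per season, seasons as
label → days maps (default two 56-day seasons, i.e. 8 weeks).  Species
encounter a station as a homogeneous Poisson process at `base_rate`
(random placement) or `base_rate × trail_multiplier` (trail), optionally
scaled by a per-season rate multiplier; each encounter emits 1–5
photographs (the common five-frame trigger) at distinct whole seconds
inside a 2-minute burst window; downtime removes one contiguous block of
`downtime_fraction` of the deployment (default 5%) and reduces recorded
active days accordingly.  Default traits: trophic mix 30/40/13.3/16.7%
(the reference community's composition), body mass lognormal around 20 kg
spanning mongoose to elephant, base rates lognormal around 0.01/day
(RAI ≈ 1), carnivores with a threefold trail preference and
insectivores/omnivores 1.5×.

Encounter starts within a station–species series are kept more than
gap + burst-window apart by sequential thinning of the Poisson draw, so
the number of filtered events equals the number of simulated encounters
*exactly* — an exact oracle for the independence filter.  The cost is a
hard-core bias in the realised rate of roughly rate × 65 min (≈ 2% at
0.5 encounters/day, negligible at typical rates), which the rate-recovery
tests absorb within Monte-Carlo error.  Not emulated: animal movement and
home ranges (encounters are independent across stations), detection
distance and imperfect detection, species misidentification, and spatial
correlation between neighbouring cells.  Passing recovery tests therefore
show the inference chain is correct and well-calibrated under the stated
sampling model, not that field data meet that model.

The recovery experiments (`trailcam.experiments`) use 54 pairs × 52 days ≈
2 800 camera-days per survey — the scale of the motivating design — with a
common base rate of 0.05 encounters/day (RAI 5, a representative common
species) so that per-species power reflects the design rather than rate
heterogeneity; replicate counts (6–10) keep the full suite and the
acceptance script within a couple of minutes on one CPU while leaving
binomial error well inside the asserted margins.

## Degenerate inputs and tie-breaks

All-zero difference vectors return V = 0, p = 1, score 0, flagged
degenerate.  Zero-abundance species in a requested RAD subset are dropped
with a warning.  RAD ties keep stable input order; rank ties take average
ranks.  AIC and deviance ties go to fewer parameters.  Effort ≤ 0 is a
hard error naming the station.  Empty photo tables flow through every
reader and the filter as empty results, not errors.
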