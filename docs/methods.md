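# Methods

This note documents the models, defaults and design choices behind
`chronoscreen`, in the order data flows through the pipeline.

## The synthetic screen generator

The generator emulates a competitive CLS screen on a pooled haploid
deletion collection: two replicate pools seeded identically, aged in the
same medium, sampled at days 3, 9, 11, 15 and 20 with day 3 defining 100%
survival. It exists so every downstream stage can be tested against planted
ground truth; its defaults are the package's statement of the study
conditions.

**Survival model.** Strain *s*'s viable count follows a Boltzmann sigmoid
normalized to 1 at the reference day,
n_s(t) = N₀ · f(t; t50_s, τ) / f(ref; t50_s, τ) with
f(t) = 1/(1 + e^{(t − t50)/τ}). The same function is the survival module's
fit model, which makes parameter recovery exact in the noiseless limit (the
zero-noise consistency check measures deviations ≈ 1e-13).

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| `timepoints` | 3, 9, 11, 15, 20 d | the screen's sampling days |
| `reference_day` | 3 d | day of peak density; 100% survival convention |
| `n_replicates` | 2 | two replicate pools |
| `pool_t50_mean` | 11 d | pool falls through ~50% between days 9 and 15 |
| `pool_t50_sd` | 0.75 d | strain-to-strain scatter of unaffected strains; sized so the neutral population stays essentially inside the ±0.5 log₂ class boundary, matching a screen in which ~15% of strains classify as lifespan-altered and the rest cluster flat |
| `slope_tau` | 2 d | gives survival curves spanning 100%→~1% over the sampled window |
| `frac_short`, `short_t50_multiplier` | 0.12, 0.5 | ~594/4800 short-lived; deletions that halve the midpoint |
| `frac_long`, `long_t50_multiplier` | 0.01, 1.8 | ~42/4800 long-lived |
| `noise_sigma` | 0.3 | lognormal per-measurement noise; intensities are positive and multiplicative error is the standard microarray assumption |
| `tag_affinity_sigma` | 0.5 | per-tag hybridization efficiency spread (constant per tag, cancels in log-ratios) |
| `frac_background_tags` | 0.10 | ~10% of tags hybridize at background |
| `background_level` | 20 (a.u.) | ~10% of a typical strain's signal at the default scale |
| `p_regrow`, `regrow_day`, `regrow_gain` | 0.01, 12 d, 5× | occasional adaptive regrowth producing the day-12–15 CFU bump |
| `cfu_jitter_sigma` | 0.02 | small lognormal error on plate counts |

Regrowth is modelled as a step gain in viable count from `regrow_day` on —
the simplest mechanism that reproduces a late CFU bump and the
longevity-mimicking inflation of a regrower's barcode signal; renewed
exponential growth is deliberately not modelled. Outgrowth before tagging
is assumed proportion-preserving (equal growth rates across strains).
Sampling (multinomial) noise at DNA extraction is folded into
`noise_sigma` rather than modelled separately.

**What the generator does not emulate:** PCR amplification bias, array
spatial artifacts, cross-hybridization between tags, strain-specific
outgrowth rates, and death–regrowth feedback through released nutrients.
Tests passing on synthetic screens therefore demonstrate the *analysis* is
correct under the stated error model, not that real arrays satisfy it.

## Profiles and quality control

Arrays (one per replicate × day) are rescaled to the grand mean of array
means; any common target yields identical log₂ ratios downstream, and the
grand mean keeps values in input units. Uptag/downtag are combined by
geometric mean (arithmetic mean of logs, matching multiplicative error);
a tag flagged at background is dropped and the other used alone. Whether
the original analysis normalized before or after combining tags is not
documented; we normalize first.

Profiles are r_{s,t} = log₂(I_{s,t}/I_{s,ref}); a zero or missing
reference-day intensity masks the strain in that replicate with a reason
code — missing data are never silently dropped.

Exclusions run background-first, RSME-second. "Background" is
operationalized as combined intensity < k·background_level (k = 2 default)
at *every* sampled day in either replicate; one day of clear signal rescues
the strain. The RSME threshold is the nearest-rank 90th percentile (value
at position ⌈0.9·n⌉ of the sorted values) — a reproducible integer cutoff —
with strict inequality for exclusion so threshold ties are retained. The
RSME averages over non-reference days only, since the reference column is
identically zero in both replicates and would dilute the statistic.

## Classification

K-means uses the non-reference-day columns of the averaged profiles
(the reference column carries no information). Lloyd's algorithm with
Euclidean distance, 20 restarts seeded from one generator, empty clusters
re-seeded from the point farthest from its centroid, ties between restarts
broken by lowest within-cluster SS then lowest restart index; strains are
processed in sorted-id order, so results are independent of input row
order. The original screen labelled clusters by manual inspection of the
plots; here the boundary is explicit — a cluster is short/long when its
centroid's mean over non-reference days crosses ∓θ (0.5 log₂ units, a
sustained ~1.4-fold change), matching the horizontal boundary such plots
are judged against. θ is configurable; the exact thresholds that would
reproduce the original manual counts are unrecoverable.

A caveat inherent to competitive screens: relative abundance is
zero-sum. When long-lived strains dominate the late pool, every other
strain's share falls, and sufficiently large planted long fractions push
truly neutral strains across the short boundary. The class calls measure
representation relative to the pool, not absolute survival — which is
exactly why the pipeline also reconstructs absolute survival curves.

## Time-course significance

The statistic is the raw RSS ratio F = (RSS₀ − RSS₁)/(RSS₁ + δ) of a flat
fit versus a natural cubic spline fit (df = min(3, T−2) by default,
interior knots at day quantiles), computed on both replicates' observations
stacked — a trend must be shared across replicates to reduce RSS₁. No
degrees-of-freedom scaling is applied because calibration comes from the
permutation null, not an F distribution; δ = 1e-8 guards exact
interpolation and F is capped at 1e12.

The null permutes day labels within each replicate, shared across strains
(preserving cross-strain dependence) and pooled across strains (5 time
points admit only 120 distinct permutations — far too few per strain). The
**reference day stays pinned**: its log₂ ratio is identically zero by
construction, so the full label set is not exchangeable, and permuting the
reference position measurably biases the null (an observed-versus-null rank
test rejects on all-null data with full permutation and accepts with the
reference pinned). Empirical p = (1 + #{null ≥ F})/(1 + |null|);
q-values use the step-up running minimum with a fixed-λ π₀ (λ = 0.5,
robust at m ≈ 4×10³; a smoother estimator was judged unnecessary).

On all-null synthetic screens (2,000 strains, noise 0.3, B = 200, 10
seeds) the mean q ≤ 0.1 call rate is ~10⁻⁴, far under the 0.12 design
bound. On screens with planted effects (1,000 strains, 50 long ×1.8, 100
short ×0.5, noise 0.3, no regrowth — the benchmark plants exactly the
effects it scores) the pipeline recovers planted long-lived strains with
precision ~1.0; recall (~0.9 typical) is bounded by the QC rules
themselves, which always discard the top RSME decile, so the benchmark
reports the median over three screens to average over the random overlap
between that decile and the 50 planted strains.

## Survival curves and mean lifespan

Estimated CFU = 2^r × pool CFU, with pool CFU averaged across replicates
(per-pool curves are also written); percent is relative to the reference
day. The Boltzmann fit initializes top = max, bottom = min, t50 = the
sampled day nearest the half-range level, τ = span/8, and optimizes within
bounds (τ > 0, t50 within the sampled range ± 10 d); fits whose midpoint
lands outside the sampled days are flagged `extrapolated` rather than
rejected, and flat (< 5% range) or monotone-increasing curves are flagged
degenerate and not fitted. Mean lifespan is the 50%-of-initial crossing of
the fitted curve — not the midpoint parameter — because curves are
normalized to 100% and the two differ whenever bottom ≠ 0; both are
reported. Under 5% multiplicative noise at the 5-day grid the median |t50
error| is ≈ 0.2 days.

## Enrichment

Direct annotations only; no ontology-graph ancestor propagation (it depends
on an ontology release — users may pre-propagate). Bonferroni over the
terms actually tested (k ≥ 1), significance at adjusted p < 0.01. The
universe defaults to the annotation's gene set and is restrictable to the
assayed/retained strains; published relative-vs-background frequencies
depend on the annotation release and are not comparable across releases.

## Reproducibility

One config seed fans out to per-stage child seeds by fixed offsets; rerun
reports are bit-identical up to wall-time fields. `scripts/acceptance.py`
recomputes every validation quantity from scratch at runtime (problem
sizes: 2,000-strain null screens × 10 seeds, three 1,000-strain recovery
screens, 100-curve fit recovery, 50-strain zero-noise consistency).

## Known limitations

- Exactly two replicates are supported where replicate concordance (RSME)
  is involved.
- The permutation null treats non-reference days as exchangeable under the
  null; systematic day effects shared across all strains (e.g. batch
  effects per array) are absorbed by mean normalization only to first
  order.
- Class boundaries (θ) and the background factor (k) are screen-dependent
  knobs; the defaults suit the simulated design and should be inspected on
  real data.
- Mean-lifespan estimates extrapolate whenever a strain's 50% crossing
  falls outside the sampled window; the `extrapolated` flag should be
  honoured in downstream use.
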