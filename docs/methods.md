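# Methods

## Survival estimation

Each subgroup's survival function is estimated with the Kaplan–Meier
product-limit estimator. Observations are pairs (tᵢ, eᵢ) of a non-negative
follow-up time and an event indicator (1 = death, 0 = right-censored). At a
tied time, deaths are processed with every case observed at that time still
at risk (the standard convention); jumps occur only at distinct event times,
and a subgroup with no events has the constant-1 curve. The estimate is a
right-continuous, non-increasing step function with S(0) = 1. The estimator
is implemented as a small vectorized routine because the cutoff search below
performs tens of thousands of fits per case base; the test suite
cross-checks it against lifelines' `KaplanMeierFitter` and against an
exhaustive hand product-limit oracle on all small cohorts.

## Area between survival curves

The dissimilarity of two values of one attribute is the signed area between
their survival step functions on [0, T],

ABS(T | v, v*) = ∫₀ᵀ [S(t|v) − S(t|v*)] dt,

computed exactly by rectangle summation over the merged jump grid. The
implementation is antisymmetric to the bit (each rectangle term negates
exactly), additive over partitions of [0, T], and bounded by T. The horizon
T defaults to the largest observed time in the training data; all curves are
extended constantly beyond their last jump.

**Time normalization.** The local similarity is exp(−|ABS|). With time
measured in days, |ABS| is of order 10²–10³ and the exponential collapses to
0 for every distinct value pair; the package therefore divides areas by T
before the exponential map (equivalent to rescaling time to [0, 1]). This is
monotone, preserves all per-attribute comparisons, and keeps similarities on
a usable scale for any time unit. A raw-area mode is available
(`ModelConfig(normalize_time=False)`). Weights are ratios of areas, so they
are unaffected either way.

## Training pipeline

1. *Optional pooling*: nominal values carried by fewer than
   `min_value_count` cases are pooled into a reserved label; few-case values
   produce rough, unreliable step curves. Off by default.
2. *Dichotomization*: every numeric attribute is converted to two nominal
   levels at the cutoff c maximizing WF(c)·|ABS(T | a≤c, a>c)|, where
   WF(c) = (p(1−p))^q and p is the fraction of non-missing values ≤ c.
   Candidates are the distinct observed values except the maximum (both
   groups always non-empty); missing values are excluded from p's
   denominator and from both groups; ties break to the smallest cutoff. The
   smoothing exponent defaults to q = 2; q = 0 disables smoothing, in which
   case spurious |ABS| peaks at extreme, tiny-group cutoffs tend to win —
   that failure mode is exactly what WF exists for.
3. *Survival functions*: one Kaplan–Meier curve per observed value of every
   (now nominal) attribute. Attributes left with fewer than two observed
   values are excluded with a warning.
4. *Local tables*: all pairwise |ABS| values and similarities
   exp(−|ABS|/T) are precomputed, so retrieval is a table lookup. Identical
   values score 1; an unknown (missing, or never seen in training) value
   scores 1 against anything, with a warning for unseen values — retrieval
   must not crash on a new patient.
5. *Weights*: ω_A = max pairwise |ABS| divided by ABS_norm, the area between
   the constant-1 curve of the alive subgroup and the Kaplan–Meier curve of
   the deceased subgroup. ω is not clamped: a value isolating only the
   earliest deaths can exceed 1 in finite samples, which is logged.
6. *Feature selection*: attributes with ω below `feature_threshold` are
   dropped. Default 0 (off).

The global similarity is sqrt(Σ (ωᵢ·simᵢ)²) over the retained attributes.
Because the local similarities already encode survival impact, the survival
weights are not reused inside this formula by default (ωᵢ = 1; survival
would count twice); `use_weights_in_global=True` enables them for use with
non-survival local measures. The literal formula yields scores up to
sqrt(Σωᵢ²) > 1; rankings are unaffected, and `normalize_global=True`
rescales to [0, 1]. Retrieval ranks all other cases by global similarity,
ties broken by ascending case id, and is deterministic and independent of
record order.

## Benchmark measures

HEOM: overlap distance on nominal attributes, range-normalized absolute
difference on numeric attributes capped at 1 outside the training range,
distance 1 for unknown values, Euclidean aggregation. (Its unknown-value
convention — maximal distance — is the opposite of the survival measure's
maximal similarity; each measure follows its own literature.) DVDM: numeric
attributes binned into 5 equal-width intervals over the training range;
per-value class-conditional probabilities P(class | value) estimated by
relative frequency; per-attribute distance Σ_c |P(c|v₁) − P(c|v₂)|²,
Euclidean aggregation; unknown values score distance 0. Its class attribute
defaults to the therapy arm — randomized by design, which is precisely why a
class-based measure fails on trial data. Random pick draws k candidates
uniformly without replacement under a seed.

## Synthetic trial generator

The generator emulates a two-arm randomized trial with planted biomarkers:
1000 cases randomized 1:1; 24 survival-neutral noise attributes (six each
from the normal(50, 10), exponential(1), Weibull(1.5, 1) and uniform(0, 1)
families — the shapes matter downstream, the parameters mostly do not,
since similarity measures range-normalize); per arm one numeric biomarker
(equal-weight mixture of normal modes at 80 and 120, sd 5 — "present" means
drawn from the 120 mode) and one nominal biomarker (Bernoulli prevalence
0.3, labels present/absent). Event times are exponential with mean 1.0 on a
scale where the administrative censoring horizon is 1.0; additionally a 0.2
fraction of cases receives an independent uniform(0, horizon) censoring
time. A biomarker that is present in a case of its matching arm multiplies
the event time by 3.0; several active biomarkers multiply independently.
Effects are arm-conditional (predictive biomarkers) by default,
`arm_conditional=False` makes them prognostic; both variants leave the two
arms with equal overall survival by symmetry. Ground truth per case is the
generating draw itself — mode membership for numeric biomarkers, never a
post-hoc threshold — so evaluation cannot reward the model with its own
discretization.

The mixture weight 0.5 and prevalence 0.3 are calibrated so that a uniform
random retriever matches biomarker status at the analytic rate
p² + (1−p)² ≈ 0.50 and 0.58 respectively, which anchors the chance floor of
the benchmark.

**What the generator does not emulate.** Real trial data have correlated
attributes, measurement error, missingness, inclusion-criteria bias and
multi-attribute subtypes; the generator has none of these, so passing
benchmarks here demonstrates correct mechanics and the intended ordering of
measures, not clinical performance. Two structural properties of this
particular design are worth knowing. First, the four biomarkers are frequent
(0.5/0.3 per arm) and act multiplicatively on overlapping subsets, so each
attribute's *marginal* survival contrast is diluted to roughly 0.09–0.11
area units against ABS_norm ≈ 0.55 — biomarker weights land near 0.15–0.2
and exceed the noise weights (≈ 0.06, the selection bias of scanning ~10³
cutoffs) by a factor of ≈ 2.4 rather than by the larger separations a
sparser or stronger effect design would produce. Second, with exactly two
binary nominal attributes among 26 numeric ones, HEOM's nominal mismatch
penalty dominates its distance, so HEOM matches the nominal biomarkers
almost perfectly here; benchmark conclusions about HEOM are therefore
design-dependent.

## Evaluation harness

Leave-one-out with an urn model: the model is trained once on the full case
base, every case in turn queries its k = 10 nearest neighbours (query
excluded, case base never depleted). Per-fold retraining is available via
the harness's retriever hook but is not the default. For each biomarker the
(query status, neighbour status) pairs are pooled into a confusion table
with "present" as the positive class; accuracy, precision, recall and F1
are computed per case base and then averaged (sample SD) across the
repeated case bases. Undefined precision/recall (zero denominator) is
recorded as NaN and excluded from means with a warning. The weight report
lists per-iteration averages over all attributes, noise attributes and each
biomarker, scaled by 10 for readability with relative differences in
percent — the scaling cancels in every ratio.

## Numerical and design notes

- Areas are exact rectangle sums; no quadrature tolerances enter anywhere.
- Cutoff ties break to the smallest candidate; retrieval ties to the
  ascending case id — both make every pipeline stage order-independent and
  reproducible.
- The acceptance script and benchmark tests use ten case bases of 1000
  cases with seeds base…base+9; examples use 300–1000 cases, chosen to keep
  each script in the seconds-to-one-minute range.
- Models serialize to a single JSON file (schema, config, cutoffs, curves,
  tables, weights); a load returns bit-identical retrievals.
- Missing survival time or status is a hard error at read time; outcome
  imputation is out of scope.
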