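# stsm — survival-time-based similarity for clinical case retrieval

`stsm` implements a similarity measure for case-based reasoning (CBR) on
clinical survival data. It is aimed at settings such as randomized controlled
trials, where the classic solution attribute "applied therapy" is randomized
and therefore useless for learning similarity, but overall survival — the
outcome that actually matters for fatal diseases — is recorded for every
case. Instead of asking experts to hand-craft local similarity matrices and
attribute weights, the measure learns both from the survival behaviour of the
case base itself.

## The measure

For every value *v* of an attribute, the survival function S(t | v) of the
cases carrying *v* is estimated with the Kaplan–Meier product-limit estimator
(right-censored observations, right-continuous step function). Two values of
one attribute are compared by the **area between their survival curves** up
to a horizon T:

    ABS(T | v, v*) = ∫₀ᵀ [ S(t | v) − S(t | v*) ] dt

computed exactly as a sum of rectangles over the merged jump grid. From this
single quantity the whole measure follows:

- **Local similarity**: sim(v, v*) = exp(−|ABS|) ∈ (0, 1], with 1 for equal
  or unknown values. By default areas are rescaled by 1/T so the exponential
  stays informative regardless of the time unit.
- **Attribute weights**: ω_A = ABS_max,A / ABS_norm, where ABS_max,A is the
  largest pairwise area of attribute A's values and ABS_norm the area between
  the alive and deceased subgroups — the strongest survival separation the
  case base admits. Weights above a threshold drive **feature selection**.
- **Numeric attributes** are dichotomized first: every unique value c is a
  candidate cutoff, scored by WF(c)·|ABS(T | a≤c, a>c)| with the smoothing
  weight WF(c) = (p(1−p))^q, p the fraction of values ≤ c. Smoothing (q = 2
  by default) suppresses spurious area peaks from tiny groups.
- **Global similarity** of two cases aggregates the local similarities as
  sim_global = sqrt( Σᵢ (ωᵢ · simᵢ)² ). The survival weights default to
  ωᵢ = 1 inside this formula (survival information would otherwise count
  twice); they remain available for feature selection, reporting, or for
  weighting non-survival local measures.

The package also ships the benchmark apparatus around the measure: HEOM and
DVDM reference metrics plus a random-pick baseline, a synthetic two-arm trial
generator with known numeric/nominal biomarkers, and a leave-one-out
biomarker-detection harness (urn model, k nearest neighbours, pooled
confusion metrics).

## Worked example

```python
from stsm import GeneratorConfig, STSMRetriever, generate_case_base, train

config = GeneratorConfig(seed=42)          # 1000 cases, 28 attributes
cb, truth = generate_case_base(config)
model = train(cb)
print({b: round(10 * model.weights[b], 2) for b in config.biomarker_names})
res = STSMRetriever(model, cb).retrieve("case_0001", k=10)
```

Running `python examples/03_train_and_retrieve.py` (the same computation)
prints:

```
survival-impact weights (x10):
  bm_num_a    2.124
  bm_num_b    1.508
  bm_nom_a    1.518
  bm_nom_b    1.616
  noise mean  0.713 (max 1.437)

query case_0001: arm=B, biomarker truth={'bm_num_a': True, ...}
10 most similar cases (global similarity, higher = more similar):
  case_0315  5.2608  matches 4/4 biomarker statuses
  case_0376  5.2598  matches 4/4 biomarker statuses
  ...
```

The four planted biomarkers receive clearly higher survival-impact weights
than the 24 noise attributes, and the retrieved neighbours share the query's
biomarker profile almost perfectly — the randomized therapy arm is never
consulted. The other scripts in `examples/` walk through each capability
(survival curves and ABS, cutoff search, measure benchmark, data generation);
each prints its numbers with a short interpretation.

A thin command line mirrors the workflow
(`stsm generate | train | retrieve | weights | nominalize | evaluate`);
run `stsm --help`.

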