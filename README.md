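# guanosat

Detection-corrected abundance estimation for colonial seabirds surveyed
with medium-resolution multispectral satellite imagery.

Adélie penguin colonies stain their nesting substrate with guano, and
the stain is spectrally distinct enough to be flagged automatically in
30 m Landsat-class imagery. A survey built on such retrievals faces two
coupled problems: converting flagged pixel area into breeding pairs,
and correcting regional totals for the colonies the sensor misses —
which are overwhelmingly the small ones. `guanosat` implements the full
estimation chain as a library, exercisable end-to-end on synthetic data
with known ground truth, for anyone studying detection-probability
correction in remote-sensing censuses.

## The model

Five pieces, per region (continental Antarctica and the Antarctic
Peninsula are always fitted separately):

* **Retrieval.** A one-class ellipsoid in 6-band reflectance space:
  centre = training-pixel mean, quadratic form = inverse training
  covariance (the stored "transition matrix"), threshold = a coverage
  quantile of the training squared Mahalanobis distances. A pixel is
  guano iff `(x−μ)ᵀ Σ⁻¹ (x−μ) ≤ t`.
* **Abundance.** Poisson regression with the log of guano area `A_i` as
  a fixed offset: `N_i ~ Poisson(λ_i)`, `log λ_i = β + log A_i`. The
  MLE is closed form, `β̂ = log(ΣN_i / ΣA_i)`, and `e^β` is the
  *apparent density* — nests per m² of detected guano (0.34 and 0.52
  nests/m² for the two regions).
* **Detection.** Logistic in colony size: `logit p(N) = β₀ + β₁N`,
  with the inverse `N*(p) = (logit p − β₀)/β₁` giving the colony size
  at any stated detection probability.
* **Missing abundance.** Colony sizes follow a lognormal law `P(N)`;
  the expected size of a *missed* colony is the conditional expectation
  `E[N|M=0] = Σ N(1−p(N))P(N) / Σ (1−p(N))P(N)`, the number of missed
  colonies is Negative Binomial (failures before `k_detected` successes
  at the overall detection probability `p̂`), and their product —
  simulated, with a percentile interval — is the total the survey
  cannot see.
* **Aggregation.** For aggregates of `k` colonies, the scaled
  difference `D = (total_Landsat − total_VHR)/total_VHR` is
  bootstrapped against a VHR-vs-VHR null and compared with a one-sided
  two-sample Kolmogorov–Smirnov test on `|D|`; the smallest `k` whose
  p-value exceeds α is the *equivalence scale* at which the two sensors
  become statistically indistinguishable.

The synthetic-data module generates all of this structure — lognormal
registries, guano footprints at `N/density` m², 6-band scenes with
cloud-disk occlusion, confuser surface classes, and reference ("VHR")
observations with accuracy-category lognormal error — so every stage is
testable against known truth without downloading a single scene.

## Worked example

`examples/05_missing_abundance.py` rebuilds the missing-abundance
estimate from the published per-region parameter sets:

```
continent: overall p(detect) = 0.63, E[size | missed] = 1,363 pairs (unconditional mean 48,907)
peninsula: overall p(detect) = 0.32, E[size | missed] = 1,215 pairs (unconditional mean 8,417)
expected missed colonies: 87
total missed abundance: 113,150 pairs (95th percentile interval 69,613-166,619)
```

Read: a randomly chosen colony is retrieved with probability 0.63
(continent), but the colonies that slip through are tiny — 1,363 pairs
on average against an unconditional mean of 48,907 — so ~87 missed
colonies carry only ~113k breeding pairs, a few percent of the
multi-million-pair total. The other examples cover scene simulation,
retrieval and outcome matching, the detection model and its thresholds
table, area-to-abundance conversion with prediction intervals, and the
aggregation equivalence scale. A thin CLI (`guanosat run-all --seed 0
--out runs/demo`) executes the whole chain and writes the registry,
scenes, candidate tables, KML and JSON reports.

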