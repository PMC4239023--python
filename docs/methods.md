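# Methods

This note records the models implemented in `guanosat`, the synthetic
world they are tested against, and the numerical and design choices
made where the procedure was genuinely open. No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` compute.

## The estimation chain

**Spectral retrieval.** The guano classifier is a one-class Mahalanobis
ellipsoid: centre `μ` = sample mean of labelled guano pixels, form
`Σ⁻¹` = inverse sample covariance (ridge `10⁻⁶ · mean(diag Σ)` added
when the covariance is near-singular; training sets with no spectral
variation at all are rejected), threshold = the coverage quantile
(upper order statistic, default coverage 0.99) of the training squared
Mahalanobis distances. The quantile construction makes the rule
data-driven rather than tied to a χ² reference value, and guarantees at
least `⌊coverage·n⌋` training pixels are accepted. Background pixels
play no role in the fit; they only audit commission. The rule is
invariant under common affine rescalings of training and scene, and the
flagged set is monotone in the threshold — both are property-tested.

Flagged pixels become candidate colonies by connected-component
labelling (8-connectivity default), transitive merging of components
whose centroids fall within `merge_radius` (default 2 px), and a
`min_pixels` floor (default 1 — the smallest real detected colony was a
single-pixel signal, so filtering happens downstream, not here).
Candidates match to registry colonies greedily by distance within 3 km;
extra candidates at an already-confirmed colony are absorbed, not
counted as commissions.

**Abundance (offset-Poisson).** `N_i ~ Poisson(A_i e^β)` with the log
guano area as a fixed offset. Fixing the offset coefficient at 1 is
what makes `e^β` interpretable as nests per m² of detected guano; a
free slope would break that reading. The MLE and its Fisher standard
error are closed form (`β̂ = log(ΣN/ΣA)`, `se = 1/√ΣN`) and are
cross-checked against a GLM fit in the tests. Zero-count colonies are
allowed (they contribute area only).

**Prediction intervals.** Pure Poisson intervals are far narrower than
the colony-to-colony scatter actually observed, so predictions layer a
lognormal residual with log-scale SD `τ` = RMS of `log(N_i/λ̂_i)` over
the fitted colonies. The predictive draw is
`Poisson(λ · exp(ε))`, `ε ~ N(−v/2, √v)`, `v = se² + τ²`. The `−v/2`
shift makes the lognormal layer mean-one. This calibration matters: the
ratio form of `β̂` already forces `Σλ̂ = ΣN` on the fitted survey, and a
median-centred layer would re-inflate expected totals by `e^{v/2}`
(~40% at the τ values the synthetic surveys produce), destroying the
unbiasedness of aggregate estimates that the closed-loop coverage test
verifies. The exact construction of the original envelopes is not
published; this layer is the package's own documented stand-in.

**Detection.** Maximum-likelihood logistic regression of the detection
indicator on raw colony size (slopes of order 10⁻⁴ per breeding pair
only make sense on the raw scale; log-size is deliberately not used).
Newton iterations to gradient tolerance 10⁻⁸; complete separation or a
single outcome class raises an error instead of returning a divergent
fit. Wald standard errors come from the observed information.
Region fits are never pooled. The published thresholds table cannot be
reproduced exactly from the rounded printed coefficients (they give
N*(0.5) = 2500, not the printed 2240, which evidently derives from
unrounded fits), so the implementation owns the formula
`N*(p) = (logit p − β₀)/β₁` and its round-trip identity, not those
integers.

**Colony-size law and missing abundance.** Sizes are lognormal, fitted
by ML on the log scale (`σ̂` uses the ML, not the Bessel, denominator;
SEs `σ/√n` and `σ/√(2n)`). The law is discretized as exact integer
support 1..1000 plus 4000 log-spaced bins out to the 1−10⁻⁹ quantile,
renormalized. No hard upper cap is imposed: with `σ ≈ 2.3` the
distribution mean draws double-digit percentages from sizes above 10⁷,
and truncating there would bias every downstream expectation; the
quantile rule keeps the grid-mean error below 0.5% for `σ ≤ 2.5`
(tested against the closed form `e^{μ+σ²/2}`).

`E[N|M=0]` is evaluated exactly on the grid (`direct_sum`, the oracle)
or by self-normalized importance sampling from `P(N)` with weights
`1−p(N)` (`monte_carlo`); the two agree within 1% at 10⁶ draws. No
Markov chain is used — a one-dimensional expectation over a discrete
grid does not need one. The missed-colony count is Negative Binomial:
failures accumulated before `k_detected` successes at success
probability `p̂`, the only parameterization under which an "overall
probability of detection" enters naturally; its expectation is
`k(1−p̂)/p̂`. The total is simulated (count draw, then that many sizes
from the `(1−p)`-weighted law, summed across regions), with a
percentile interval.

Two estimators of `p̂` are used where they belong: in the synthetic
closed loop, the empirical detected/known fraction per region; in the
printed-parameter reconstruction (no per-colony table available), the
marginal `Σ p(N)P(N)` under the fitted size law and logistic — with the
published parameter sets this gives 0.63 (continent) and 0.32
(peninsula) and a total missed abundance near 113k pairs, inside the
published interval.

**Aggregation.** Aggregates of `k` colonies are drawn without
replacement (an "area" holds distinct colonies). The Landsat total sums
predictive draws from the fitted abundance model; the reference total
sums independent draws from each colony's VHR sampling distribution;
the null replaces the Landsat total with a second independent VHR draw.
The one-sided two-sample KS statistic on `|D|` is
`sup_x(F_null(x) − F_landsat(x))` — alternative: Landsat differences
stochastically larger — with the one-sided asymptotic p-value
`exp(−2s²mn/(m+n))`; the statistic is verified against a brute-force
ECDF sweep and scipy. The equivalence scale is the smallest `k` with
`p > α`; `α = 0` always returns the "not reached" sentinel. Whether the
original test ran on `D` or `|D|` is unstated; `|D|` is used because
the scientific question is about the magnitude of disagreement.

## The synthetic world

Defaults reproduce the published study conditions: 180 continental +
64 peninsula colonies; lognormal size parameters (8.06, 2.34) and
(6.64, 2.19); apparent densities 0.34 and 0.52 nests/m²; 30 m pixels,
six reflective bands.

* **Footprints** are `round(N/density/900)` pixels (min 1), grown by
  nearest-pixel accretion from a seed pixel — compact disc-ish blobs.
  Only area matters downstream, so shape is not modelled further.
  Colonies are shelf-packed so footprints never overlap, and never
  straddle scenes.
* **Spectra** are class-wise multivariate normals (band SD 0.012 by
  default, placing guano ≥ 5 pooled SD from every background class —
  rock, soil, snow, water, vegetation). Confuser classes draw each
  pixel from the guano distribution with a configurable probability,
  giving direct control of the commission rate; in pipeline runs they
  are placed beyond matching range of any colony so a flagged confuser
  scores as a commission rather than being absorbed.
* **Occlusion** is rendered as random cloud/shadow disks of radius 2–6
  pixels stamped until the requested scene fraction (default 0.3) is
  covered. Small disks are the load-bearing choice: a one-pixel colony
  vanishes under any overlapping disk while a footprint wider than the
  largest disk can never be hidden by one, so non-detection is sharply
  size-dependent — the structure a logistic-in-N detection model
  assumes, with retrieval essentially certain above ~10⁴ pairs. Large
  disks would make omission nearly size-independent and the detection
  model unfittable in principle, not just in noise.
* **Reference (VHR) observations** are lognormal around the true size
  with a CV set by an accuracy-category rule — 0.05 below 10³ pairs,
  0.10 to 10⁴, 0.20 to 10⁵, 0.30 above — emulating surveys in which
  small colonies are field-counted precisely and very large ones are
  photo-interpreted coarsely. Heteroscedasticity is not cosmetic: with
  a constant CV the aggregation |D| distributions remain
  scale-separated at every aggregate size (both medians shrink as
  ~1/√k, their ratio does not), and no equivalence scale exists at any
  k; with category noise, large aggregates are dominated by colonies
  whose reference noise matches the medium-resolution noise, and the
  KS profile rises to a finite, registry-specific equivalence scale
  (80–240 colonies on the default registries). A constant-CV mode
  remains available and is used for the pure averaging property
  (median |D| non-increasing in k), which the per-colony offsets of
  the heteroscedastic world can legitimately break.

What the generator does **not** emulate: atmospheric effects and their
correction, sensor geometry (path/row, SLC-off striping), multi-date
compositing, the ~decade gap between the imagery eras (which degrades
the real rank correlation to ~0.7; the synthetic one is ~0.9),
mixed-species colonies, and the judgment calls behind excluding
individual real colonies (an `excluded` flag exists but nothing sets
it). Passing tests therefore demonstrate the estimation chain is
correct and calibrated *under its own assumptions*, not that those
assumptions hold for any particular archive of real scenes.

## Problem sizes and tolerances

The closed-loop coverage experiment runs 100 independent surveys of 244
colonies with 500 Monte Carlo draws of the corrected total each;
parameter recovery uses 200 replicates at n = 500 (logistic), 100
(Poisson) and 10⁵ (lognormal); oracle equivalence uses 10⁶ draws; the
aggregation panel runs 1000 bootstrap replicates per aggregate size on
five registries. The whole suite completes in well under a minute of
CPU. Acceptance-script surveys average apparent densities over five
independent clear-sky registries because a single survey's ratio
estimator is dominated by the reference error of its largest colony
(a heavy-tail effect, not an implementation artifact).

## Known limitations

* The ellipsoid construction (Mahalanobis ball with quantile threshold)
  is the minimal faithful reading of the published description; the
  original decision rule is stored in supplementary material not
  reproduced here and may differ in detail.
* `τ` pools all residual scatter into one per-region constant, though
  the true relative error shrinks with colony size; prediction
  intervals for very large colonies are therefore conservative.
* The Negative Binomial missed-count model treats colonies as
  exchangeable Bernoulli trials at rate `p̂`, ignoring the size
  dependence it is paired with; the paired size draw corrects the
  abundance, not the count.
* KML export writes scene-local metre coordinates, not geographic
  degrees — structural compatibility only.
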