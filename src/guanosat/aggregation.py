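"""Does medium-resolution disagreement wash out with spatial aggregation?

For an aggregate of k colonies drawn at random (without replacement)
from the registry, the scaled difference is

    D = (total_Landsat - total_VHR) / total_VHR,

where the Landsat total is a sum of predictive draws from the fitted
offset-Poisson abundance model and the VHR total is a sum of
independent draws from each colony's VHR sampling distribution.  The
null distribution replaces the Landsat total with a second independent
VHR draw, so it isolates the disagreement attributable to reference
uncertainty alone.  |D| samples from the two schemes are compared with
a one-sided two-sample Kolmogorov-Smirnov test (alternative: Landsat
|D| stochastically larger; statistic sup_x(F_null(x) - F_landsat(x))),
and the equivalence scale is the smallest k at which the test no longer
rejects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .abundance import AbundanceModelFit
from .exceptions import ParameterError
from .synth import ColonyRecord, vhr_sdlog


@dataclass
class AggregationInputs:
    """Vectorized per-colony quantities for the resampling loop."""

    area: np.ndarray          # retrieved guano area, m^2
    lam: np.ndarray           # area * apparent density, per colony
    pred_sdlog: np.ndarray    # log-scale SD of the Landsat predictive draw
    vhr_median: np.ndarray
    vhr_sdlog: np.ndarray

    @property
    def n_colonies(self) -> int:
        return self.area.size


def build_aggregation_inputs(records: list[ColonyRecord],
                             fits: dict[str, AbundanceModelFit],
                             areas: dict[str, float] | None = None,
                             landsat_sdlog: float | None = None) -> AggregationInputs:
    """Assemble inputs from a registry and region-matched abundance fits.

    ``areas`` optionally maps colony_id to retrieved guano area;
    otherwise the true footprint area is used.  ``landsat_sdlog``
    overrides the fit's predictive log-SD (useful for controlled noise
    experiments).  Colonies with a zero VHR count are excluded (their
    sampling distribution is undefined).
    """
    rows = []
    for rec in records:
        if rec.n_vhr <= 0:
            continue
        fit = fits[rec.region]
        area = areas.get(rec.colony_id, rec.guano_area_true) if areas \
            else rec.guano_area_true
        sd = landsat_sdlog if landsat_sdlog is not None else fit.pred_sdlog
        rows.append((area, area * fit.apparent_density, sd,
                     float(rec.n_vhr), vhr_sdlog(rec.vhr_cv)))
    if not rows:
        raise ParameterError("no usable colonies (all VHR counts zero?)")
    arr = np.asarray(rows, dtype=float)
    return AggregationInputs(area=arr[:, 0], lam=arr[:, 1], pred_sdlog=arr[:, 2],
                             vhr_median=arr[:, 3], vhr_sdlog=arr[:, 4])


@dataclass
class AggregationResult:
    k: int
    d_landsat: np.ndarray = field(repr=False)
    d_null: np.ndarray = field(repr=False)
    ks_stat: float | None = None
    ks_p: float | None = None

    @property
    def median_abs_d_landsat(self) -> float:
        return float(np.median(np.abs(self.d_landsat)))

    @property
    def median_abs_d_null(self) -> float:
        return float(np.median(np.abs(self.d_null)))


def sample_aggregate_differences(inputs: AggregationInputs, k: int,
                                 n_rep: int = 1000, seed=None,
                                 rng: np.random.Generator | None = None) -> AggregationResult:
    """Bootstrap the scaled-difference distributions at aggregate size k."""
    n = inputs.n_colonies
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}]")
    if n_rep < 1:
        raise ParameterError("n_rep must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    # k distinct colonies per replicate, vectorized
    idx = rng.random((n_rep, n)).argsort(axis=1)[:, :k]
    sd = inputs.pred_sdlog[idx]
    # mean-one lognormal layer (-sd^2/2 shift) keeps the Landsat draw
    # calibrated in expectation, mirroring the predictive draw
    lam = np.exp(np.log(inputs.lam[idx]) - sd * sd / 2.0
                 + rng.normal(0.0, 1.0, idx.shape) * sd)
    landsat = rng.poisson(lam).sum(axis=1).astype(float)
    log_med = np.log(inputs.vhr_median[idx])
    sd = inputs.vhr_sdlog[idx]
    vhr1 = np.exp(log_med + rng.normal(0.0, 1.0, idx.shape) * sd).sum(axis=1)
    vhr2 = np.exp(log_med + rng.normal(0.0, 1.0, idx.shape) * sd).sum(axis=1)
    d_landsat = (landsat - vhr1) / vhr1
    d_null = (vhr2 - vhr1) / vhr1
    res = AggregationResult(k=k, d_landsat=d_landsat, d_null=d_null)
    res.ks_stat, res.ks_p = ks_compare(d_landsat, d_null)
    return res


def ks_compare(d_landsat, d_null) -> tuple[float, float]:
    """One-sided two-sample KS test on |D|.

    Alternative: Landsat |D| is stochastically larger than the null
    |D|, i.e. F_landsat lies below F_null; statistic is
    sup_x(F_null(x) - F_landsat(x)) over the pooled sample, with the
    one-sided asymptotic p-value exp(-2 s^2 m n / (m + n)).
    """
    a = np.sort(np.abs(np.asarray(d_landsat, dtype=float)))
    b = np.sort(np.abs(np.asarray(d_null, dtype=float)))
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    f_l = np.searchsorted(a, grid, side="right") / a.size
    f_n = np.searchsorted(b, grid, side="right") / b.size
    stat = float(np.max(f_n - f_l))
    if stat <= 0:
        return max(stat, 0.0), 1.0
    m, n = a.size, b.size
    p = math.exp(-2.0 * stat * stat * m * n / (m + n))
    return stat, min(1.0, p)


@dataclass
class EquivalenceScaleResult:
    k_equiv: int | None                 # None => "not reached"
    alpha: float
    profile: list[AggregationResult]

    @property
    def reached(self) -> bool:
        return self.k_equiv is not None


def find_equivalence_scale(inputs: AggregationInputs, k_grid,
                           alpha: float = 0.05, n_rep: int = 1000,
                           seed=None) -> EquivalenceScaleResult:
    """Smallest aggregate size at which Landsat and VHR totals are
    statistically indistinguishable (KS p > alpha).

    Returns the full (k, statistic, p) profile; ``k_equiv`` is None
    when no k in the grid crosses alpha.  ``alpha = 0`` demands an
    impossible level of evidence, so the sentinel is always returned.
    """
    k_grid = list(k_grid)
    if any(k2 <= k1 for k1, k2 in zip(k_grid, k_grid[1:])):
        raise ParameterError("k_grid must be strictly ascending")
    ss = np.random.SeedSequence(seed)
    profile = []
    k_equiv = None
    for k, child in zip(k_grid, ss.spawn(len(k_grid))):
        res = sample_aggregate_differences(inputs, k, n_rep=n_rep,
                                           rng=np.random.default_rng(child))
        profile.append(res)
        if k_equiv is None and alpha > 0 and res.ks_p > alpha:
            k_equiv = k
    return EquivalenceScaleResult(k_equiv=k_equiv, alpha=alpha, profile=profile)
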