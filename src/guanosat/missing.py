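"""Abundance missed by the survey.

Three pieces combine to estimate the breeding pairs a size-biased
survey fails to capture:

1. A lognormal law for colony size N, fitted by maximum likelihood to
   reference abundances and discretized onto a grid (integer support on
   the head, log-spaced bins in the tail).
2. The conditional expectation of the size of a *missed* colony,
   E[N | M = 0] = sum_n n (1 - p(n)) P(n) / sum_n (1 - p(n)) P(n),
   where p(n) is the logistic detection probability.  Evaluated exactly
   on the grid (``direct_sum``) or by self-normalized Monte Carlo
   (``monte_carlo``); the direct sum is the oracle.
3. The number of missed colonies, modelled as the failures of a
   Negative Binomial with ``k_detected`` required successes at success
   probability ``p_hat`` (the overall detection probability), giving
   expectation k (1 - p) / p.

The total is simulated: per replicate draw a missed-colony count per
region, then that many sizes from the (1 - p)-weighted size law, and
sum across regions; the point estimate is the replicate mean and the
interval is a percentile interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from .detection import DetectionModelFit, detection_probability
from .exceptions import (InsufficientDataError, NoMissingMassError,
                         ParameterError)


@dataclass
class SizeDistributionFit:
    region: str
    mu: float
    sigma: float
    se_mu: float
    se_sigma: float
    n_obs: int


def fit_colony_size_distribution(abundances, region: str) -> SizeDistributionFit:
    """ML lognormal fit: mu = mean(log N), sigma = RMS deviation of log N.

    Standard errors are sigma/sqrt(n) for mu and sigma/sqrt(2n) for
    sigma (the usual normal-theory values on the log scale).
    """
    N = np.asarray(list(abundances), dtype=float)
    if N.size < 3:
        raise InsufficientDataError("need at least 3 abundances")
    if np.any(N < 1):
        raise ParameterError("abundances must be >= 1 breeding pair")
    logs = np.log(N)
    mu = float(np.mean(logs))
    sigma = float(np.sqrt(np.mean((logs - mu) ** 2)))
    if sigma == 0.0:
        raise ParameterError("all abundances equal; sigma is degenerate")
    n = N.size
    return SizeDistributionFit(region=region, mu=mu, sigma=sigma,
                               se_mu=sigma / math.sqrt(n),
                               se_sigma=sigma / math.sqrt(2 * n), n_obs=n)


@dataclass
class ColonySizeDistribution:
    """Discretized lognormal colony-size law P(N = n) on a finite grid."""

    region: str
    mu: float
    sigma: float
    n: np.ndarray = field(repr=False)     # support points (breeding pairs)
    pmf: np.ndarray = field(repr=False)

    def mean(self) -> float:
        return float(np.sum(self.n * self.pmf))


def discretize_size_distribution(mu: float, sigma: float,
                                 n_max_quantile: float = 1 - 1e-9,
                                 n_integer: int = 1000,
                                 n_log_bins: int = 4000,
                                 region: str = "") -> ColonySizeDistribution:
    """Discretize lognormal(mu, sigma) onto integers 1..n_integer plus
    log-spaced bins out to the ``n_max_quantile`` quantile.

    Integer support point n carries the CDF mass of (n - 1/2, n + 1/2]
    (all mass below 1.5 goes to n = 1); each tail bin carries its CDF
    mass at its geometric midpoint.  Probabilities are renormalized to
    sum to exactly 1.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    top = float(dist.ppf(n_max_quantile))
    ints = np.arange(1, n_integer + 1, dtype=float)
    edges_int = np.concatenate(([0.0], ints + 0.5))
    pmf_int = np.diff(dist.cdf(edges_int))
    if top > n_integer + 0.5:
        log_edges = np.logspace(math.log10(n_integer + 0.5), math.log10(top),
                                n_log_bins + 1)
        pmf_log = np.diff(dist.cdf(log_edges))
        mids = np.sqrt(log_edges[:-1] * log_edges[1:])
        n = np.concatenate([ints, mids])
        pmf = np.concatenate([pmf_int, pmf_log])
    else:
        n = ints
        pmf = pmf_int
    pmf = np.clip(pmf, 0.0, None)
    pmf = pmf / pmf.sum()
    return ColonySizeDistribution(region=region, mu=mu, sigma=sigma, n=n, pmf=pmf)


def expected_missing_colony_size(dist: ColonySizeDistribution,
                                 det: DetectionModelFit,
                                 method: str = "direct_sum",
                                 n_draws: int = 10**6, seed=None) -> float:
    """E[N | M = 0]: expected size of a colony the survey missed."""
    p = expit(det.beta0 + det.beta1 * dist.n)
    w = (1.0 - p) * dist.pmf
    denom = w.sum()
    if denom < 1e-300:
        raise NoMissingMassError("detection probability ~1 everywhere; "
                                 "no missing mass to condition on")
    if method == "direct_sum":
        return float(np.sum(dist.n * w) / denom)
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        idx = rng.choice(dist.n.size, size=n_draws, p=dist.pmf)
        wt = 1.0 - p[idx]
        tot = wt.sum()
        if tot <= 0:
            raise NoMissingMassError("no draw landed in the missed region")
        return float(np.sum(dist.n[idx] * wt) / tot)
    raise ParameterError(f"unknown method {method!r}")


@dataclass
class MissingColonyCount:
    """Distribution of the number of colonies the survey missed.

    Negative Binomial: failures (missed colonies) accumulated before
    ``k_detected`` successes, each success occurring with probability
    ``p_hat`` — the overall probability of detection.
    """

    k_detected: int
    p_hat: float

    def __post_init__(self) -> None:
        if self.k_detected < 1:
            raise ParameterError("k_detected must be >= 1")
        if not 0.0 < self.p_hat < 1.0:
            raise ParameterError("p_hat must be in (0, 1)")
        self._dist = stats.nbinom(self.k_detected, self.p_hat)

    @property
    def expectation(self) -> float:
        return self.k_detected * (1.0 - self.p_hat) / self.p_hat

    def pmf(self, m) -> np.ndarray:
        return self._dist.pmf(m)

    def quantile(self, q) -> np.ndarray:
        return self._dist.ppf(q)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.negative_binomial(self.k_detected, self.p_hat, size)


def missing_colony_count(k_detected: int, p_hat: float) -> MissingColonyCount:
    """Missed-colony count distribution given k detections at rate p_hat."""
    return MissingColonyCount(k_detected=k_detected, p_hat=p_hat)


@dataclass
class RegionMissingInputs:
    region: str
    dist: ColonySizeDistribution
    det: DetectionModelFit
    k_detected: int
    p_hat: float


@dataclass
class RegionMissingSummary:
    region: str
    e_missing_size: float
    p_hat: float
    k_detected: int
    expected_missing_colonies: float


@dataclass
class MissingAbundanceEstimate:
    regions: list[RegionMissingSummary]
    total_missing: float
    ci: tuple[float, float]
    level: float
    samples: np.ndarray = field(repr=False, default=None)


def total_missing_abundance(inputs: list[RegionMissingInputs],
                            n_rep: int = 1000, seed=None,
                            level: float = 0.95) -> MissingAbundanceEstimate:
    """Simulate the total abundance missed across regions.

    Per replicate and region: draw a missed-colony count from the
    Negative Binomial, then that many colony sizes from the
    (1 - p(n))-weighted size law, and sum.  Point estimate is the
    replicate mean; the interval is the percentile interval at
    ``level``.
    """
    if n_rep < 1:
        raise ParameterError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    totals = np.zeros(n_rep)
    summaries = []
    for reg in inputs:
        count = missing_colony_count(reg.k_detected, reg.p_hat)
        p = expit(reg.det.beta0 + reg.det.beta1 * reg.dist.n)
        w = (1.0 - p) * reg.dist.pmf
        denom = w.sum()
        if denom < 1e-300:
            raise NoMissingMassError(f"region {reg.region}: no missing mass")
        wp = w / denom
        e_size = float(np.sum(reg.dist.n * wp))
        summaries.append(RegionMissingSummary(
            region=reg.region, e_missing_size=e_size, p_hat=reg.p_hat,
            k_detected=reg.k_detected,
            expected_missing_colonies=count.expectation))
        m = count.sample(rng, n_rep)
        pos = m > 0
        if pos.any():
            sizes = rng.choice(reg.dist.n, size=int(m.sum()), p=wp)
            starts = np.concatenate(([0], np.cumsum(m[pos])[:-1]))
            totals[pos] += np.add.reduceat(sizes, starts)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(totals, [alpha, 1.0 - alpha])
    return MissingAbundanceEstimate(regions=summaries,
                                    total_missing=float(totals.mean()),
                                    ci=(float(lo), float(hi)), level=level,
                                    samples=totals)


def marginal_detection_probability(dist: ColonySizeDistribution,
                                   det: DetectionModelFit) -> float:
    """Overall detection probability sum_n p(n) P(n) under the size law."""
    p = expit(det.beta0 + det.beta1 * dist.n)
    return float(np.sum(p * dist.pmf))


def missing_report(est: MissingAbundanceEstimate) -> dict:
    """JSON-serializable summary."""
    return {
        "regions": [{
            "region": r.region, "e_missing_size": r.e_missing_size,
            "p_hat": r.p_hat, "k_detected": r.k_detected,
            "expected_missing_colonies": r.expected_missing_colonies,
        } for r in est.regions],
        "total_missing": est.total_missing,
        "ci": list(est.ci),
        "level": est.level,
    }
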