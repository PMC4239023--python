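"""Guano area to abundance: intercept-only Poisson regression with offset.

Expected abundance of colony i is lambda_i = A_i * exp(beta), i.e. a
Poisson log-link model with log guano area as a fixed offset and a
single intercept beta.  exp(beta) is the "apparent density" — nests per
square metre of *detected* guano area, which differs from on-ground
nest density because sensor-detected area is not true occupied area.
The offset coefficient is fixed at 1 by construction; a free slope
would destroy that interpretation.

The MLE is closed form: beta_hat = log(sum N_i / sum A_i), with Fisher
standard error 1 / sqrt(sum N_i).  Prediction envelopes add a lognormal
residual layer (the RMS of log(N_i / lambda_hat_i)) on top of Poisson
variation, because pure Poisson intervals are far narrower than the
colony-to-colony scatter actually observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, ParameterError


@dataclass
class AbundanceModelFit:
    """Fitted offset-Poisson abundance model for one region."""

    region: str
    beta: float             # log apparent density (log nests / m^2)
    se: float
    tau_log_resid: float    # SD of log-scale residuals, for envelopes
    n_obs: int = 0

    @property
    def apparent_density(self) -> float:
        """exp(beta), in nests per m^2 of detected guano."""
        return math.exp(self.beta)

    @property
    def pred_sdlog(self) -> float:
        """Log-scale SD of the colony-level prediction distribution."""
        return math.hypot(self.se, self.tau_log_resid)


def fit_abundance_model(pairs, region: str) -> AbundanceModelFit:
    """Fit the offset-Poisson model from (guano_area_m2, N_pairs) pairs.

    Colonies with N = 0 are allowed (they contribute area only); any
    non-positive area is a domain error.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParameterError("pairs must be (guano_area, N) tuples")
    if arr.shape[0] < 1:
        raise InsufficientDataError("need at least one (area, N) pair")
    A = arr[:, 0]
    N = arr[:, 1]
    if np.any(A <= 0):
        raise ParameterError("guano areas must be > 0")
    if np.any(N < 0):
        raise ParameterError("abundances must be >= 0")
    total_n = N.sum()
    if total_n <= 0:
        raise ParameterError("at least one colony must have N > 0")
    beta = math.log(total_n / A.sum())
    se = 1.0 / math.sqrt(total_n)
    lam = A * math.exp(beta)
    pos = N > 0
    resid = np.log(N[pos] / lam[pos])
    tau = float(np.sqrt(np.mean(resid ** 2))) if pos.any() else 0.0
    return AbundanceModelFit(region=region, beta=beta, se=se,
                             tau_log_resid=tau, n_obs=arr.shape[0])


@dataclass
class PredictedAbundance:
    lam: float
    lo: float
    hi: float
    level: float


def predict_abundance(fit: AbundanceModelFit, guano_area: float,
                      level: float = 0.95, n_draws: int = 10000,
                      seed=None, rng: np.random.Generator | None = None) -> PredictedAbundance:
    """Point prediction and percentile interval for a new guano area.

    The Monte Carlo predictive draw is Poisson(lambda * exp(eps)) with
    eps ~ Normal(-v/2, sqrt(v)), v = se^2 + tau^2.  The -v/2 shift makes
    the lognormal layer mean-one, so predictions stay calibrated in
    expectation (the fit itself is ratio-calibrated: sum of lambda_hat
    equals sum of N).  With se = tau = 0 the interval collapses to
    Poisson quantiles around lambda.
    """
    if guano_area <= 0:
        raise ParameterError("guano_area must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    lam = guano_area * fit.apparent_density
    sd = fit.pred_sdlog
    lam_draws = np.exp(rng.normal(math.log(lam) - sd * sd / 2.0, sd, n_draws)) \
        if sd > 0 else np.full(n_draws, lam)
    y = rng.poisson(lam_draws)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(y, [alpha, 1.0 - alpha])
    return PredictedAbundance(lam=float(lam), lo=float(lo), hi=float(hi), level=level)


def draw_abundance(fit: AbundanceModelFit, guano_area, rng: np.random.Generator):
    """One predictive abundance draw per area (vectorized)."""
    area = np.asarray(guano_area, dtype=float)
    lam = area * fit.apparent_density
    sd = fit.pred_sdlog
    if sd > 0:
        lam = np.exp(np.log(lam) - sd * sd / 2.0 + rng.normal(0.0, sd, lam.shape))
    return rng.poisson(lam)


def kendall_tau(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall rank correlation (tau-b) with two-sided p.

    The p-value is exact (enumeration) for n <= 10 with no ties and a
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ParameterError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ParameterError("correlation undefined for constant input")
    has_ties = (np.unique(x).size < x.size) or (np.unique(y).size < y.size)
    method = "exact" if (x.size <= 10 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def predictions_table(fit: AbundanceModelFit, colonies, level: float = 0.95,
                      n_draws: int = 10000, seed=None) -> list[dict]:
    """Per-colony predictions: (colony_id, guano_area_m2) -> lambda, lo, hi."""
    rng = np.random.default_rng(seed)
    rows = []
    for colony_id, area in colonies:
        pred = predict_abundance(fit, area, level=level, n_draws=n_draws, rng=rng)
        rows.append({"colony_id": colony_id, "guano_area_m2": float(area),
                     "lambda_hat": pred.lam, "lo": pred.lo, "hi": pred.hi})
    return rows
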