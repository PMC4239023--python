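"""Size-dependent detection probability model.

The probability that a survey retrieves a colony of N breeding pairs is
modelled on the logistic scale, logit(p) = beta0 + beta1 * N, fitted by
maximum likelihood per region (continent and peninsula fits are never
pooled).  The covariate is raw abundance, not log abundance: the
published slopes (~1e-4 per breeding pair) only make sense on the raw
scale.  The inverse relation N*(p) gives the colony size at which a
stated detection probability is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import ParameterError, SeparationError

DEFAULT_PROBABILITIES = (0.5, 0.75, 0.90, 0.95, 0.99)


@dataclass
class DetectionModelFit:
    """Logistic detection model: logit(p) = beta0 + beta1 * N."""

    region: str
    beta0: float
    beta1: float
    se0: float
    se1: float
    n_obs: int = 0
    converged: bool = True


def fit_detection_model(observations, region: str) -> DetectionModelFit:
    """ML logistic regression of the detection indicator on colony size.

    ``observations`` is an iterable of ``(N, detected)`` with
    detected in {0, 1}.  Complete separation (including a single
    outcome class) raises :class:`SeparationError` rather than
    returning a silently divergent fit.
    """
    obs = np.asarray(list(observations), dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ParameterError("observations must be (N, detected) pairs")
    N = obs[:, 0]
    y = obs[:, 1]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ParameterError("detected must be 0 or 1")
    if len(np.unique(y)) < 2:
        raise SeparationError(
            f"all colonies share outcome {int(y[0])}; the logistic fit is degenerate")
    X = sm.add_constant(N)
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-8, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    converged = bool(res.mle_retvals.get("converged", True))
    if not np.all(np.isfinite(params)) or not converged:
        raise SeparationError("logistic fit did not converge (likely separation)")
    return DetectionModelFit(region=region, beta0=float(params[0]),
                             beta1=float(params[1]), se0=float(bse[0]),
                             se1=float(bse[1]), n_obs=len(y), converged=converged)


def detection_probability(fit: DetectionModelFit, N) -> np.ndarray | float:
    """p(N) = 1 / (1 + exp(-(beta0 + beta1 N)))."""
    N = np.asarray(N, dtype=float)
    p = expit(fit.beta0 + fit.beta1 * N)
    return float(p) if p.ndim == 0 else p


def size_at_detection_probability(fit: DetectionModelFit, p: float) -> float:
    """Colony size N* at which the detection probability equals ``p``."""
    if not 0.0 < p < 1.0:
        raise ParameterError("p must be in (0, 1)")
    if fit.beta1 == 0.0:
        raise ParameterError("beta1 = 0: detection does not depend on size, "
                             "no threshold exists")
    return float((logit(p) - fit.beta0) / fit.beta1)


def thresholds_table(fit: DetectionModelFit,
                     probabilities=DEFAULT_PROBABILITIES) -> dict[float, float]:
    """Colony sizes at the standard detection probabilities."""
    return {float(p): size_at_detection_probability(fit, p) for p in probabilities}


def fit_report(fit: DetectionModelFit) -> dict:
    """JSON-serializable fit summary with the thresholds table."""
    return {
        "region": fit.region,
        "beta0": fit.beta0, "se0": fit.se0,
        "beta1": fit.beta1, "se1": fit.se1,
        "n_obs": fit.n_obs,
        "thresholds": {str(p): n for p, n in thresholds_table(fit).items()},
    }
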