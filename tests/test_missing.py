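import math

import numpy as np
import pytest

from guanosat import detection, missing
from guanosat.exceptions import (InsufficientDataError, NoMissingMassError,
                                 ParameterError)

CONT = dict(mu=8.06, sigma=2.34, beta0=-1.00, beta1=4e-4)
PEN = dict(mu=6.64, sigma=2.19, beta0=-1.72, beta1=3e-4)


def _det(p, region="x"):
    return detection.DetectionModelFit(region, p["beta0"], p["beta1"], 0, 0)


def _dist(p, region="x"):
    return missing.discretize_size_distribution(p["mu"], p["sigma"],
                                                region=region)


class TestSizeFit:
    def test_two_point_log_symmetry(self):
        fit = missing.fit_colony_size_distribution(
            [math.e ** 2, math.e ** 4, math.e ** 2, math.e ** 4], "x")
        assert fit.mu == pytest.approx(3.0)
        assert fit.sigma == pytest.approx(1.0)

    def test_recovery_at_large_n(self, rng):
        draws = np.exp(rng.normal(8.06, 2.34, 100_000))
        fit = missing.fit_colony_size_distribution(draws[draws >= 1], "continent")
        assert fit.mu == pytest.approx(8.06, abs=2 * fit.se_mu)
        assert fit.sigma == pytest.approx(2.34, abs=2 * fit.se_sigma)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            missing.fit_colony_size_distribution([0.5, 2, 3], "x")
        with pytest.raises(ParameterError):
            missing.fit_colony_size_distribution([7, 7, 7], "x")
        with pytest.raises(InsufficientDataError):
            missing.fit_colony_size_distribution([3, 4], "x")


class TestDiscretize:
    @pytest.mark.parametrize("p", [CONT, PEN])
    def test_pmf_normalized(self, p):
        dist = _dist(p)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("mu,sigma", [(8.06, 2.34), (6.64, 2.19),
                                          (5.0, 1.0), (9.0, 2.5)])
    def test_grid_mean_matches_closed_form(self, mu, sigma):
        dist = missing.discretize_size_distribution(mu, sigma)
        assert dist.mean() == pytest.approx(math.exp(mu + sigma ** 2 / 2),
                                            rel=0.005)

    def test_unimodal_in_log_size(self):
        # dP/dlog n has a single peak; on the unit-width integer
        # section that density is pmf(n) * n
        dist = missing.discretize_size_distribution(5.0, 1.0)
        shape = dist.pmf[:1000] * dist.n[:1000]
        keep = shape > shape.max() * 1e-9
        s = shape[keep]
        peak = int(np.argmax(s))
        assert np.all(np.diff(s[:peak + 1]) >= -1e-12 * s.max())
        assert np.all(np.diff(s[peak:]) <= 1e-12 * s.max())

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ParameterError):
            missing.discretize_size_distribution(8.0, 0.0)


class TestExpectedMissingSize:
    def test_constant_detection_reduces_to_mean(self):
        dist = _dist(CONT)
        det = detection.DetectionModelFit("x", -1.0, 0.0, 0, 0)
        e = missing.expected_missing_colony_size(dist, det)
        assert e == pytest.approx(dist.mean(), rel=1e-9)

    @pytest.mark.parametrize("p", [CONT, PEN])
    def test_monte_carlo_matches_direct_sum(self, p):
        dist, det = _dist(p), _det(p)
        direct = missing.expected_missing_colony_size(dist, det)
        mc = missing.expected_missing_colony_size(dist, det,
                                                  method="monte_carlo",
                                                  n_draws=10**6, seed=5)
        assert mc == pytest.approx(direct, rel=0.01)

    def test_monte_carlo_error_shrinks_with_draws(self):
        dist, det = _dist(CONT), _det(CONT)
        direct = missing.expected_missing_colony_size(dist, det)
        err = {n: np.median([abs(missing.expected_missing_colony_size(
            dist, det, method="monte_carlo", n_draws=n, seed=s) - direct)
            for s in range(5)]) for n in (10**4, 10**6)}
        assert err[10**6] < err[10**4]

    def test_size_bias_shrinks_missed_colonies(self):
        # E[N | missed] < E[N] whenever detection increases with size,
        # and it decreases as the size bias strengthens
        dist = _dist(CONT)
        prev = dist.mean()
        for b1 in (1e-5, 1e-4, 4e-4, 1e-3):
            det = detection.DetectionModelFit("x", -1.0, b1, 0, 0)
            e = missing.expected_missing_colony_size(dist, det)
            assert e < prev
            prev = e

    def test_certain_detection_raises(self):
        dist = _dist(CONT)
        det = detection.DetectionModelFit("x", 800.0, 1.0, 0, 0)
        with pytest.raises(NoMissingMassError):
            missing.expected_missing_colony_size(dist, det)


class TestMissingColonyCount:
    def test_symmetric_expectation(self):
        assert missing.missing_colony_count(10, 0.5).expectation == \
            pytest.approx(10.0)

    def test_pmf_normalized(self):
        count = missing.missing_colony_count(91, 0.7)
        assert count.pmf(np.arange(0, 10**6)).sum() == \
            pytest.approx(1.0, abs=1e-9)

    def test_certain_detection_limit(self):
        assert missing.missing_colony_count(50, 1 - 1e-12).expectation == \
            pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("p_hat", [0.0, 1.0, -0.2, 1.3])
    def test_invalid_p_hat_rejected(self, p_hat):
        with pytest.raises(ParameterError):
            missing.missing_colony_count(10, p_hat)


class TestTotalMissing:
    def _inputs(self, p_hats=(0.631, 0.32)):
        out = []
        for p, ph, k, region in ((CONT, p_hats[0], 91, "continent"),
                                 (PEN, p_hats[1], 16, "peninsula")):
            out.append(missing.RegionMissingInputs(
                region, _dist(p, region), _det(p, region), k, ph))
        return out

    def test_certain_detection_gives_zero_total(self):
        est = missing.total_missing_abundance(
            self._inputs(p_hats=(1 - 1e-9, 1 - 1e-9)), n_rep=200, seed=1)
        assert est.total_missing == pytest.approx(0.0, abs=1.0)

    def test_law_of_total_expectation(self):
        inputs = self._inputs()
        est = missing.total_missing_abundance(inputs, n_rep=4000, seed=2)
        expected = sum(r.e_missing_size * r.expected_missing_colonies
                       for r in est.regions)
        mc_se = est.samples.std() / math.sqrt(len(est.samples))
        assert est.total_missing == pytest.approx(expected, abs=2.5 * mc_se)

    def test_ci_brackets_point(self):
        est = missing.total_missing_abundance(self._inputs(), n_rep=500, seed=3)
        assert est.ci[0] <= est.total_missing <= est.ci[1]

    def test_reproducible_under_seed(self):
        a = missing.total_missing_abundance(self._inputs(), n_rep=100, seed=4)
        b = missing.total_missing_abundance(self._inputs(), n_rep=100, seed=4)
        assert a.total_missing == b.total_missing
        assert a.ci == b.ci
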