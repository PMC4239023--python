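import numpy as np
import pytest
from scipy.spatial.distance import mahalanobis

from guanosat import retrieval, synth
from guanosat.exceptions import (DegenerateTrainingError,
                                 InsufficientDataError, ParameterError,
                                 SchemaError)


def _train(library, n=473, seed=0):
    return library.sample_training_pixels("guano", n, seed=seed)


class TestFitEllipsoid:
    def test_center_always_accepted(self, library):
        clf = retrieval.fit_ellipsoid(_train(library))
        assert clf.decision_value(clf.center[None, :])[0] == pytest.approx(0.0)
        assert clf.accepts(clf.center[None, :])[0]

    def test_coverage_quantile_acceptance_count(self, library):
        # 473 training pixels at coverage 0.99: at least floor(0.99*473)=468
        X = _train(library, n=473)
        clf = retrieval.fit_ellipsoid(X, coverage=0.99)
        assert int(clf.accepts(X).sum()) >= 468

    def test_matches_bruteforce_mahalanobis(self, rng):
        # 2-band toy set: decision values equal an independent
        # pixel-by-pixel quadratic-form evaluation
        X = rng.normal(size=(40, 2))
        clf = retrieval.fit_ellipsoid(X, coverage=0.9)
        VI = np.linalg.inv(np.cov(X, rowvar=False, ddof=1))
        mu = X.mean(axis=0)
        probe = rng.normal(size=(25, 2))
        expected = np.array([mahalanobis(p, mu, VI) ** 2 for p in probe])
        assert np.allclose(clf.decision_value(probe), expected)

    def test_too_few_pixels_rejected(self, library):
        with pytest.raises(InsufficientDataError):
            retrieval.fit_ellipsoid(_train(library, n=6))

    def test_identical_pixels_degenerate(self):
        X = np.tile(np.full(6, 0.2), (20, 1))
        with pytest.raises(DegenerateTrainingError):
            retrieval.fit_ellipsoid(X)

    def test_constant_band_regularized_not_fatal(self, rng):
        # one zero-variance band is rescued by the ridge
        X = rng.normal(size=(50, 6))
        X[:, 3] = 0.5
        clf = retrieval.fit_ellipsoid(X)
        assert np.isfinite(clf.threshold)

    def test_affine_invariance(self, library, rng):
        # Mahalanobis acceptance is invariant under a common affine
        # rescaling of training pixels and probes
        X = _train(library, n=200, seed=3)
        probe = rng.normal(0.18, 0.05, size=(100, 6))
        scale = np.array([2.0, 0.5, 1.5, 3.0, 0.25, 1.0])
        shift = np.array([0.1, -0.2, 0.0, 0.3, 0.05, -0.1])
        a = retrieval.fit_ellipsoid(X).accepts(probe)
        b = retrieval.fit_ellipsoid(X * scale + shift).accepts(probe * scale + shift)
        assert np.array_equal(a, b)


class TestClassifyPixels:
    def test_center_pixels_all_flagged(self, library):
        clf = retrieval.fit_ellipsoid(_train(library))
        bands = np.tile(clf.center[:, None, None], (1, 5, 5)).astype(np.float32)
        scene = synth.SpectralScene(bands=bands,
                                    valid_mask=np.ones((5, 5), bool),
                                    truth_guano_mask=np.zeros((5, 5), bool))
        assert retrieval.classify_pixels(scene, clf).all()

    def test_invalid_pixels_never_flagged(self, library):
        clf = retrieval.fit_ellipsoid(_train(library))
        bands = np.tile(clf.center[:, None, None], (1, 5, 5)).astype(np.float32)
        scene = synth.SpectralScene(bands=bands,
                                    valid_mask=np.zeros((5, 5), bool),
                                    truth_guano_mask=np.zeros((5, 5), bool))
        assert not retrieval.classify_pixels(scene, clf).any()

    def test_band_count_mismatch(self, library):
        clf = retrieval.fit_ellipsoid(np.random.default_rng(0).normal(size=(30, 2)))
        recs = synth.sample_colony_registry({"continent": 3}, seed=1)
        scene = synth.render_scene(recs, library, seed=1)
        with pytest.raises(SchemaError):
            retrieval.classify_pixels(scene, clf)

    def test_threshold_monotonicity(self, library):
        # shrinking the threshold never increases the flagged count
        clf = retrieval.fit_ellipsoid(_train(library))
        recs = synth.sample_colony_registry({"continent": 20}, seed=2)
        scene = synth.render_scene(recs, library, seed=2)
        counts = []
        for frac in (1.0, 0.5, 0.25, 0.1):
            sub = retrieval.EllipsoidClassifier(
                clf.center, clf.form, clf.threshold * frac, clf.bands_used)
            counts.append(int(retrieval.classify_pixels(scene, sub).sum()))
        assert counts == sorted(counts, reverse=True)


def _flood_fill_oracle(mask, connectivity):
    """Brute-force BFS labelling."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                and mask[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
                comps.append(sorted(comp))
    return sorted(comps)


class TestExtractCandidates:
    def test_single_component_area(self):
        mask = np.zeros((10, 10), bool)
        mask[2:4, 2:7] = True  # 10 pixels
        cands = retrieval.extract_candidates(mask)
        assert len(cands) == 1
        assert cands[0].pixel_count == 10
        assert cands[0].guano_area == pytest.approx(9000.0)

    def test_merge_radius_joins_near_components(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 2] = True
        mask[5, 4] = True  # 2 px apart -> separate at radius 0, merged at 2.5
        assert len(retrieval.extract_candidates(mask, merge_radius=0.0)) == 2
        assert len(retrieval.extract_candidates(mask, merge_radius=2.5)) == 1

    def test_min_pixels_filter(self):
        mask = np.zeros((10, 10), bool)
        mask[1, 1] = True
        mask[5:8, 5:8] = True
        cands = retrieval.extract_candidates(mask, min_pixels=2)
        assert [c.pixel_count for c in cands] == [9]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        mask = rng.random((30, 30)) < 0.35
        cands = retrieval.extract_candidates(mask, connectivity=connectivity)
        oracle = _flood_fill_oracle(mask, connectivity)
        assert sorted(c.pixel_count for c in cands) == \
               sorted(len(c) for c in oracle)

    def test_empty_mask(self):
        assert retrieval.extract_candidates(np.zeros((5, 5), bool)) == []


def _colony(cid, x, y, n=1000):
    return synth.ColonyRecord(colony_id=cid, region="continent", x=x, y=y,
                              n_true=n, n_vhr=n, vhr_cv=0.1,
                              guano_area_true=n / 0.34)


def _cand(cid, x, y, px=5):
    return retrieval.RetrievalCandidate(candidate_id=cid, pixel_count=px,
                                        x=x, y=y)


class TestMatchOutcomes:
    def test_candidate_at_colony_is_both(self):
        m = retrieval.match_outcomes([_cand("a", 100, 100)],
                                     [_colony("c", 100, 100)])
        assert m.n_both == 1 and m.n_omission == 0 and m.n_commission == 0

    def test_unretrieved_colony_is_omission(self):
        m = retrieval.match_outcomes([], [_colony("c", 100, 100)])
        assert m.n_omission == 1 and not m.detected["c"]

    def test_far_candidate_is_commission(self):
        m = retrieval.match_outcomes([_cand("a", 9000, 9000)],
                                     [_colony("c", 0, 0)])
        assert m.n_commission == 1
        assert m.commission_rate == 1.0

    def test_extra_candidates_absorbed_not_commissions(self):
        m = retrieval.match_outcomes(
            [_cand("a", 90, 100), _cand("b", 130, 100)],
            [_colony("c", 100, 100)])
        assert m.n_both == 1 and m.n_commission == 0
        assert set(m.assignments["c"]) == {"a", "b"}
        # nearest candidate confirms
        both = [o for o in m.outcomes if o.outcome == "both"][0]
        assert both.candidate_id == "a"

    def test_count_invariants(self, rng):
        registry = [_colony(f"c{i}", *rng.uniform(0, 5000, 2)) for i in range(20)]
        cands = [_cand(f"a{i}", *rng.uniform(0, 5000, 2)) for i in range(25)]
        m = retrieval.match_outcomes(cands, registry)
        assert m.n_both + m.n_omission == len(registry)
        n_absorbed = sum(len(v) for v in m.assignments.values()) - m.n_both
        assert m.n_both + n_absorbed + m.n_commission == len(cands)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ParameterError):
            retrieval.match_outcomes([], [], max_match_distance=0.0)
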