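"""Ellipsoid spectral classifier, candidate extraction and outcome matching.

The retrieval rule is a one-class ellipsoid in 6-band reflectance space:
the sample mean of the guano training pixels is the centre, the inverse
sample covariance is the quadratic form (the stored "transition
matrix"), and the decision threshold is a coverage quantile of the
training pixels' squared Mahalanobis distances.  A scene pixel is
flagged as guano when it is valid and its quadratic form value falls
under the threshold.  Flagged pixels are grouped into candidate
colonies by connected-component labelling, and candidates are scored
against a registry as detections (both), omissions and commissions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .exceptions import (DegenerateTrainingError, InsufficientDataError,
                         ParameterError, SchemaError)
from .synth import BAND_NAMES, PIXEL_AREA, PIXEL_SIZE, ColonyRecord, SpectralScene


@dataclass
class EllipsoidClassifier:
    """Mahalanobis-ball decision rule in band space.

    ``decision_value`` is (x - center)^T form (x - center); a pixel is
    accepted when the value is <= ``threshold``.  The value at the
    centre is 0, so the centre is always accepted.
    """

    center: np.ndarray
    form: np.ndarray
    threshold: float
    bands_used: tuple = BAND_NAMES

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.form = np.asarray(self.form, dtype=float)
        d = self.center.size
        if self.form.shape != (d, d):
            raise ParameterError("form must be square and match center")
        if self.threshold < 0:
            raise ParameterError("threshold must be >= 0")

    def decision_value(self, pixels: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(pixels, dtype=float)) - self.center
        return np.einsum("ij,jk,ik->i", x, self.form, x)

    def accepts(self, pixels: np.ndarray) -> np.ndarray:
        return self.decision_value(pixels) <= self.threshold


def fit_ellipsoid(in_class_pixels: np.ndarray, coverage: float = 0.99) -> EllipsoidClassifier:
    """Fit the ellipsoid rule from labelled guano pixels.

    centre = sample mean; form = inverse sample covariance (with a small
    ridge ``1e-6 * mean(diag)`` when near-singular); threshold = the
    ``coverage`` quantile (upper order statistic) of the training
    squared Mahalanobis distances, so at least
    ``floor(coverage * n)`` training pixels are accepted.
    """
    X = np.asarray(in_class_pixels, dtype=float)
    if X.ndim != 2:
        raise ParameterError("training pixels must be a (n, bands) array")
    n, d = X.shape
    if not 0.0 < coverage < 1.0:
        raise ParameterError("coverage must be in (0, 1)")
    if n < d + 1:
        raise InsufficientDataError(
            f"need at least {d + 1} training pixels for {d} bands, got {n}")
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if float(np.mean(np.diag(cov))) <= 1e-20:
        raise DegenerateTrainingError(
            "training pixels carry no spectral variation; the ellipsoid "
            "is degenerate — add varied in-class pixels or regularize")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 1e-10 * max(eigvals.max(), 1e-300):
        cov = cov + np.eye(d) * 1e-6 * np.mean(np.diag(cov))
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise DegenerateTrainingError(
                "training covariance singular even after ridge regularization; "
                "drop constant bands or add more varied training pixels")
    form = np.linalg.inv(cov)
    diff = X - center
    d2 = np.einsum("ij,jk,ik->i", diff, form, diff)
    threshold = float(np.quantile(d2, coverage, method="higher"))
    bands = BAND_NAMES if d == len(BAND_NAMES) else tuple(f"b{i}" for i in range(d))
    return EllipsoidClassifier(center=center, form=form, threshold=threshold,
                               bands_used=bands)


def classify_pixels(scene: SpectralScene, classifier: EllipsoidClassifier) -> np.ndarray:
    """Boolean guano mask: valid pixels inside the ellipsoid."""
    if scene.bands.shape[0] != len(classifier.bands_used):
        raise SchemaError(
            f"scene has {scene.bands.shape[0]} bands but classifier expects "
            f"{len(classifier.bands_used)}")
    flat = scene.bands.reshape(scene.bands.shape[0], -1).T
    inside = classifier.accepts(flat).reshape(scene.shape)
    return inside & scene.valid_mask


@dataclass
class RetrievalCandidate:
    """A connected group of flagged pixels proposed as a colony."""

    candidate_id: str
    pixel_count: int
    x: float            # centroid, scene metres
    y: float
    scene_id: str = "scene"

    @property
    def guano_area(self) -> float:
        return self.pixel_count * PIXEL_AREA


def extract_candidates(guano_mask: np.ndarray, connectivity: int = 8,
                       merge_radius: float = 0.0, min_pixels: int = 1,
                       scene_id: str = "scene",
                       pixel_size: float = PIXEL_SIZE) -> list[RetrievalCandidate]:
    """Group flagged pixels into candidates.

    Connected components under 4- or 8-connectivity; components whose
    centroids lie within ``merge_radius`` pixels of each other are
    merged (transitively); merged groups with fewer than ``min_pixels``
    pixels are dropped.
    """
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    labels = measure.label(np.asarray(guano_mask, dtype=bool),
                           connectivity=1 if connectivity == 4 else 2)
    props = measure.regionprops(labels)
    if not props:
        return []
    counts = np.array([p.area for p in props], dtype=float)
    cents = np.array([p.centroid for p in props], dtype=float)  # (row, col)

    # union-find merge of centroid-close components
    parent = list(range(len(props)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if merge_radius > 0 and len(props) > 1:
        r2 = merge_radius * merge_radius
        for i in range(len(props)):
            for j in range(i + 1, len(props)):
                if np.sum((cents[i] - cents[j]) ** 2) <= r2:
                    parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(props)):
        groups.setdefault(find(i), []).append(i)

    out: list[RetrievalCandidate] = []
    for members in groups.values():
        total = counts[members].sum()
        if total < min_pixels:
            continue
        w = counts[members] / total
        crow, ccol = (cents[members] * w[:, None]).sum(axis=0)
        out.append(RetrievalCandidate(
            candidate_id="", pixel_count=int(total),
            x=(ccol + 0.5) * pixel_size, y=(crow + 0.5) * pixel_size,
            scene_id=scene_id))
    out.sort(key=lambda c: (c.y, c.x))
    for i, c in enumerate(out):
        c.candidate_id = f"{scene_id}-{i:04d}"
    return out


@dataclass
class MatchOutcome:
    """One row of the four-outcome comparison scheme.

    ``both``: a registry colony confirmed by at least one candidate
    (its missing indicator M = 1); ``omission``: a registry colony with
    no candidate in range (M = 0); ``commission``: a candidate matching
    no colony.  (``neither`` — no colony, nothing flagged — describes
    the unlisted background and is never emitted.)
    """

    outcome: str
    colony_id: str | None = None
    candidate_id: str | None = None
    distance: float | None = None


@dataclass
class MatchResult:
    outcomes: list[MatchOutcome]
    assignments: dict[str, list[str]]   # colony_id -> candidate ids (incl. absorbed)
    n_both: int
    n_omission: int
    n_commission: int
    n_candidates: int
    commission_rate: float
    detected: dict[str, bool] = field(default_factory=dict)


def match_outcomes(candidates: list[RetrievalCandidate],
                   registry: list[ColonyRecord],
                   max_match_distance: float = 3000.0) -> MatchResult:
    """Score candidates against a registry, greedily by distance.

    Each candidate goes to its nearest registry colony within
    ``max_match_distance`` metres; the nearest candidate confirms the
    colony, further candidates at the same colony are absorbed (they are
    not commissions).  Unmatched colonies are omissions, unmatched
    candidates commissions.
    """
    if max_match_distance <= 0:
        raise ParameterError("max_match_distance must be > 0")
    outcomes: list[MatchOutcome] = []
    assignments: dict[str, list[str]] = {r.colony_id: [] for r in registry}
    cand_dist: dict[str, float] = {}
    if candidates and registry:
        cx = np.array([c.x for c in candidates])
        cy = np.array([c.y for c in candidates])
        rx = np.array([r.x for r in registry])
        ry = np.array([r.y for r in registry])
        dists = np.hypot(cx[:, None] - rx[None, :], cy[:, None] - ry[None, :])
        nearest = np.argmin(dists, axis=1)
        for ci, cand in enumerate(candidates):
            d = float(dists[ci, nearest[ci]])
            if d <= max_match_distance:
                assignments[registry[nearest[ci]].colony_id].append(cand.candidate_id)
                cand_dist[cand.candidate_id] = d

    detected = {}
    n_both = n_omission = 0
    for rec in registry:
        hit = bool(assignments[rec.colony_id])
        detected[rec.colony_id] = hit
        if hit:
            n_both += 1
            ids = sorted(assignments[rec.colony_id], key=lambda c: cand_dist[c])
            assignments[rec.colony_id] = ids
            outcomes.append(MatchOutcome("both", colony_id=rec.colony_id,
                                         candidate_id=ids[0],
                                         distance=cand_dist[ids[0]]))
        else:
            n_omission += 1
            outcomes.append(MatchOutcome("omission", colony_id=rec.colony_id))
    matched_ids = {cid for ids in assignments.values() for cid in ids}
    n_commission = 0
    for cand in candidates:
        if cand.candidate_id not in matched_ids:
            n_commission += 1
            outcomes.append(MatchOutcome("commission", candidate_id=cand.candidate_id))
    rate = n_commission / len(candidates) if candidates else 0.0
    return MatchResult(outcomes=outcomes, assignments=assignments,
                       n_both=n_both, n_omission=n_omission,
                       n_commission=n_commission, n_candidates=len(candidates),
                       commission_rate=rate, detected=detected)


def abundance_pairs(match: MatchResult, candidates: list[RetrievalCandidate],
                    registry: list[ColonyRecord]) -> list[tuple[str, float, int]]:
    """(colony_id, retrieved guano area m^2, VHR abundance) for detected
    colonies; area is summed over all candidates assigned to the colony."""
    by_id = {c.candidate_id: c for c in candidates}
    pairs = []
    for rec in registry:
        ids = match.assignments.get(rec.colony_id, [])
        if ids:
            area = sum(by_id[cid].guano_area for cid in ids)
            pairs.append((rec.colony_id, area, rec.n_vhr))
    return pairs
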