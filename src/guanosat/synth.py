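"""Synthetic colony registries, spectral scenes and reference observations.

The generator emulates the statistical world assumed by the survey
analysis: colony sizes (breeding pairs) follow a region-specific
lognormal law; each colony leaves a guano footprint whose area is
abundance divided by an "apparent density" (nests per m^2 of detected
guano); footprints appear in a 6-band, 30 m-pixel reflectance raster as
contiguous blobs of a spectrally distinct guano class over background
classes (rock, soil, snow, water, vegetation, optional confusers); cloud
and shadow occlusion knock pixels out of the valid mask; and a
very-high-resolution (VHR) reference survey observes each colony's
abundance with lognormal error of known coefficient of variation.

Region parameter defaults are the published continental / Antarctic
Peninsula values for the Adelie penguin survey this design follows:
lognormal (mu, sigma) of log breeding pairs, apparent density in
nests/m^2, and logistic detection coefficients (intercept, slope per
breeding pair).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, ParameterError

PIXEL_SIZE = 30.0
PIXEL_AREA = PIXEL_SIZE * PIXEL_SIZE
BAND_NAMES = ("B1", "B2", "B3", "B4", "B5", "B7")
N_BANDS = len(BAND_NAMES)

REGIONS = ("continent", "peninsula")


@dataclass(frozen=True)
class RegionParams:
    """Published per-region parameter block."""

    mu: float           # mean of log colony size (log breeding pairs)
    sigma: float        # SD of log colony size
    density: float      # apparent density, nests per m^2 of detected guano
    det_beta0: float    # logistic detection intercept (log-odds)
    det_beta1: float    # logistic detection slope (log-odds per breeding pair)


DEFAULT_REGION_PARAMS: dict[str, RegionParams] = {
    "continent": RegionParams(mu=8.06, sigma=2.34, density=0.34,
                              det_beta0=-1.00, det_beta1=0.0004),
    "peninsula": RegionParams(mu=6.64, sigma=2.19, density=0.52,
                              det_beta0=-1.72, det_beta1=0.0003),
}

#: Fallback constant coefficient of variation of the VHR reference count.
DEFAULT_VHR_CV = 0.1

#: Accuracy-category rule: (upper size bound, cv).  Small colonies are
#: field-countable to a few percent; very large colonies are
#: photo-interpreted with much coarser precision.
VHR_ACCURACY_CATEGORIES = ((1_000, 0.05), (10_000, 0.10),
                           (100_000, 0.20), (float("inf"), 0.30))


def vhr_cv_for_size(n_true: int) -> float:
    """Per-colony VHR observation CV from the accuracy-category rule."""
    for bound, cv in VHR_ACCURACY_CATEGORIES:
        if n_true < bound:
            return cv
    return VHR_ACCURACY_CATEGORIES[-1][1]


@dataclass
class ColonyRecord:
    """One breeding colony in a synthetic registry.

    ``x``/``y`` are scene-local metric coordinates (m), origin at the
    top-left pixel corner, x east along columns, y south along rows.
    """

    colony_id: str
    region: str
    x: float
    y: float
    n_true: int
    n_vhr: int
    vhr_cv: float
    guano_area_true: float
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ParameterError(f"unknown region {self.region!r}")
        if self.n_true < 1:
            raise ParameterError("n_true must be >= 1")

    @property
    def footprint_pixels(self) -> int:
        """Number of raster pixels the true guano footprint occupies."""
        return max(1, int(round(self.guano_area_true / PIXEL_AREA)))


@dataclass(frozen=True)
class VhrSampler:
    """Sampling distribution of a VHR abundance observation.

    Lognormal with median ``median`` and log-scale SD ``sdlog``;
    repeated independent draws emulate re-observing the colony, which
    the aggregation null distribution requires.
    """

    median: float
    sdlog: float

    def draw(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        if self.sdlog == 0.0:
            out = np.full(size if size is not None else (), self.median)
            return float(out) if size is None else out
        z = rng.normal(0.0, self.sdlog, size)
        return np.exp(np.log(self.median) + z)


def vhr_sdlog(cv: float) -> float:
    """Log-scale SD implied by a coefficient of variation."""
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    return math.sqrt(math.log1p(cv * cv))


def simulate_vhr_observation(n_true: int, cv: float, seed=None):
    """Observe a colony of ``n_true`` pairs with lognormal error.

    Returns ``(n_vhr, sampler)`` where ``n_vhr`` is one rounded draw and
    ``sampler`` describes the full sampling distribution (median
    ``n_true``) for repeated independent draws.
    """
    sdlog = vhr_sdlog(cv)
    sampler = VhrSampler(median=float(n_true), sdlog=sdlog)
    if cv == 0.0:
        return int(n_true), sampler
    rng = np.random.default_rng(seed)
    n_vhr = int(round(float(sampler.draw(rng))))
    return max(0, n_vhr), sampler


def colony_sampler(record: ColonyRecord) -> VhrSampler:
    """Sampling distribution centred on the recorded VHR observation."""
    return VhrSampler(median=float(max(record.n_vhr, 1)), sdlog=vhr_sdlog(record.vhr_cv))


# ---------------------------------------------------------------------------
# Registry generation
# ---------------------------------------------------------------------------

def _footprint_half_extent(k_pixels: int) -> int:
    # blob = k nearest pixels to the seed, i.e. a disc of radius ~sqrt(k/pi)
    return int(math.ceil(math.sqrt(k_pixels / math.pi))) + 2


def _pack_cells(sides: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Shelf-pack square cells; return (row, col) centers in pixels and shape."""
    order = np.argsort(-sides, kind="stable")
    width = int(max(sides.max(initial=1),
                    math.ceil(math.sqrt(float(np.sum(sides.astype(np.int64) ** 2)))) + sides.max(initial=1)))
    rows = np.zeros(len(sides), dtype=float)
    cols = np.zeros(len(sides), dtype=float)
    x = 0
    y = 0
    shelf_h = 0
    for i in order:
        s = int(sides[i])
        if x + s > width:
            y += shelf_h
            x = 0
            shelf_h = 0
        rows[i] = y + s / 2.0
        cols[i] = x + s / 2.0
        x += s
        shelf_h = max(shelf_h, s)
    total_rows = y + shelf_h
    return rows, cols, (int(total_rows) + 2, width + 2)


def sample_colony_registry(n_colonies, size_params=None, density=None,
                           vhr_cv=None, seed=None,
                           region_prefix: str = "") -> list[ColonyRecord]:
    """Draw a synthetic colony registry.

    Parameters
    ----------
    n_colonies
        Either ``{"continent": 180, "peninsula": 64}`` or an int applied
        to every region.
    size_params
        Optional ``{region: (mu, sigma)}`` of the lognormal size law;
        defaults to the published values.
    density
        Optional ``{region: nests_per_m2}``; defaults published values.
    vhr_cv
        Coefficient of variation of the VHR reference observation; a
        float applies to every colony, ``None`` (default) uses the
        size-dependent accuracy-category rule.

    Colony sizes are a discretized lognormal (round of a continuous
    variate, floored at 1 breeding pair); ``guano_area_true`` is size
    divided by apparent density.  Locations are shelf-packed per region
    so footprints never overlap.
    """
    if not isinstance(n_colonies, dict):
        n_colonies = {r: int(n_colonies) for r in REGIONS}
    rng = np.random.default_rng(seed)
    records: list[ColonyRecord] = []
    for region, count in n_colonies.items():
        if region not in REGIONS:
            raise ParameterError(f"unknown region {region!r}")
        if count < 0:
            raise ParameterError("n_colonies must be >= 0")
        defaults = DEFAULT_REGION_PARAMS[region]
        mu, sigma = (size_params[region] if size_params else (defaults.mu, defaults.sigma))
        dens = density[region] if density else defaults.density
        if sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if dens <= 0:
            raise ParameterError("density must be > 0")
        if count == 0:
            continue
        n_true = np.maximum(1, np.round(np.exp(rng.normal(mu, sigma, count)))).astype(np.int64)
        areas = n_true / dens
        k_pix = np.maximum(1, np.round(areas / PIXEL_AREA)).astype(np.int64)
        sides = np.array([2 * _footprint_half_extent(int(k)) + 3 for k in k_pix])
        prow, pcol, _shape = _pack_cells(sides)
        for i in range(count):
            cv = vhr_cv_for_size(int(n_true[i])) if vhr_cv is None else float(vhr_cv)
            n_obs, _ = simulate_vhr_observation(
                int(n_true[i]), cv, seed=rng.integers(0, 2**31 - 1))
            records.append(ColonyRecord(
                colony_id=f"{region_prefix}{region[:4]}-{i:04d}",
                region=region,
                x=float(pcol[i] * PIXEL_SIZE),
                y=float(prow[i] * PIXEL_SIZE),
                n_true=int(n_true[i]),
                n_vhr=n_obs,
                vhr_cv=cv,
                guano_area_true=float(areas[i]),
            ))
    return records


def scene_shape(records: list[ColonyRecord], margin: int = 2) -> tuple[int, int]:
    """Smallest raster (rows, cols) that contains every colony footprint."""
    if not records:
        return (margin * 2 + 1, margin * 2 + 1)
    max_r = 0.0
    max_c = 0.0
    for rec in records:
        h = _footprint_half_extent(rec.footprint_pixels)
        max_r = max(max_r, rec.y / PIXEL_SIZE + h)
        max_c = max(max_c, rec.x / PIXEL_SIZE + h)
    return (int(math.ceil(max_r)) + margin, int(math.ceil(max_c)) + margin)


# ---------------------------------------------------------------------------
# Spectral library
# ---------------------------------------------------------------------------

@dataclass
class SpectralClass:
    """A surface class: multivariate-normal band reflectances.

    ``guano_mix`` > 0 marks a confuser class: each rendered pixel is
    drawn from the guano class with that probability instead, so the
    class overlaps the guano ellipsoid at a controlled rate.
    """

    name: str
    mean: np.ndarray
    cov: np.ndarray
    guano_mix: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (N_BANDS,) or self.cov.shape != (N_BANDS, N_BANDS):
            raise ParameterError("class mean/cov must be 6-band")
        if np.any(self.mean < 0) or np.any(self.mean > 1):
            raise ParameterError("reflectance means must lie in [0, 1]")
        # require positive semi-definite; a zero matrix (noise-free
        # class) is allowed and draws collapse to the mean
        w, v = np.linalg.eigh(self.cov)
        if w.min() < -1e-12 * max(abs(w).max(), 1.0):
            raise ParameterError(f"covariance of class {self.name!r} "
                                 "is not positive semi-definite")
        self._chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        z = rng.standard_normal((n, N_BANDS))
        return self.mean + z @ self._chol.T


@dataclass
class SpectralLibrary:
    """Named surface classes; one must be called ``guano``."""

    classes: dict[str, SpectralClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "guano" not in self.classes:
            raise ParameterError("library must contain a 'guano' class")

    def __getitem__(self, name: str) -> SpectralClass:
        return self.classes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.classes

    def add_confuser(self, name: str, overlap: float, base_mean=None,
                     noise_sd: float = 0.012) -> None:
        """Add a background class that lands inside the guano spectral
        distribution with probability ``overlap``."""
        if not 0.0 <= overlap <= 1.0:
            raise ParameterError("overlap must be in [0, 1]")
        mean = np.asarray(base_mean if base_mean is not None
                          else [0.12, 0.13, 0.15, 0.17, 0.20, 0.18], dtype=float)
        self.classes[name] = SpectralClass(
            name, mean, np.eye(N_BANDS) * noise_sd**2, guano_mix=overlap)

    def sample_training_pixels(self, class_name: str, n: int, seed=None) -> np.ndarray:
        """Draw labelled training pixels (no mixture contamination)."""
        rng = np.random.default_rng(seed)
        return self[class_name].sample(rng, n)


def default_library(noise_sd: float = 0.012) -> SpectralLibrary:
    """Six-band reflectance library with guano and five background classes.

    Means are plausible top-of-atmosphere reflectances; with the default
    noise SD the guano class sits >= 5 pooled SD from every background
    class in band space, matching the separability the retrieval
    training set exhibits in practice.
    """
    def cls(name, mean):
        return SpectralClass(name, np.asarray(mean), np.eye(N_BANDS) * noise_sd**2)

    classes = {
        "guano": cls("guano", [0.18, 0.20, 0.22, 0.24, 0.26, 0.22]),
        "rock": cls("rock", [0.10, 0.11, 0.12, 0.13, 0.15, 0.14]),
        "soil": cls("soil", [0.14, 0.16, 0.18, 0.22, 0.30, 0.28]),
        "snow": cls("snow", [0.90, 0.90, 0.85, 0.80, 0.35, 0.25]),
        "water": cls("water", [0.06, 0.05, 0.04, 0.03, 0.02, 0.01]),
        "vegetation": cls("vegetation", [0.05, 0.06, 0.05, 0.30, 0.25, 0.12]),
    }
    return SpectralLibrary(classes)


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

@dataclass
class SpectralScene:
    """A 6-band reflectance raster with masks.

    ``bands`` is (6, rows, cols) float32 top-of-atmosphere reflectance in
    band order B1..B5, B7; 30 m square pixels (900 m^2).  ``valid_mask``
    is False under cloud, shadow or water; ``truth_guano_mask`` marks the
    rendered guano pixels (synthetic truth layer).
    """

    bands: np.ndarray
    valid_mask: np.ndarray
    truth_guano_mask: np.ndarray
    pixel_size: float = PIXEL_SIZE
    scene_id: str = "scene"
    band_names: tuple = BAND_NAMES

    def __post_init__(self) -> None:
        if self.bands.ndim != 3 or self.bands.shape[0] != len(self.band_names):
            raise ParameterError("bands must be (n_bands, rows, cols)")
        shape = self.bands.shape[1:]
        if self.valid_mask.shape != shape or self.truth_guano_mask.shape != shape:
            raise ParameterError("mask layers must match band geometry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    @property
    def pixel_area(self) -> float:
        return self.pixel_size ** 2


def _blob_pixels(row: int, col: int, k: int, shape: tuple[int, int]):
    """k contiguous pixels grown by nearest-pixel accretion from a seed."""
    h = _footprint_half_extent(k)
    rr, cc = np.mgrid[row - h:row + h + 1, col - h:col + h + 1]
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    order = np.argsort(d2.ravel(), kind="stable")[:k]
    r = rr.ravel()[order]
    c = cc.ravel()[order]
    if r.min() < 0 or c.min() < 0 or r.max() >= shape[0] or c.max() >= shape[1]:
        raise GeometryError("colony footprint exceeds scene bounds")
    return r, c


def _cloud_blob_mask(shape, fraction, rng, radius_range=(2, 6)) -> np.ndarray:
    """Occlusion mask from random disks until ~``fraction`` of the scene
    is covered.  Disk-shaped occlusion makes non-detection size-dependent:
    a one-pixel colony vanishes under any overlapping disk, while a
    footprint wider than the largest disk can never be fully covered by
    one, so large colonies are essentially always retrieved — the
    structure a size-biased survey assumes."""
    mask = np.zeros(shape, dtype=bool)
    if fraction <= 0:
        return mask
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    target = fraction * mask.size
    covered = 0
    guard = 0
    max_disks = 100 * int(np.ceil(target / max(1.0, np.pi * radius_range[0] ** 2)))
    while covered < target and guard < max_disks:
        guard += 1
        r0 = int(rng.integers(0, shape[0]))
        c0 = int(rng.integers(0, shape[1]))
        rad = int(rng.integers(radius_range[0], radius_range[1] + 1))
        rr0, rr1 = max(0, r0 - rad), min(shape[0], r0 + rad + 1)
        cc0, cc1 = max(0, c0 - rad), min(shape[1], c0 + rad + 1)
        yy, xx = np.ogrid[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0]
        disk = yy * yy + xx * xx <= rad * rad
        sub = mask[rr0:rr1, cc0:cc1]
        covered += int((disk & ~sub).sum())
        sub |= disk
    return mask


def render_scene(records: list[ColonyRecord], library: SpectralLibrary,
                 shape: tuple[int, int] | None = None, background: str | np.ndarray = "rock",
                 cloud_fraction: float = 0.0, shadow_fraction: float = 0.0,
                 seed=None, scene_id: str = "scene",
                 cloud_radius_range: tuple[int, int] = (2, 6)) -> SpectralScene:
    """Render a registry into a 6-band reflectance scene.

    Each colony contributes ``round(guano_area_true / 900)`` contiguous
    guano pixels (minimum 1), grown by nearest-pixel accretion from its
    seed pixel.  Every pixel's band vector is drawn from its class's
    multivariate normal.  Cloud and shadow occlusion is rendered as
    random disks until the requested scene fractions are covered;
    occluded and water pixels have ``valid_mask`` False.
    """
    if shape is None:
        shape = scene_shape(records)
    rng = np.random.default_rng(seed)
    class_names = list(library.classes)
    name_to_idx = {n: i for i, n in enumerate(class_names)}

    if isinstance(background, str):
        if background not in library:
            raise ParameterError(f"unknown background class {background!r}")
        class_map = np.full(shape, name_to_idx[background], dtype=np.int32)
    else:
        class_map = np.asarray(background, dtype=np.int32)
        if class_map.shape != tuple(shape):
            raise ParameterError("background map shape mismatch")
        if class_map.min() < 0 or class_map.max() >= len(class_names):
            raise ParameterError("background map holds unknown class index")

    truth = np.zeros(shape, dtype=bool)
    gi = name_to_idx["guano"]
    for rec in records:
        row = int(round(rec.y / PIXEL_SIZE))
        col = int(round(rec.x / PIXEL_SIZE))
        r, c = _blob_pixels(row, col, rec.footprint_pixels, tuple(shape))
        class_map[r, c] = gi
        truth[r, c] = True

    # confuser classes draw a fraction of their pixels from the guano class
    draw_map = class_map.copy()
    for name, sc in library.classes.items():
        if sc.guano_mix > 0:
            sel = class_map == name_to_idx[name]
            flip = sel & (rng.random(shape) < sc.guano_mix)
            draw_map[flip] = gi

    bands = np.empty((N_BANDS,) + tuple(shape), dtype=np.float32)
    flat = bands.reshape(N_BANDS, -1)
    draw_flat = draw_map.ravel()
    for idx, name in enumerate(class_names):
        sel = np.flatnonzero(draw_flat == idx)
        if sel.size:
            flat[:, sel] = np.clip(library[name].sample(rng, sel.size), 0.0, 1.0).T

    occl = min(1.0, cloud_fraction + shadow_fraction)
    valid = ~_cloud_blob_mask(tuple(shape), occl, rng, cloud_radius_range)
    valid &= class_map != name_to_idx.get("water", -1)
    return SpectralScene(bands=bands, valid_mask=valid, truth_guano_mask=truth,
                         scene_id=scene_id)
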