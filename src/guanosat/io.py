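"""File formats: registry CSV, scene rasters, candidate CSV, KML, reports.

Scenes travel in either of two dialects, both with a JSON sidecar
describing band order and pixel size:

* multi-band TIFF (float32 reflectance) plus uint8 mask TIFFs, or
* a single compressed ``.npz`` container holding bands and masks.

A write-then-read round trip preserves every field (reflectance to
float32 precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import SchemaError
from .retrieval import MatchResult, RetrievalCandidate
from .synth import BAND_NAMES, PIXEL_SIZE, REGIONS, ColonyRecord, SpectralScene

REGISTRY_COLUMNS = ["colony_id", "region", "x_m", "y_m", "n_true", "n_vhr",
                    "vhr_cv", "guano_area_true_m2", "excluded"]

CANDIDATE_COLUMNS = ["candidate_id", "scene_id", "pixel_count", "guano_area_m2",
                     "centroid_x", "centroid_y", "matched_colony_id", "outcome"]


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def write_registry(records: list[ColonyRecord], path) -> None:
    rows = [{
        "colony_id": r.colony_id, "region": r.region, "x_m": r.x, "y_m": r.y,
        "n_true": r.n_true, "n_vhr": r.n_vhr, "vhr_cv": r.vhr_cv,
        "guano_area_true_m2": r.guano_area_true, "excluded": r.excluded,
    } for r in records]
    # %.17g round-trips doubles exactly through text
    pd.DataFrame(rows, columns=REGISTRY_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_registry(path) -> list[ColonyRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"registry is missing columns: {sorted(missing)}")
    bad = set(df["region"].unique()) - set(REGIONS)
    if bad:
        raise SchemaError(f"unknown region labels: {sorted(bad)}")
    return [ColonyRecord(
        colony_id=str(row.colony_id), region=str(row.region),
        x=float(row.x_m), y=float(row.y_m), n_true=int(row.n_true),
        n_vhr=int(row.n_vhr), vhr_cv=float(row.vhr_cv),
        guano_area_true=float(row.guano_area_true_m2),
        excluded=bool(row.excluded),
    ) for row in df.itertuples()]


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

def _sidecar(scene: SpectralScene) -> dict:
    return {"band_order": list(scene.band_names),
            "pixel_size_m": scene.pixel_size,
            "scene_id": scene.scene_id,
            "shape": list(scene.shape)}


def write_scene(scene: SpectralScene, path) -> None:
    """Write a scene; dialect chosen by extension (``.npz`` or ``.tif``)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, bands=scene.bands,
                            valid_mask=scene.valid_mask.astype(np.uint8),
                            truth_guano_mask=scene.truth_guano_mask.astype(np.uint8))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, scene.bands.astype(np.float32),
                         photometric="minisblack")
        tifffile.imwrite(path.with_suffix(".valid.tif"),
                         scene.valid_mask.astype(np.uint8))
        tifffile.imwrite(path.with_suffix(".truth.tif"),
                         scene.truth_guano_mask.astype(np.uint8))
    else:
        raise SchemaError(f"unknown scene dialect {path.suffix!r}; "
                          "use .npz or .tif")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(_sidecar(scene), indent=2, sort_keys=True))


def read_scene(path) -> SpectralScene:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    if path.suffix == ".npz":
        with np.load(path) as z:
            for key in ("bands", "valid_mask", "truth_guano_mask"):
                if key not in z:
                    raise SchemaError(f"scene container missing array {key!r}")
            bands = z["bands"]
            valid = z["valid_mask"].astype(bool)
            truth = z["truth_guano_mask"].astype(bool)
    elif path.suffix in (".tif", ".tiff"):
        bands = tifffile.imread(path)
        valid = tifffile.imread(path.with_suffix(".valid.tif")).astype(bool)
        truth = tifffile.imread(path.with_suffix(".truth.tif")).astype(bool)
    else:
        raise SchemaError(f"unknown scene dialect {path.suffix!r}")
    if bands.ndim != 3 or bands.shape[0] != len(BAND_NAMES):
        raise SchemaError(f"expected {len(BAND_NAMES)} bands, got shape {bands.shape}")
    return SpectralScene(bands=bands, valid_mask=valid, truth_guano_mask=truth,
                         pixel_size=float(meta.get("pixel_size_m", PIXEL_SIZE)),
                         scene_id=str(meta.get("scene_id", path.stem)))


# ---------------------------------------------------------------------------
# Candidates / outcomes
# ---------------------------------------------------------------------------

def write_candidates(candidates: list[RetrievalCandidate], path,
                     match: MatchResult | None = None) -> None:
    matched: dict[str, str] = {}
    outcome: dict[str, str] = {}
    if match is not None:
        for colony_id, ids in match.assignments.items():
            for i, cid in enumerate(ids):
                matched[cid] = colony_id
                outcome[cid] = "both" if i == 0 else "absorbed"
        for o in match.outcomes:
            if o.outcome == "commission":
                outcome[o.candidate_id] = "commission"
    rows = [{
        "candidate_id": c.candidate_id, "scene_id": c.scene_id,
        "pixel_count": c.pixel_count, "guano_area_m2": c.guano_area,
        "centroid_x": c.x, "centroid_y": c.y,
        "matched_colony_id": matched.get(c.candidate_id, ""),
        "outcome": outcome.get(c.candidate_id, ""),
    } for c in candidates]
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, index=False)


def export_candidates_kml(candidates: list[RetrievalCandidate], path,
                          name: str = "retrievals") -> None:
    """Minimal KML of candidate placemarks.

    Synthetic scenes carry scene-local metric coordinates, so the
    placemark coordinates are metres, not geographic degrees; the file
    is for structural compatibility with KML-consuming tooling.
    """
    def esc(s):
        return (str(s).replace("&", "&amp;").replace("<", "&lt;")
                .replace(">", "&gt;"))
    parts = ['<?xml version="1.0" encoding="UTF-8"?>',
             '<kml xmlns="http://www.opengis.net/kml/2.2"><Document>',
             f"<name>{esc(name)}</name>"]
    for c in candidates:
        parts.append(
            f"<Placemark><name>{esc(c.candidate_id)}</name>"
            f"<description>pixels={c.pixel_count} area_m2={c.guano_area:.0f}"
            f"</description><Point><coordinates>{c.x:.1f},{c.y:.1f},0"
            f"</coordinates></Point></Placemark>")
    parts.append("</Document></kml>")
    Path(path).write_text("\n".join(parts))


# ---------------------------------------------------------------------------
# Reference table (optional external data)
# ---------------------------------------------------------------------------

_REFERENCE_ALIASES = {
    "colony_id": ("colony_id", "colony", "site", "site_name", "name"),
    "region": ("region", "area", "zone"),
    "pixel_count": ("pixel_count", "pixels", "n_pixels", "landsat_pixels"),
    "guano_area_m2": ("guano_area_m2", "guano_area", "area_m2", "area"),
    "abundance": ("abundance", "n_vhr", "pairs", "breeding_pairs", "nests", "n"),
    "detected": ("detected", "landsat_detected", "m", "retrieved"),
}


def load_reference_table(path) -> pd.DataFrame:
    """Load an external reference survey table (XLSX or CSV).

    Column names are matched case-insensitively against common aliases
    and normalized to: colony_id, region, pixel_count, guano_area_m2,
    abundance, detected.  Columns that cannot be identified are kept
    untouched; a table without an abundance column is rejected.
    """
    path = Path(path)
    df = pd.read_excel(path) if path.suffix in (".xlsx", ".xls") \
        else pd.read_csv(path)
    lower = {str(c).strip().lower().replace(" ", "_"): c for c in df.columns}
    renames = {}
    for canon, aliases in _REFERENCE_ALIASES.items():
        for alias in aliases:
            if alias in lower and canon not in renames.values():
                renames[lower[alias]] = canon
                break
    df = df.rename(columns=renames)
    if "abundance" not in df.columns:
        raise SchemaError("reference table has no recognizable abundance column")
    return df


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=float))
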