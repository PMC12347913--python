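"""Readers and writers for labeled sections.

Two on-disk dialects are supported:

* **Raster directory** — one single-channel indexed PNG per class layer
  (0 = background, 255 = class), an optional ``capsule.png`` marking the
  capsule-annotated part of the tissue boundary, and a versioned sidecar
  ``meta.json`` holding the calibration, section kind and the code→name
  map.  Layers are per *class*, not per tree level, because sibling
  aggregate layers may legitimately overlap.
* **GeoJSON** — a FeatureCollection of Polygon/MultiPolygon features with
  ``properties: {"class_name": ...}`` in pixel coordinates (x right,
  y down, pixel-centered, 0-based), with the calibration in the top-level
  ``properties`` object.  This serves QuPath-style annotation workflows.

Vectorization uses half-level marching squares, so rasterize∘vectorize is
the identity on boolean masks (pixel centers are never on the contour).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image
from skimage import measure

from .section import Calibration, LabeledSection
from .taxonomy import ClassTaxonomy, TaxonomyError, default_taxonomy

FORMAT_NAME = "nephromorph-section"
FORMAT_VERSION = 1
CAPSULE_LAYER = "Kidney capsule"  # reserved GeoJSON class name, not a taxonomy class

__all__ = [
    "load_section",
    "save_section",
    "save_geojson",
    "load_geojson",
    "vectorize_mask",
    "rasterize_rings",
]


# ---------------------------------------------------------------------------
# mask <-> polygon conversion

def vectorize_mask(mask: np.ndarray) -> list[np.ndarray]:
    """Boundary rings of a boolean mask as (N, 2) arrays of (x, y) px.

    Rings come from the 0.5-level marching-squares contour of the padded
    mask (8-connected foreground); both outer boundaries and holes are
    returned.  Ring orientation is as produced by marching squares; nesting
    parity, not orientation, determines holes.
    """
    if not mask.any():
        return []
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5, fully_connected="high")
    rings = []
    for c in contours:
        xy = np.column_stack([c[:, 1] - 1.0, c[:, 0] - 1.0])  # (x, y)
        rings.append(xy)
    return rings


def rasterize_rings(rings: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    """Fill rings onto a pixel grid by even-odd parity of pixel centers.

    A pixel belongs to the region when its center lies inside an odd
    number of rings.  Centers exactly on a ring edge are resolved by a
    tiny positive offset, i.e. boundaries are inclusive on the low-x/low-y
    side — a polygon ``(0,0)-(w,0)-(w,h)-(0,h)`` fills exactly ``w × h``
    pixels.
    """
    out = np.zeros(shape, dtype=bool)
    eps = 1e-9
    for ring in rings:
        if len(ring) < 3:
            continue
        path = MplPath(ring)
        xmin, ymin = np.floor(ring.min(axis=0)).astype(int)
        xmax, ymax = np.ceil(ring.max(axis=0)).astype(int)
        xmin, ymin = max(xmin, 0), max(ymin, 0)
        xmax, ymax = min(xmax, shape[1] - 1), min(ymax, shape[0] - 1)
        if xmax < xmin or ymax < ymin:
            continue
        xs = np.arange(xmin, xmax + 1)
        ys = np.arange(ymin, ymax + 1)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel() + eps, gy.ravel() + eps])
        inside = path.contains_points(pts).reshape(gy.shape)
        out[ymin : ymax + 1, xmin : xmax + 1] ^= inside
    return out


# ---------------------------------------------------------------------------
# raster directory dialect

def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name.lower())


def save_section(section: LabeledSection, out_dir: str | Path) -> Path:
    """Write a section as per-class PNG layers plus ``meta.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, mask in section.masks.items():
        code = section.taxonomy.code(name)
        fname = f"class_{code:02d}_{_slug(name)}.png"
        Image.fromarray(mask.astype(np.uint8) * 255).save(out / fname)
        entries.append({"code": code, "name": name, "file": fname})
    capsule_file = None
    if section.capsule is not None:
        capsule_file = "capsule.png"
        Image.fromarray(section.capsule.astype(np.uint8) * 255).save(out / capsule_file)
    meta = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "microns_per_pixel": section.calibration.microns_per_pixel,
        "section_thickness_um": section.calibration.section_thickness_um,
        "kind": section.kind,
        "shape": list(section.shape),
        "classes": sorted(entries, key=lambda e: e["code"]),
        "capsule_file": capsule_file,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def _load_raster_dir(
    path: Path, taxonomy: ClassTaxonomy, calibration: Calibration | None
) -> LabeledSection:
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("format") != FORMAT_NAME:
        raise ValueError(f"{path} is not a {FORMAT_NAME} directory")
    if calibration is None:
        calibration = Calibration(
            microns_per_pixel=meta["microns_per_pixel"],
            section_thickness_um=meta.get("section_thickness_um", 2.5),
        )
    masks: dict[str, np.ndarray] = {}
    for entry in meta["classes"]:
        name = entry["name"]
        if name not in taxonomy:
            raise TaxonomyError(f"class {name!r} (code {entry['code']}) not in taxonomy")
        if taxonomy.code(name) != entry["code"]:
            raise TaxonomyError(
                f"code mismatch for {name!r}: file says {entry['code']}, "
                f"taxonomy says {taxonomy.code(name)}"
            )
        arr = np.asarray(Image.open(path / entry["file"]))
        masks[name] = arr > 0
    capsule = None
    if meta.get("capsule_file"):
        capsule = np.asarray(Image.open(path / meta["capsule_file"])) > 0
    return LabeledSection(
        taxonomy=taxonomy,
        calibration=calibration,
        masks=masks,
        capsule=capsule,
        kind=meta.get("kind", "needle-core"),
    )


# ---------------------------------------------------------------------------
# GeoJSON dialect

def save_geojson(section: LabeledSection, path: str | Path) -> Path:
    """Write a section as a GeoJSON FeatureCollection in pixel coordinates."""
    features = []

    def mask_features(name: str, mask: np.ndarray) -> None:
        rings = vectorize_mask(mask)
        if not rings:
            return
        features.append(
            {
                "type": "Feature",
                "properties": {"class_name": name},
                # rings as a single multi-ring geometry; even-odd fill rule
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [r.tolist() for r in rings],
                },
            }
        )

    for name, mask in section.masks.items():
        mask_features(name, mask)
    if section.capsule is not None:
        mask_features(CAPSULE_LAYER, section.capsule)
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "format": FORMAT_NAME,
            "version": FORMAT_VERSION,
            "microns_per_pixel": section.calibration.microns_per_pixel,
            "section_thickness_um": section.calibration.section_thickness_um,
            "kind": section.kind,
            "shape": list(section.shape),
        },
        "features": features,
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_geojson(
    path: str | Path,
    taxonomy: ClassTaxonomy | None = None,
    calibration: Calibration | None = None,
    shape: tuple[int, int] | None = None,
) -> LabeledSection:
    """Read a GeoJSON annotation set and rasterize it at the calibration grid."""
    taxonomy = taxonomy or default_taxonomy()
    doc = json.loads(Path(path).read_text())
    props = doc.get("properties", {})
    if calibration is None:
        calibration = Calibration(
            microns_per_pixel=props.get("microns_per_pixel", 0.5),
            section_thickness_um=props.get("section_thickness_um", 2.5),
        )
    if shape is None:
        if "shape" in props:
            shape = tuple(props["shape"])
        else:
            # smallest frame containing all vertices
            xmax = ymax = 0.0
            for feat in doc["features"]:
                for ring in _feature_rings(feat):
                    arr = np.asarray(ring, dtype=float)
                    xmax = max(xmax, arr[:, 0].max())
                    ymax = max(ymax, arr[:, 1].max())
            shape = (int(np.ceil(ymax)) + 1, int(np.ceil(xmax)) + 1)
    masks: dict[str, np.ndarray] = {}
    capsule = None
    for feat in doc["features"]:
        name = feat.get("properties", {}).get("class_name")
        rings = [np.asarray(r, dtype=float) for r in _feature_rings(feat)]
        filled = rasterize_rings(rings, shape)
        if name == CAPSULE_LAYER:
            capsule = filled if capsule is None else (capsule | filled)
            continue
        if name not in taxonomy:
            raise TaxonomyError(f"feature class {name!r} not in taxonomy")
        if name in masks:
            masks[name] |= filled
        else:
            masks[name] = filled
    return LabeledSection(
        taxonomy=taxonomy,
        calibration=calibration,
        masks=masks,
        capsule=capsule,
        kind=props.get("kind", "needle-core"),
    )


def _feature_rings(feat: dict) -> list:
    geom = feat["geometry"]
    if geom["type"] == "Polygon":
        return list(geom["coordinates"])
    if geom["type"] == "MultiPolygon":
        return [ring for poly in geom["coordinates"] for ring in poly]
    raise ValueError(f"unsupported geometry type {geom['type']!r}")


# ---------------------------------------------------------------------------
# dispatch

def load_section(
    path: str | Path,
    taxonomy: ClassTaxonomy | None = None,
    calibration: Calibration | None = None,
    validate: bool = True,
) -> LabeledSection:
    """Load a section from a raster directory or a GeoJSON file.

    Nesting (child region inside parent region) is validated on load;
    violations raise :class:`~nephromorph.section.NestingViolationError`
    listing the offending classes.
    """
    taxonomy = taxonomy or default_taxonomy()
    p = Path(path)
    if p.is_dir():
        section = _load_raster_dir(p, taxonomy, calibration)
    elif p.suffix.lower() in {".geojson", ".json"}:
        section = load_geojson(p, taxonomy, calibration)
    else:
        raise ValueError(f"cannot infer section format from {p}")
    if validate:
        section.validate_nesting()
    if section.capsule is None:
        warnings.warn(f"{p}: no capsule annotation found", stacklevel=2)
    return section
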