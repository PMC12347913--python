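"""Seeded synthetic kidney sections with exhaustive ground truth.

Real study material (patient whole-slide images and their segmentations)
cannot be redistributed, so this module generates label images of needle
cores and wedge sections that exercise every downstream measure: cortex
and medulla compartments, a capsule band along the anatomical outer edge
(needle cut edges carry no capsule), glomerular subclasses, packed
proximal/distal tubules, tubular-atrophy foci, arteries with intima and
lumen, arterioles with hyalinosis lesions, and deliberately edge-clipped
glomeruli.

Structures are laid out as vector shapes (circles, annuli, Fourier-blob
polygons) and rasterized afterwards, so true areas are known analytically
before any discretization.  The :class:`GroundTruth` carries every
structural count and derived measure "as generated":

* compartment areas come from the exact pixel rectangles;
* counts, ratios and mean areas of large structures use the analytic
  vector areas (discretization error is far below structure scale);
* mean AH-lesion area and luminal stenosis — quantities defined on small
  or thin raster regions (tens to hundreds of pixels) — use the
  generator's own per-structure rasterization bookkeeping, since at that
  scale the measurand *is* the label image.

Placement enforces guard margins so that strict-threshold rules can never
be decided differently by the analytic truth and the rasterized
measurement: AH lesion pairs avoid boundary distances in (470, 530) um
around the 500 um merge rule, and artery profile areas avoid
(7450, 8250) um^2 around the 7850 um^2 stenosis gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import taxonomy as tx
from .morphometry import (
    MorphometryResult,
    cortex_per_glomerulus_mm3,
    glomerular_volume_mm3,
)
from .section import Calibration, LabeledSection

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "ShapeRecord",
    "PackingError",
    "generate",
    "PerturbationSpec",
    "perturb_annotation",
    "donor_like_spec",
    "tumor_like_spec",
]


class PackingError(RuntimeError):
    """Requested structures cannot be placed without overlap."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic section.

    Structure sizes and composition default to the published cohort means
    for living kidney donors (mean glomerular profile area consistent with
    a 0.0028 mm^3 glomerular volume, proximal/distal tubule profile areas
    2768/1523 um^2, artery stenosis around 16%); counts are chosen to give
    donor-like densities on a scaled-down section.  The raster resolution
    defaults to 2.0 um/px: the measures are scale-equivariant, so density
    and ratio recovery does not require full-slide rasters.
    """

    kind: str = "needle-core"  # "needle-core" | "wedge"
    microns_per_pixel: float = 2.0
    section_thickness_um: float = 2.5
    cortex_area_mm2: float = 3.0
    medulla_area_mm2: float = 1.0
    core_width_mm: float = 1.0
    wedge_aspect: float = 2.0
    # counts
    n_nsg: int = 7
    n_edge_clipped_nsg: int = 1
    n_gsg: int = 1
    n_empty_capsule: int = 2
    n_ta_foci: int = 3
    n_arteries: int = 2
    n_arterioles: int = 8
    n_ah_lesions: int = 1
    n_interlobar: int = 1
    tubule_limit: int | None = None  # None = fill the tubulointerstitium
    # glomeruli
    glom_area_mean_um2: float = 16000.0
    glom_area_cv: float = 0.30
    gsg_area_mean_um2: float = 9000.0
    gsg_area_cv: float = 0.30
    empty_capsule_outer_area_um2: float = 8000.0
    empty_capsule_ring_fraction: float = 0.35
    # tubules
    prox_tubule_area_mean_um2: float = 2768.0
    dist_tubule_area_mean_um2: float = 1523.0
    tubule_area_cv: float = 0.12
    # tubular atrophy foci
    ta_area_mean_um2: float = 4000.0
    ta_area_cv: float = 0.30
    # vessels
    artery_area_mean_um2: float = 20000.0
    artery_area_cv: float = 0.25
    artery_lumen_fraction: float = 0.30
    artery_intima_fraction_mean: float = 0.06
    p_artery_no_intima: float = 0.3
    arteriole_area_mean_um2: float = 1500.0
    arteriole_area_cv: float = 0.35
    ah_area_mean_um2: float = 300.0
    ah_area_cv: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_nsg", "n_edge_clipped_nsg", "n_gsg", "n_empty_capsule",
            "n_ta_foci", "n_arteries", "n_arterioles", "n_ah_lesions",
            "n_interlobar",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "microns_per_pixel", "cortex_area_mm2", "glom_area_mean_um2",
            "gsg_area_mean_um2", "empty_capsule_outer_area_um2",
            "prox_tubule_area_mean_um2", "dist_tubule_area_mean_um2",
            "ta_area_mean_um2", "artery_area_mean_um2",
            "arteriole_area_mean_um2", "ah_area_mean_um2",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.medulla_area_mm2 < 0:
            raise ValueError("medulla_area_mm2 must be >= 0")
        if self.n_ah_lesions > self.n_arterioles:
            raise ValueError("n_ah_lesions cannot exceed n_arterioles")
        if self.kind not in ("needle-core", "wedge"):
            raise ValueError(f"unknown section kind {self.kind!r}")


@dataclass
class ShapeRecord:
    """Bookkeeping for one placed structure."""

    kind: str
    center_px: tuple[float, float]  # (x, y)
    bounding_r_px: float
    analytic_area_um2: float
    raster_px: int = 0
    raster_centroid_px: tuple[float, float] | None = None
    clipped: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    """True structural and derived measures of a generated scene."""

    measures: MorphometryResult
    structures: list[ShapeRecord]
    ah_merged_clusters: list[list[int]]  # indices into AH lesion records
    spec: SceneSpec


# ---------------------------------------------------------------------------
# sampling and painting helpers

def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _sample_area(
    rng: np.random.Generator,
    mean: float,
    cv: float,
    forbid: tuple[float, float] | None = None,
    lo: float | None = None,
    hi: float | None = None,
) -> float:
    for _ in range(1000):
        a = _lognormal(rng, mean, cv)
        if lo is not None and a < lo:
            continue
        if hi is not None and a > hi:
            continue
        if forbid is not None and forbid[0] < a < forbid[1]:
            continue
        return a
    raise PackingError(f"could not sample an admissible area around {mean}")


def _paint_disc(
    mask: np.ndarray, cx: float, cy: float, r: float,
    clip: np.ndarray | None = None,
) -> tuple[int, tuple[float, float]]:
    """Paint a disc; returns painted pixel count and raster centroid (x, y)."""
    h, w = mask.shape
    x0 = max(int(math.floor(cx - r)) - 1, 0)
    x1 = min(int(math.ceil(cx + r)) + 2, w)
    y0 = max(int(math.floor(cy - r)) - 1, 0)
    y1 = min(int(math.ceil(cy + r)) + 2, h)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    sel = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    if clip is not None:
        sel = sel & clip[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= sel
    n = int(sel.sum())
    if n == 0:
        return 0, (cx, cy)
    rows, cols = np.nonzero(sel)
    return n, (float(cols.mean()) + x0, float(rows.mean()) + y0)


def _paint_annulus(
    mask: np.ndarray, cx: float, cy: float, r_out: float, r_in: float
) -> int:
    h, w = mask.shape
    x0 = max(int(math.floor(cx - r_out)) - 1, 0)
    x1 = min(int(math.ceil(cx + r_out)) + 2, w)
    y0 = max(int(math.floor(cy - r_out)) - 1, 0)
    y1 = min(int(math.ceil(cy + r_out)) + 2, h)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    sel = (d2 <= r_out * r_out) & (d2 > r_in * r_in)
    mask[y0:y1, x0:x1] |= sel
    return int(sel.sum())


def _blob_polygon(
    rng: np.random.Generator, area_px2: float, n_points: int = 256
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """A smooth star-shaped blob with exactly the given analytic area.

    Radius r(t) = r0 (1 + sum_k a_k cos(k t + phi_k)); the polar-area
    integral gives area = pi r0^2 (1 + sum a_k^2 / 2), which fixes r0.
    Returns (x, y) vertex arrays (centered at 0), r0 and the bounding radius.
    """
    ks = np.array([2, 3, 4, 5])
    amps = rng.uniform(0.0, 0.12, size=ks.size)
    phis = rng.uniform(0.0, 2 * math.pi, size=ks.size)
    r0 = math.sqrt(area_px2 / (math.pi * (1.0 + 0.5 * float(np.sum(amps**2)))))
    t = np.linspace(0.0, 2 * math.pi, n_points, endpoint=False)
    r = r0 * (1.0 + (amps[:, None] * np.cos(ks[:, None] * t + phis[:, None])).sum(axis=0))
    return r * np.cos(t), r * np.sin(t), r0, r0 * (1.0 + float(amps.sum()))


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _paint_polygon(mask: np.ndarray, x: np.ndarray, y: np.ndarray) -> int:
    from skimage.draw import polygon as sk_polygon

    rr, cc = sk_polygon(y, x, shape=mask.shape)
    before = int(mask[rr, cc].sum())
    mask[rr, cc] = True
    return len(rr) - before


def _clipped_disc_area(r: float, h: float) -> float:
    """Area of a disc of radius r retained on one side of a straight cut.

    ``h`` is the signed distance from the disc center to the cut line,
    positive when the center lies on the retained side.
    """
    h = float(np.clip(h, -r, r))
    return r * r * math.acos(-h / r) + h * math.sqrt(max(r * r - h * h, 0.0))


# ---------------------------------------------------------------------------
# placement

class _Placer:
    """Rejection-sampling placer with pairwise bounding-circle exclusion."""

    def __init__(self, rng: np.random.Generator, gap_px: float = 4.0):
        self.rng = rng
        self.gap = gap_px
        self.placed: list[tuple[float, float, float]] = []  # (cx, cy, r)

    def fits(self, cx: float, cy: float, r: float) -> bool:
        for px, py, pr in self.placed:
            if (cx - px) ** 2 + (cy - py) ** 2 < (r + pr + self.gap) ** 2:
                return False
        return True

    def place(
        self,
        r: float,
        bounds: tuple[float, float, float, float],  # (x0, x1, y0, y1) inclusive region
        max_attempts: int = 4000,
        what: str = "structure",
    ) -> tuple[float, float]:
        x0, x1, y0, y1 = bounds
        if x1 - x0 < 2 * r or y1 - y0 < 2 * r:
            raise PackingError(f"{what} of radius {r:.1f}px does not fit in region")
        for _ in range(max_attempts):
            cx = self.rng.uniform(x0 + r, x1 - r)
            cy = self.rng.uniform(y0 + r, y1 - r)
            if self.fits(cx, cy, r):
                self.placed.append((cx, cy, r))
                return cx, cy
        raise PackingError(f"could not place {what} of radius {r:.1f}px")


# ---------------------------------------------------------------------------
# generation

_MARGIN = 8  # background frame around the tissue, px
_EDGE_MARGIN = 4  # interior structures keep this distance from compartment edges


def _frame_geometry(spec: SceneSpec) -> tuple[int, int, int]:
    """(tissue width px, cortex height px, medulla height px)."""
    mpp = spec.microns_per_pixel
    if spec.kind == "needle-core":
        w_px = max(int(round(spec.core_width_mm * 1000.0 / mpp)), 32)
    else:
        total_mm2 = spec.cortex_area_mm2 + spec.medulla_area_mm2
        h_mm = math.sqrt(total_mm2 / spec.wedge_aspect)
        w_px = max(int(round(spec.wedge_aspect * h_mm * 1000.0 / mpp)), 32)
    hc_px = max(int(round(spec.cortex_area_mm2 * 1e6 / (mpp * mpp) / w_px)), 16)
    hm_px = int(round(spec.medulla_area_mm2 * 1e6 / (mpp * mpp) / w_px))
    return w_px, hc_px, hm_px


def generate(spec: SceneSpec) -> tuple[LabeledSection, GroundTruth]:
    """Generate one synthetic labeled section and its ground truth.

    The same spec (including its seed) always yields a bit-identical
    raster.  Raises :class:`PackingError` if the requested structures
    cannot be placed; structures are never silently dropped.
    """
    rng = np.random.default_rng(spec.seed)
    mpp = spec.microns_per_pixel
    um2 = mpp * mpp
    w_px, hc_px, hm_px = _frame_geometry(spec)

    shape = (hc_px + hm_px + 2 * _MARGIN, w_px + 2 * _MARGIN)
    top, left = _MARGIN, _MARGIN
    bottom, right = top + hc_px + hm_px, left + w_px  # exclusive

    def rect_mask(r0, r1, c0, c1):
        m = np.zeros(shape, dtype=bool)
        m[r0:r1, c0:c1] = True
        return m

    cortex = rect_mask(top, top + hc_px, left, right)
    medulla = rect_mask(top + hc_px, bottom, left, right)
    tissue = cortex | medulla
    cortex_area_um2 = hc_px * w_px * um2
    medulla_area_um2 = hm_px * w_px * um2

    # capsule: the anatomical outer (top) edge of the tissue boundary
    rim = tissue & ~ndimage.binary_erosion(tissue)
    capsule = np.zeros(shape, dtype=bool)
    capsule[top : top + 2, left:right] = rim[top : top + 2, left:right]

    placer = _Placer(rng)
    records: list[ShapeRecord] = []
    m = _EDGE_MARGIN
    cortex_bounds = (left + m, right - m, top + m, top + hc_px - m)
    medulla_bounds = (left + m, right - m, top + hc_px + m, bottom - m)

    nsg_mask = np.zeros(shape, dtype=bool)
    gsg_mask = np.zeros(shape, dtype=bool)
    ec_mask = np.zeros(shape, dtype=bool)
    glom_filled = np.zeros(shape, dtype=bool)
    vessels = np.zeros(shape, dtype=bool)
    interlobar = np.zeros(shape, dtype=bool)
    intima = np.zeros(shape, dtype=bool)
    lumen = np.zeros(shape, dtype=bool)
    intima_med = np.zeros(shape, dtype=bool)
    lumen_med = np.zeros(shape, dtype=bool)
    ah_mask = np.zeros(shape, dtype=bool)
    ta_mask = np.zeros(shape, dtype=bool)

    # --- arteries (cortical and medullary interlobar) ---------------------
    def add_artery(kind: str, bounds, target_mask, intima_mask, lumen_mask, mean_area):
        area = _sample_area(
            rng, mean_area, spec.artery_area_cv, forbid=(7450.0, 8250.0)
        )
        r = math.sqrt(area / math.pi) / mpp
        cx, cy = placer.place(r, bounds, what=kind)
        n, cen = _paint_disc(target_mask, cx, cy, r)
        fl = spec.artery_lumen_fraction
        if rng.uniform() < spec.p_artery_no_intima:
            fi = 0.0
        else:
            fi = min(rng.uniform(0.3, 1.7) * spec.artery_intima_fraction_mean, 0.9 - fl)
        r_l = r * math.sqrt(fl)
        n_l, _ = _paint_disc(lumen_mask, cx, cy, r_l)
        n_i = 0
        if fi > 0:
            r_i = r * math.sqrt(fl + fi)
            n_i = _paint_annulus(intima_mask, cx, cy, r_i, r_l)
        records.append(
            ShapeRecord(
                kind=kind,
                center_px=(cx, cy),
                bounding_r_px=r,
                analytic_area_um2=area,
                raster_px=n,
                raster_centroid_px=cen,
                meta={
                    "intima_px": n_i,
                    "lumen_px": n_l,
                    "intima_fraction": fi,
                    "lumen_fraction": fl,
                },
            )
        )

    for _ in range(spec.n_arteries):
        add_artery("artery", cortex_bounds, vessels, intima, lumen,
                   spec.artery_area_mean_um2)
    for _ in range(spec.n_interlobar):
        if hm_px <= 2 * m:
            raise PackingError("interlobar arteries requested but no medulla")
        add_artery("interlobar", medulla_bounds, interlobar, intima_med, lumen_med,
                   spec.artery_area_mean_um2 * 1.5)

    # --- glomeruli --------------------------------------------------------
    def add_glom(kind: str, mask: np.ndarray, mean: float, cv: float):
        area = _sample_area(rng, mean, cv)
        r = math.sqrt(area / math.pi) / mpp
        cx, cy = placer.place(r, cortex_bounds, what=kind)
        n, cen = _paint_disc(mask, cx, cy, r)
        _paint_disc(glom_filled, cx, cy, r)
        records.append(
            ShapeRecord(kind, (cx, cy), r, area, n, cen)
        )

    for _ in range(spec.n_nsg):
        add_glom("nsg", nsg_mask, spec.glom_area_mean_um2, spec.glom_area_cv)
    for _ in range(spec.n_gsg):
        add_glom("gsg", gsg_mask, spec.gsg_area_mean_um2, spec.gsg_area_cv)

    # edge-clipped NSG straddling a needle-cut (left/right) edge
    for _ in range(spec.n_edge_clipped_nsg):
        area = _sample_area(rng, spec.glom_area_mean_um2, spec.glom_area_cv)
        r = math.sqrt(area / math.pi) / mpp
        side = rng.integers(0, 2)
        h = rng.uniform(-0.4, 0.4) * r  # signed distance of center inside tissue
        placed_ok = False
        for _ in range(2000):
            cy = rng.uniform(top + m + r, top + hc_px - m - r)
            cx = left + h if side == 0 else right - 1 - h
            if placer.fits(cx, cy, r):
                placer.placed.append((cx, cy, r))
                placed_ok = True
                break
            h = rng.uniform(-0.4, 0.4) * r
        if not placed_ok:
            raise PackingError("could not place edge-clipped glomerulus")
        n, cen = _paint_disc(nsg_mask, cx, cy, r, clip=cortex)
        _paint_disc(glom_filled, cx, cy, r, clip=cortex)
        # distance from center to the cut line through the outermost pixel rim
        h_eff = (cx - (left - 0.5)) if side == 0 else ((right - 0.5) - cx)
        clipped_area = _clipped_disc_area(r, h_eff / 1.0) * um2
        records.append(
            ShapeRecord("nsg", (cx, cy), r, clipped_area, n, cen, clipped=True,
                        meta={"full_area_um2": area})
        )

    for _ in range(spec.n_empty_capsule):
        outer = _sample_area(rng, spec.empty_capsule_outer_area_um2, 0.2)
        r_out = math.sqrt(outer / math.pi) / mpp
        r_in = r_out * math.sqrt(1.0 - spec.empty_capsule_ring_fraction)
        cx, cy = placer.place(r_out, cortex_bounds, what="empty capsule")
        n = _paint_annulus(ec_mask, cx, cy, r_out, r_in)
        _paint_disc(glom_filled, cx, cy, r_out)
        ring_area = outer * spec.empty_capsule_ring_fraction
        records.append(
            ShapeRecord("empty_capsule", (cx, cy), r_out, ring_area, n,
                        meta={"outer_area_um2": outer})
        )

    # --- arterioles and AH lesions ---------------------------------------
    # retried as a block so AH pair distances stay outside the merge guard band
    for attempt in range(50):
        sub_placer = _Placer(rng)
        sub_placer.placed = list(placer.placed)
        trial_records: list[ShapeRecord] = []
        carriers = set(
            rng.choice(spec.n_arterioles, size=spec.n_ah_lesions, replace=False)
            if spec.n_arterioles
            else []
        )
        lesions: list[tuple[float, float, float, float]] = []  # cx, cy, r, area
        try:
            for i in range(spec.n_arterioles):
                a_area = _sample_area(
                    rng, spec.arteriole_area_mean_um2, spec.arteriole_area_cv,
                    hi=7000.0,
                )
                ar = math.sqrt(a_area / math.pi) / mpp
                cx, cy = sub_placer.place(ar, cortex_bounds, what="arteriole")
                rec = ShapeRecord("arteriole", (cx, cy), ar, a_area,
                                  meta={"has_ah": False})
                trial_records.append(rec)
                if i in carriers:
                    l_area = _sample_area(
                        rng, spec.ah_area_mean_um2, spec.ah_area_cv,
                        hi=0.8 * a_area,
                    )
                    lr = math.sqrt(l_area / math.pi) / mpp
                    max_off = max(ar - lr - 1.0, 0.0)
                    off = rng.uniform(0, max_off)
                    ang = rng.uniform(0, 2 * math.pi)
                    lx, ly = cx + off * math.cos(ang), cy + off * math.sin(ang)
                    rec.meta["has_ah"] = True
                    lesions.append((lx, ly, lr, l_area))
        except PackingError:
            if attempt == 49:
                raise
            continue
        # guard band around the 500 um merge threshold
        ok = True
        for i in range(len(lesions)):
            for j in range(i + 1, len(lesions)):
                d_um = (
                    math.hypot(lesions[i][0] - lesions[j][0],
                               lesions[i][1] - lesions[j][1])
                    - lesions[i][2] - lesions[j][2]
                ) * mpp
                if 470.0 < d_um < 530.0:
                    ok = False
        if ok:
            break
    else:  # pragma: no cover
        raise PackingError("could not place arterioles with admissible AH spacing")
    placer.placed = sub_placer.placed
    ah_records: list[ShapeRecord] = []
    for rec in trial_records:
        cx, cy = rec.center_px
        n, cen = _paint_disc(vessels, cx, cy, rec.bounding_r_px)
        rec.raster_px, rec.raster_centroid_px = n, cen
        records.append(rec)
    for lx, ly, lr, l_area in lesions:
        n, cen = _paint_disc(ah_mask, lx, ly, lr)
        ah_rec = ShapeRecord("ah", (lx, ly), lr, l_area, n, cen)
        records.append(ah_rec)
        ah_records.append(ah_rec)

    # --- tubular atrophy foci --------------------------------------------
    for _ in range(spec.n_ta_foci):
        area = _sample_area(rng, spec.ta_area_mean_um2, spec.ta_area_cv)
        bx, by, r0, r_bound = _blob_polygon(rng, area / um2)
        cx, cy = placer.place(r_bound, cortex_bounds, what="TA focus")
        n = _paint_polygon(ta_mask, bx + cx, by + cy)
        poly_area = _shoelace(bx, by) * um2  # analytic area of the drawn polygon
        records.append(ShapeRecord("ta", (cx, cy), r_bound, poly_area, n))

    # --- compartment layers ----------------------------------------------
    ti = cortex & ~glom_filled & ~vessels
    cortex_excl = cortex & ~vessels & ~ta_mask

    # --- tubules: grid packing inside the tubulointerstitium --------------
    prox_mask = np.zeros(shape, dtype=bool)
    dist_mask = np.zeros(shape, dtype=bool)
    n_tub = 0
    if spec.tubule_limit is None or spec.tubule_limit > 0:
        allowed = ti & ~ndimage.binary_dilation(ta_mask, iterations=3)
        allowed &= ndimage.binary_erosion(tissue, iterations=_EDGE_MARGIN)
        # distance to the nearest non-allowed pixel, at allowed pixels
        dt = ndimage.distance_transform_edt(allowed)
        # rows alternate proximal/distal; area clip at 1.25x the class mean
        # bounds the radius so grid spacing guarantees non-touching circles
        r_cap = 1.25
        rmax_p = math.sqrt(r_cap * spec.prox_tubule_area_mean_um2 / math.pi) / mpp
        rmax_d = math.sqrt(r_cap * spec.dist_tubule_area_mean_um2 / math.pi) / mpp
        limit = spec.tubule_limit if spec.tubule_limit is not None else np.inf
        yc = top + m + rmax_p
        row_i = 0
        while yc < top + hc_px - m and n_tub < limit:
            proximal = row_i % 2 == 0
            rmax_row = rmax_p if proximal else rmax_d
            pitch = 2.0 * rmax_row + 3.0
            mean = (
                spec.prox_tubule_area_mean_um2
                if proximal
                else spec.dist_tubule_area_mean_um2
            )
            xstart = left + m + rng.uniform(0.0, pitch)
            for xc in np.arange(xstart, right - m, pitch):
                if n_tub >= limit:
                    break
                area = _sample_area(
                    rng, mean, spec.tubule_area_cv,
                    lo=mean / r_cap, hi=mean * r_cap,
                )
                r = math.sqrt(area / math.pi) / mpp
                iy, ix = int(round(yc)), int(round(xc))
                if not (0 <= iy < shape[0] and 0 <= ix < shape[1]):
                    continue
                if dt[iy, ix] < r + 1.5:
                    continue
                target = prox_mask if proximal else dist_mask
                n, cen = _paint_disc(target, xc, yc, r)
                records.append(
                    ShapeRecord("tubule_prox" if proximal else "tubule_dist",
                                (xc, yc), r, area, n, cen)
                )
                n_tub += 1
            yc += rmax_row + (rmax_d if proximal else rmax_p) + 3.0
            row_i += 1

    tubules = prox_mask | dist_mask

    masks = {
        tx.TISSUE: tissue,
        tx.CORTEX: cortex,
        tx.MEDULLA: medulla,
        tx.TA_CLUSTER: ta_mask,
        tx.CORTEX_EXCL: cortex_excl,
        tx.TUBULOINTERSTITIUM: ti,
        tx.TUBULES: tubules,
        tx.PROXIMAL_TUBULE: prox_mask,
        tx.DISTAL_TUBULE: dist_mask,
        tx.GLOMERULAR_AREA: glom_filled,
        tx.GSG: gsg_mask,
        tx.EMPTY_CAPSULE: ec_mask,
        tx.NSG: nsg_mask,
        tx.ARTERIES: vessels,
        tx.AH: ah_mask,
        tx.INTIMA: intima,
        tx.ARTERIAL_LUMEN: lumen,
        tx.INTERLOBAR: interlobar,
        tx.INTIMA_MED: intima_med,
        tx.ARTERY_LUMEN_MED: lumen_med,
    }
    from .taxonomy import default_taxonomy

    section = LabeledSection(
        taxonomy=default_taxonomy(),
        calibration=Calibration(mpp, spec.section_thickness_um),
        masks=masks,
        capsule=capsule,
        kind=spec.kind,
    )
    truth = _ground_truth(
        spec, records, ah_records, cortex_area_um2, medulla_area_um2, um2
    )
    return section, truth


def _ground_truth(
    spec: SceneSpec,
    records: list[ShapeRecord],
    ah_records: list[ShapeRecord],
    cortex_area_um2: float,
    medulla_area_um2: float,
    um2: float,
) -> GroundTruth:
    by_kind: dict[str, list[ShapeRecord]] = {}
    for r in records:
        by_kind.setdefault(r.kind, []).append(r)

    res = MorphometryResult()
    res.cortex_area_mm2 = cortex_area_um2 / 1e6
    res.medulla_area_mm2 = medulla_area_um2 / 1e6
    nsg = by_kind.get("nsg", [])
    gsg = by_kind.get("gsg", [])
    res.nsg_count = len(nsg)
    res.gsg_count = len(gsg)
    res.empty_capsule_count = len(by_kind.get("empty_capsule", []))
    res.ta_foci_count = len(by_kind.get("ta", []))

    interior_nsg = [r.analytic_area_um2 for r in nsg if not r.clipped]
    if interior_nsg:
        res.glomerular_volume_mm3 = glomerular_volume_mm3(float(np.mean(interior_nsg)))
        res.extras["mean_nsg_profile_area_um2"] = float(np.mean(interior_nsg))
    else:
        res.missing["glomerular_volume_mm3"] = "no non-sclerosed glomerular profiles"
    glom_count = res.nsg_count + res.gsg_count
    if glom_count == 0:
        res.missing["pct_gsg"] = "no glomerular profiles"
        res.missing["cortex_per_glomerulus_mm3"] = "no glomerular profiles"
    else:
        res.pct_gsg = 100.0 * res.gsg_count / glom_count
        if res.glomerular_volume_mm3 is not None:
            res.cortex_per_glomerulus_mm3 = cortex_per_glomerulus_mm3(
                res.cortex_area_mm2, glom_count, res.glomerular_volume_mm3,
                spec.section_thickness_um,
            )
        else:
            res.missing["cortex_per_glomerulus_mm3"] = "glomerular volume unavailable"

    for kind, attr in (
        ("tubule_prox", "mean_proximal_tubular_area_um2"),
        ("tubule_dist", "mean_distal_tubular_area_um2"),
    ):
        recs = by_kind.get(kind, [])
        if recs:
            setattr(res, attr, float(np.mean([r.analytic_area_um2 for r in recs])))
        else:
            res.missing[attr] = "no tubular profiles"

    tubule_area = sum(
        r.analytic_area_um2
        for r in by_kind.get("tubule_prox", []) + by_kind.get("tubule_dist", [])
    )
    ta_area = sum(r.analytic_area_um2 for r in by_kind.get("ta", []))
    tubular_denom = tubule_area + ta_area
    if tubular_denom > 0:
        res.pct_ta = 100.0 * ta_area / tubular_denom
        res.ta_foci_density_per_mm2 = res.ta_foci_count / (tubular_denom / 1e6)
    else:
        res.missing["pct_ta"] = "no tubular area"
        res.missing["ta_foci_density_per_mm2"] = "no tubular area"

    glom_filled_area = (
        sum(r.analytic_area_um2 for r in nsg + gsg)
        + sum(r.meta["outer_area_um2"] for r in by_kind.get("empty_capsule", []))
    )
    vessel_area = sum(
        r.analytic_area_um2
        for r in by_kind.get("artery", []) + by_kind.get("arteriole", [])
    )
    ti_area = cortex_area_um2 - glom_filled_area - vessel_area
    if ti_area > 0:
        res.pct_ita = 100.0 * (ti_area - tubule_area) / ti_area
    else:
        res.missing["pct_ita"] = "no tubulointerstitium"

    # AH merge on analytic circle distances (transitive closure)
    n_ah = len(ah_records)
    parent = list(range(n_ah))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    mpp = spec.microns_per_pixel
    for i in range(n_ah):
        for j in range(i + 1, n_ah):
            a, b = ah_records[i], ah_records[j]
            d_um = (
                math.hypot(a.center_px[0] - b.center_px[0],
                           a.center_px[1] - b.center_px[1])
                - a.bounding_r_px - b.bounding_r_px
            ) * mpp
            if d_um < 500.0:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n_ah):
        clusters.setdefault(find(i), []).append(i)
    reps: list[ShapeRecord] = []
    for members in clusters.values():
        rep = max(
            (ah_records[i] for i in members),
            key=lambda r: (
                r.raster_px,
                tuple(-c * mpp for c in r.raster_centroid_px),
            ),
        )
        reps.append(rep)
    res.ah_lesion_count = len(reps)
    res.ah_density_per_mm2 = res.ah_lesion_count / res.cortex_area_mm2
    if reps:
        # small-lesion areas are defined on the label raster itself
        res.mean_ah_area_um2 = float(np.mean([r.raster_px for r in reps])) * um2
    else:
        res.missing["mean_ah_area_um2"] = "no AH lesions"
    arterioles = by_kind.get("arteriole", [])
    if arterioles:
        res.pct_arterioles_with_ah = (
            100.0 * sum(1 for r in arterioles if r.meta["has_ah"]) / len(arterioles)
        )
    else:
        res.missing["pct_arterioles_with_ah"] = "no arterioles"

    stenoses = []
    for r in by_kind.get("artery", []) + by_kind.get("interlobar", []):
        if r.analytic_area_um2 > 7850.0:
            i_px, l_px = r.meta["intima_px"], r.meta["lumen_px"]
            stenoses.append(100.0 * i_px / (i_px + l_px) if i_px else 0.0)
    if stenoses:
        res.pct_luminal_stenosis = float(np.mean(stenoses))
    else:
        res.missing["pct_luminal_stenosis"] = "no artery with profile area > 7850 um^2"

    return GroundTruth(
        measures=res,
        structures=records,
        ah_merged_clusters=[sorted(v) for v in clusters.values()],
        spec=spec,
    )


# ---------------------------------------------------------------------------
# presets

def donor_like_spec(seed: int = 0, **overrides) -> SceneSpec:
    """A scaled-down needle core with donor-cohort-like composition."""
    return replace(SceneSpec(seed=seed), **overrides)


def tumor_like_spec(seed: int = 0, **overrides) -> SceneSpec:
    """A scaled-down wedge with tumor-cohort-like composition.

    Higher glomerulosclerosis and atrophy burden, larger tubules, more and
    larger AH lesions, more stenosed arteries than the donor preset.
    """
    base = SceneSpec(
        kind="wedge",
        seed=seed,
        cortex_area_mm2=4.0,
        medulla_area_mm2=1.2,
        wedge_aspect=2.0,
        n_nsg=9,
        n_edge_clipped_nsg=1,
        n_gsg=2,
        n_empty_capsule=2,
        n_ta_foci=6,
        n_arteries=3,
        n_arterioles=10,
        n_ah_lesions=2,
        n_interlobar=1,
        glom_area_mean_um2=15600.0,
        prox_tubule_area_mean_um2=4205.0,
        dist_tubule_area_mean_um2=2598.0,
        ta_area_mean_um2=9000.0,
        artery_intima_fraction_mean=0.12,  # stenosis around 28%
        p_artery_no_intima=0.1,
        ah_area_mean_um2=405.0,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# annotator perturbation

@dataclass(frozen=True)
class PerturbationSpec:
    """Degradation simulating a second annotator.

    ``dilate_px``/``erode_px`` grow or shrink class regions (within the
    tissue silhouette); ``flip_rate`` relabels whole connected components
    from ``flip_from`` to ``flip_to``.  Zero magnitudes reproduce the
    section exactly.
    """

    dilate_px: int = 0
    erode_px: int = 0
    classes: tuple[str, ...] | None = None  # None = all non-compartment layers
    flip_rate: float = 0.0
    flip_from: str | None = None
    flip_to: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilate_px < 0 or self.erode_px < 0:
            raise ValueError("perturbation magnitudes must be >= 0")
        if not 0.0 <= self.flip_rate <= 1.0:
            raise ValueError("flip_rate must be in [0, 1]")


_COMPARTMENTS = (tx.TISSUE, tx.CORTEX, tx.MEDULLA)


def perturb_annotation(
    section: LabeledSection, pert: PerturbationSpec
) -> LabeledSection:
    """A degraded copy of a section under a seeded perturbation."""
    rng = np.random.default_rng(pert.seed)
    tissue = section.mask(tx.TISSUE)
    masks = {name: m.copy() for name, m in section.masks.items()}
    targets = (
        pert.classes
        if pert.classes is not None
        else tuple(n for n in masks if n not in _COMPARTMENTS)
    )
    for name in targets:
        m = masks.get(name)
        if m is None or not m.any():
            continue
        if pert.dilate_px:
            m = ndimage.binary_dilation(m, iterations=pert.dilate_px) & tissue
        if pert.erode_px:
            m = ndimage.binary_erosion(m, iterations=pert.erode_px)
        masks[name] = m
    if pert.flip_rate > 0 and pert.flip_from and pert.flip_to:
        src = masks.get(pert.flip_from)
        if src is not None and src.any():
            dst = masks.get(
                pert.flip_to, np.zeros(section.shape, dtype=bool)
            ).copy()
            labels, n = ndimage.label(
                src, structure=ndimage.generate_binary_structure(2, 2)
            )
            src = src.copy()
            for i in range(1, n + 1):
                if rng.uniform() < pert.flip_rate:
                    comp = labels == i
                    src &= ~comp
                    dst |= comp
            masks[pert.flip_from] = src
            masks[pert.flip_to] = dst
    return LabeledSection(
        taxonomy=section.taxonomy,
        calibration=section.calibration,
        masks=masks,
        capsule=None if section.capsule is None else section.capsule.copy(),
        kind=section.kind,
    )
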