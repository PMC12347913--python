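"""Nephron-size and nephrosclerosis morphometry from a labeled section.

Given a calibrated multiclass segmentation of a kidney section, this
module computes the per-section battery of structural counts/areas and
the derived measures used to quantify chronic kidney damage:

Nephron size
    * glomerular volume (Weibel–Gomez stereology on mean non-sclerosed
      glomerular profile area),
    * cortex volume per glomerulus (inverse volumetric glomerular
      density, via the areal→volumetric density conversion
      ``N_V = N_A / (D + T)`` with sphere-equivalent diameter ``D`` and
      section thickness ``T``),
    * mean proximal and distal tubular profile areas.

Nephrosclerosis
    * %GSG — globally sclerosed fraction of glomeruli,
    * %TA per tubular area and %ITA per tubulointerstitial area,
    * TA foci density per tubular area,
    * arteriolar hyalinosis (AH) lesion density, % arterioles with AH and
      mean AH lesion area, after merging lesions closer than 500 um
      (about two adjacent glomerular profile widths — such lesions are
      likely sections of one lesion),
    * % luminal stenosis from intimal thickening, averaged over arteries
      with profile area > 7850 um^2; an artery with no detected intima is
      not thickened and contributes 0%.

Structures bisected by the needle/block cut edge are excluded from mean
profile areas and from the glomerular-volume estimate (their profiles
underestimate the structure) but are kept in counts and densities.
Missing denominators set per-measure missing flags, never silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from . import taxonomy as tx
from .section import (
    LabeledSection,
    StructureComponent,
    cut_edge_distance_px,
    extract_components,
    flag_edge_bisected,
)

__all__ = [
    "MorphometryConfig",
    "MorphometryResult",
    "glomerular_volume_mm3",
    "cortex_per_glomerulus_mm3",
    "pct_gsg",
    "merge_ah_lesions",
    "quantify",
]


@dataclass(frozen=True)
class MorphometryConfig:
    """Every decision knob of the measure battery, with defaults.

    ``weibel_gomez_beta``/``weibel_gomez_d`` are the shape and
    size-distribution coefficients of the Weibel–Gomez glomerular volume
    model (1.38 for a sphere, 1.01 for a narrow size distribution).
    ``artery_min_area_um2`` splits the arteries-and-arterioles class:
    profiles strictly above the gate are arteries (enter the stenosis
    average), the rest are arterioles (enter the AH measures).
    """

    connectivity: int = 8
    edge_epsilon_px: float = 1.0
    exclude_edge_bisected_from_means: bool = True
    include_empty_capsules_in_glomeruli: bool = False
    exclude_tubules_in_ta: bool = True
    weibel_gomez_beta: float = 1.38
    weibel_gomez_d: float = 1.01
    ah_merge_distance_um: float = 500.0
    artery_min_area_um2: float = 7850.0
    stenosis_pool_compartments: bool = True


_MEASURE_FIELDS = (
    "cortex_area_mm2",
    "medulla_area_mm2",
    "nsg_count",
    "gsg_count",
    "empty_capsule_count",
    "ta_foci_count",
    "ah_lesion_count",
    "glomerular_volume_mm3",
    "cortex_per_glomerulus_mm3",
    "mean_proximal_tubular_area_um2",
    "mean_distal_tubular_area_um2",
    "pct_gsg",
    "pct_ta",
    "pct_ita",
    "ta_foci_density_per_mm2",
    "ah_density_per_mm2",
    "pct_arterioles_with_ah",
    "mean_ah_area_um2",
    "pct_luminal_stenosis",
)


@dataclass
class MorphometryResult:
    """Per-section record of structural counts/areas and derived measures.

    A measure whose denominator class is absent is ``None`` and the reason
    is recorded in ``missing`` under the measure name.
    """

    cortex_area_mm2: float = 0.0
    medulla_area_mm2: float = 0.0
    nsg_count: int = 0
    gsg_count: int = 0
    empty_capsule_count: int = 0
    ta_foci_count: int = 0
    ah_lesion_count: int = 0
    glomerular_volume_mm3: float | None = None
    cortex_per_glomerulus_mm3: float | None = None
    mean_proximal_tubular_area_um2: float | None = None
    mean_distal_tubular_area_um2: float | None = None
    pct_gsg: float | None = None
    pct_ta: float | None = None
    pct_ita: float | None = None
    ta_foci_density_per_mm2: float | None = None
    ah_density_per_mm2: float | None = None
    pct_arterioles_with_ah: float | None = None
    mean_ah_area_um2: float | None = None
    pct_luminal_stenosis: float | None = None
    missing: dict[str, str] = field(default_factory=dict)
    extras: dict[str, float] = field(default_factory=dict)

    @staticmethod
    def measure_names() -> tuple[str, ...]:
        return _MEASURE_FIELDS

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in _MEASURE_FIELDS}

    def __post_init__(self) -> None:
        for name in _MEASURE_FIELDS:
            v = getattr(self, name)
            if v is None:
                continue
            if name.startswith("pct_") and not (-1e-9 <= v <= 100 + 1e-9):
                raise ValueError(f"{name}={v} outside [0, 100]")
            if name.endswith("_count") and (v < 0 or v != int(v)):
                raise ValueError(f"{name}={v} is not a non-negative integer")


# ---------------------------------------------------------------------------
# elementary measures

def glomerular_volume_mm3(
    mean_profile_area_um2: float, beta: float = 1.38, d: float = 1.01
) -> float:
    """Weibel–Gomez glomerular volume: ``V = (beta/d) * A^(3/2)``.

    ``A`` is the mean non-sclerosed glomerular profile area in um^2; the
    result is in mm^3.
    """
    if not mean_profile_area_um2 > 0:
        raise ValueError("mean profile area must be > 0")
    v_um3 = (beta / d) * mean_profile_area_um2**1.5
    return v_um3 / 1e9


def cortex_per_glomerulus_mm3(
    cortex_area_mm2: float,
    glomerular_profile_count: int,
    glomerular_volume_mm3: float,
    section_thickness_um: float = 2.5,
) -> float:
    """Cortical volume supplying one glomerulus (mm^3).

    Areal profile density ``N_A = count / cortex_area`` is converted to
    volumetric density with the sphere-equivalent diameter:
    ``N_V = N_A / (D + T)`` where ``D = (6 V / pi)^(1/3)`` and ``T`` is
    the section thickness; the result is ``1 / N_V``.
    """
    if glomerular_profile_count <= 0:
        raise ValueError("glomerular profile count must be > 0")
    if not cortex_area_mm2 > 0:
        raise ValueError("cortex area must be > 0")
    n_a = glomerular_profile_count / cortex_area_mm2  # per mm^2
    d_mm = (6.0 * glomerular_volume_mm3 / math.pi) ** (1.0 / 3.0)
    n_v = n_a / (d_mm + section_thickness_um / 1000.0)  # per mm^3
    return 1.0 / n_v


def pct_gsg(nsg_count: int, gsg_count: int) -> float:
    """Percent globally sclerosed glomeruli, 100*GSG/(NSG+GSG)."""
    total = nsg_count + gsg_count
    if total <= 0:
        raise ValueError("no glomeruli")
    return 100.0 * gsg_count / total


def merge_ah_lesions(
    lesions: list[StructureComponent], merge_distance_um: float = 500.0
) -> list[StructureComponent]:
    """Merge AH lesions whose boundaries lie strictly closer than 500 um.

    Lesions closer than about two adjacent glomerular-profile widths are
    plausibly cuts through one lesion, so each connected cluster (under
    the transitive closure of the pairwise rule) counts once.  The
    retained representative of a cluster is its largest-area lesion, and
    the reported area is the representative's own area, not a sum.
    """
    n = len(lesions)
    if n <= 1:
        return list(lesions)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    polys = [c.boundary for c in lesions]
    for i in range(n):
        for j in range(i + 1, n):
            if polys[i].distance(polys[j]) < merge_distance_um:
                parent[find(i)] = find(j)
    clusters: dict[int, list[StructureComponent]] = {}
    for i, comp in enumerate(lesions):
        clusters.setdefault(find(i), []).append(comp)
    reps = [
        max(members, key=lambda c: (c.area_um2, tuple(-x for x in c.centroid_um)))
        for members in clusters.values()
    ]
    reps.sort(key=lambda c: (-c.area_um2, c.centroid_um))
    return reps


# ---------------------------------------------------------------------------
# full battery

def _mean_area(
    comps: list[StructureComponent], exclude_edge: bool
) -> tuple[float | None, int]:
    kept = [c for c in comps if not (exclude_edge and c.edge_bisected)]
    if not kept:
        return None, 0
    return float(np.mean([c.area_um2 for c in kept])), len(kept)


def _overlap_fraction(comp: StructureComponent, mask: np.ndarray) -> float:
    rows, cols = comp.pixels
    return float(mask[rows, cols].mean())


def quantify(
    section: LabeledSection, config: MorphometryConfig = MorphometryConfig()
) -> MorphometryResult:
    """Compute the full measure battery for one section.

    Deterministic given the section and config; never raises on absent
    classes — measures whose inputs are absent come back as ``None`` with
    a reason in ``result.missing``.
    """
    cal = section.calibration
    res = MorphometryResult()
    res.cortex_area_mm2 = section.area_um2(tx.CORTEX) / 1e6
    res.medulla_area_mm2 = section.area_um2(tx.MEDULLA) / 1e6

    dist = cut_edge_distance_px(section) if section.mask(tx.TISSUE).any() else None

    def comps(name: str) -> list[StructureComponent]:
        cs = extract_components(section, name, connectivity=config.connectivity)
        if cs and dist is not None:
            flag_edge_bisected(section, cs, config.edge_epsilon_px, _distance=dist)
        return cs

    nsg = comps(tx.NSG)
    gsg = comps(tx.GSG)
    empty = comps(tx.EMPTY_CAPSULE)
    ta = comps(tx.TA_CLUSTER)
    res.nsg_count = len(nsg)
    res.gsg_count = len(gsg)
    res.empty_capsule_count = len(empty)
    res.ta_foci_count = len(ta)

    # glomerular volume from mean NSG profile area
    mean_nsg, n_used = _mean_area(nsg, config.exclude_edge_bisected_from_means)
    if mean_nsg is None:
        res.missing["glomerular_volume_mm3"] = "no non-sclerosed glomerular profiles"
    else:
        res.glomerular_volume_mm3 = glomerular_volume_mm3(
            mean_nsg, config.weibel_gomez_beta, config.weibel_gomez_d
        )
        res.extras["mean_nsg_profile_area_um2"] = mean_nsg

    # cortex per glomerulus
    glom_count = res.nsg_count + res.gsg_count
    if config.include_empty_capsules_in_glomeruli:
        glom_count += res.empty_capsule_count
    if glom_count == 0:
        res.missing["cortex_per_glomerulus_mm3"] = "no glomerular profiles"
        res.missing["pct_gsg"] = "no glomerular profiles"
    else:
        res.pct_gsg = pct_gsg(res.nsg_count, res.gsg_count)
        if res.glomerular_volume_mm3 is None:
            res.missing["cortex_per_glomerulus_mm3"] = "glomerular volume unavailable"
        elif res.cortex_area_mm2 <= 0:
            res.missing["cortex_per_glomerulus_mm3"] = "no cortex"
        else:
            res.cortex_per_glomerulus_mm3 = cortex_per_glomerulus_mm3(
                res.cortex_area_mm2,
                glom_count,
                res.glomerular_volume_mm3,
                cal.section_thickness_um,
            )

    # mean tubular profile areas
    ta_mask = section.mask(tx.TA_CLUSTER)
    for name, attr in (
        (tx.PROXIMAL_TUBULE, "mean_proximal_tubular_area_um2"),
        (tx.DISTAL_TUBULE, "mean_distal_tubular_area_um2"),
    ):
        tub = comps(name)
        if config.exclude_tubules_in_ta and ta_mask.any():
            tub = [c for c in tub if _overlap_fraction(c, ta_mask) <= 0.5]
        mean, _ = _mean_area(tub, config.exclude_edge_bisected_from_means)
        if mean is None:
            res.missing[attr] = "no tubular profiles"
        else:
            setattr(res, attr, mean)

    # tubular atrophy measures
    ta_area = section.area_um2(tx.TA_CLUSTER)
    tubule_area = section.area_um2(tx.TUBULES)
    ti_area = section.area_um2(tx.TUBULOINTERSTITIUM)
    tubular_denominator = tubule_area + ta_area
    if tubular_denominator > 0:
        res.pct_ta = 100.0 * ta_area / tubular_denominator
        res.ta_foci_density_per_mm2 = res.ta_foci_count / (tubular_denominator / 1e6)
    else:
        res.missing["pct_ta"] = "no tubular area"
        res.missing["ta_foci_density_per_mm2"] = "no tubular area"
    if ti_area > 0:
        res.pct_ita = 100.0 * (ti_area - tubule_area) / ti_area
    else:
        res.missing["pct_ita"] = "no tubulointerstitium"

    # vessels: split arteries vs arterioles at the profile-area gate
    vessels = comps(tx.ARTERIES)
    arteries = [c for c in vessels if c.area_um2 > config.artery_min_area_um2]
    arterioles = [c for c in vessels if c.area_um2 <= config.artery_min_area_um2]

    # arteriolar hyalinosis
    ah_raw = comps(tx.AH)
    merged = merge_ah_lesions(ah_raw, config.ah_merge_distance_um)
    res.ah_lesion_count = len(merged)
    if res.cortex_area_mm2 > 0:
        res.ah_density_per_mm2 = res.ah_lesion_count / res.cortex_area_mm2
    else:
        res.missing["ah_density_per_mm2"] = "no cortex"
    if merged:
        res.mean_ah_area_um2 = float(np.mean([c.area_um2 for c in merged]))
    else:
        res.missing["mean_ah_area_um2"] = "no AH lesions"
    if arterioles:
        ah_mask = section.mask(tx.AH)
        with_ah = sum(1 for c in arterioles if ah_mask[c.pixels].any())
        res.pct_arterioles_with_ah = 100.0 * with_ah / len(arterioles)
    else:
        res.missing["pct_arterioles_with_ah"] = "no arterioles"

    # luminal stenosis, cortical and medullary arteries under the same rule
    groups = {
        "cortical": (arteries, tx.INTIMA, tx.ARTERIAL_LUMEN),
        "medullary": (
            [
                c
                for c in comps(tx.INTERLOBAR)
                if c.area_um2 > config.artery_min_area_um2
            ],
            tx.INTIMA_MED,
            tx.ARTERY_LUMEN_MED,
        ),
    }
    all_stenoses: list[float] = []
    for label, (arts, intima_name, lumen_name) in groups.items():
        if not arts:
            continue
        intima_mask = section.mask(intima_name)
        lumen_mask = section.mask(lumen_name)
        vals = []
        for art in arts:
            rows, cols = art.pixels
            i_px = int(intima_mask[rows, cols].sum())
            l_px = int(lumen_mask[rows, cols].sum())
            # intima is detected only when thickened: none detected => 0%
            vals.append(100.0 * i_px / (i_px + l_px) if i_px else 0.0)
        res.extras[f"pct_luminal_stenosis_{label}"] = float(np.mean(vals))
        all_stenoses.extend(vals)
    if all_stenoses:
        if config.stenosis_pool_compartments:
            res.pct_luminal_stenosis = float(np.mean(all_stenoses))
        else:
            res.pct_luminal_stenosis = res.extras.get(
                "pct_luminal_stenosis_cortical",
                res.extras.get("pct_luminal_stenosis_medullary"),
            )
    else:
        res.missing["pct_luminal_stenosis"] = (
            f"no artery with profile area > {config.artery_min_area_um2} um^2"
        )
    return res
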