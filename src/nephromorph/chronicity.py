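"""Ordinal chronicity scores and the reference-limit report.

Four morphometric measures are banded 0–3 and summed into 0–12 composite
scores used for CKD prognosis:

* **Nephrosclerosis chronicity score** = %GSG band + %ITA band +
  TA-foci-density band + mean-AH-area band.
* **Nephron hypertrophy and nephrosclerosis chronicity score** — the
  same, with the %ITA band replaced by the cortex-per-glomerulus band.

Band cut points follow the published conventions: %GSG and %ITA use the
commonly used thresholds (< 10%, 10%–25%, 26%–50%, > 50%), read as
half-open bands [0,10), [10,26), [26,50], (50,∞) for continuous values;
TA foci density (≤5, 6–10, 11–20, >20 per mm²), mean AH area (≤500,
501–750, 751–1000, >1000 µm²) and cortex per glomerulus (≤0.075,
0.076–0.125, 0.126–0.175, >0.175 mm³) use upper-inclusive bands.

A missing component measure propagates by default (the total is missing,
with a reason) rather than being imputed as zero: absent denominators on
real sections are informative, not benign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .morphometry import MorphometryResult

__all__ = [
    "BandSpec",
    "ChronicityScore",
    "band_score",
    "nephrosclerosis_score",
    "hypertrophy_score",
    "score",
    "reference_report",
    "DEFAULT_BANDS",
]


@dataclass(frozen=True)
class BandSpec:
    """Three ascending cut points mapping a measure onto scores 0–3.

    ``boundary="left_closed"``: bands [0,c1), [c1,c2), [c2,c3], (c3,∞) —
    the convention for the percent measures, where the printed thresholds
    are "< c1" for 0 and "> c3" for 3 with the top of band 2 inclusive.
    ``boundary="right_closed"``: bands [0,c1], (c1,c2], (c2,c3], (c3,∞) —
    the convention for measures printed as "≤ c1" for 0.
    """

    measure: str
    cuts: tuple[float, float, float]
    boundary: str = "right_closed"

    def __post_init__(self) -> None:
        c1, c2, c3 = self.cuts
        if not (c1 < c2 < c3):
            raise ValueError(f"cut points must be strictly ascending, got {self.cuts}")
        if self.boundary not in ("left_closed", "right_closed"):
            raise ValueError(f"unknown boundary rule {self.boundary!r}")


DEFAULT_BANDS: dict[str, BandSpec] = {
    "pct_gsg": BandSpec("pct_gsg", (10.0, 26.0, 50.0), "left_closed"),
    "pct_ita": BandSpec("pct_ita", (10.0, 26.0, 50.0), "left_closed"),
    "ta_foci_density_per_mm2": BandSpec(
        "ta_foci_density_per_mm2", (5.0, 10.0, 20.0), "right_closed"
    ),
    "mean_ah_area_um2": BandSpec(
        "mean_ah_area_um2", (500.0, 750.0, 1000.0), "right_closed"
    ),
    "cortex_per_glomerulus_mm3": BandSpec(
        "cortex_per_glomerulus_mm3", (0.075, 0.125, 0.175), "right_closed"
    ),
}


def band_score(value: float | None, spec: BandSpec) -> int | None:
    """Map a measure value onto its 0–3 band; None propagates."""
    if value is None:
        return None
    c1, c2, c3 = spec.cuts
    if spec.boundary == "left_closed":
        if value < c1:
            return 0
        if value < c2:
            return 1
        if value <= c3:
            return 2
        return 3
    if value <= c1:
        return 0
    if value <= c2:
        return 1
    if value <= c3:
        return 2
    return 3


@dataclass
class ChronicityScore:
    """Component bands (0–3 each) and the two 0–12 composite totals."""

    gsg_score: int | None = None
    ita_score: int | None = None
    ta_density_score: int | None = None
    ah_area_score: int | None = None
    cortex_per_glom_score: int | None = None
    nephrosclerosis_total: int | None = None
    hypertrophy_total: int | None = None
    missing_policy: str = "propagate"
    missing: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "gsg_score", "ita_score", "ta_density_score", "ah_area_score",
                "cortex_per_glom_score", "nephrosclerosis_total",
                "hypertrophy_total",
            )
        }


_COMPONENTS = {
    "gsg_score": "pct_gsg",
    "ita_score": "pct_ita",
    "ta_density_score": "ta_foci_density_per_mm2",
    "ah_area_score": "mean_ah_area_um2",
    "cortex_per_glom_score": "cortex_per_glomerulus_mm3",
}


def score(
    result: MorphometryResult,
    bands: dict[str, BandSpec] = DEFAULT_BANDS,
    missing_policy: str = "propagate",
) -> ChronicityScore:
    """Band every component measure and form both composite totals.

    ``missing_policy="propagate"`` leaves a total undefined when any of
    its four components is missing; ``"treat-as-0"`` scores missing
    components as 0.
    """
    if missing_policy not in ("propagate", "treat-as-0"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    cs = ChronicityScore(missing_policy=missing_policy)
    for attr, measure in _COMPONENTS.items():
        value = getattr(result, measure)
        s = band_score(value, bands[measure])
        if s is None:
            cs.missing[attr] = result.missing.get(measure, f"{measure} missing")
            if missing_policy == "treat-as-0":
                s = 0
        setattr(cs, attr, s)

    def total(parts: tuple[str, ...], name: str) -> int | None:
        vals = [getattr(cs, p) for p in parts]
        if any(v is None for v in vals):
            cs.missing[name] = "; ".join(
                f"{p}: {cs.missing[p]}" for p in parts if getattr(cs, p) is None
            )
            return None
        return int(sum(vals))

    cs.nephrosclerosis_total = total(
        ("gsg_score", "ita_score", "ta_density_score", "ah_area_score"),
        "nephrosclerosis_total",
    )
    cs.hypertrophy_total = total(
        ("cortex_per_glom_score", "gsg_score", "ta_density_score", "ah_area_score"),
        "hypertrophy_total",
    )
    return cs


def nephrosclerosis_score(
    result: MorphometryResult,
    bands: dict[str, BandSpec] = DEFAULT_BANDS,
    missing_policy: str = "propagate",
) -> ChronicityScore:
    """%GSG + %ITA + TA-foci-density + AH-area bands, 0–12."""
    return score(result, bands, missing_policy)


def hypertrophy_score(
    result: MorphometryResult,
    bands: dict[str, BandSpec] = DEFAULT_BANDS,
    missing_policy: str = "propagate",
) -> ChronicityScore:
    """Cortex-per-glomerulus + %GSG + TA-foci-density + AH-area bands, 0–12."""
    return score(result, bands, missing_policy)


# ---------------------------------------------------------------------------
# reference-limit report

def reference_report(
    result: MorphometryResult,
    reference,  # pandas.DataFrame of reference-cohort measures
    percentile: float = 95.0,
    min_observations: int = 20,
) -> dict:
    """Patient-vs-reference report with upper reference limits.

    For every measure present in the reference table (one column per
    measure, one reference subject per row) the upper limit is the given
    percentile of the reference distribution (default 95th); the patient
    value is flagged when it exceeds the limit.  Measures absent from the
    reference, or missing on the patient, are reported with a note
    instead of a limit/flag.
    """
    report: dict = {"percentile": percentile, "measures": {}, "notes": {}}
    for name in MorphometryResult.measure_names():
        value = getattr(result, name)
        entry: dict = {"value": value}
        if name not in getattr(reference, "columns", []):
            report["notes"][name] = "measure absent from reference table"
            report["measures"][name] = entry
            continue
        col = np.asarray(reference[name].dropna(), dtype=float)
        if col.size < min_observations:
            report["notes"][name] = (
                f"only {col.size} reference observations (< {min_observations})"
            )
            report["measures"][name] = entry
            continue
        limit = float(np.percentile(col, percentile))
        entry["upper_reference_limit"] = limit
        if value is None:
            report["notes"][name] = result.missing.get(name, "patient value missing")
        else:
            entry["out_of_range"] = bool(value > limit)
        report["measures"][name] = entry
    return report


def render_report_text(report: dict) -> str:
    """Human-readable rendering of a reference report."""
    lines = [
        "Morphometry report "
        f"(upper reference limit = {report['percentile']:g}th percentile)",
        "-" * 72,
    ]
    for name, entry in report["measures"].items():
        value = entry.get("value")
        limit = entry.get("upper_reference_limit")
        flag = " *HIGH*" if entry.get("out_of_range") else ""
        vtxt = "missing" if value is None else f"{value:.4g}"
        ltxt = "-" if limit is None else f"{limit:.4g}"
        note = report["notes"].get(name, "")
        lines.append(f"{name:36s} {vtxt:>12s}  (limit {ltxt}){flag}"
                     + (f"  [{note}]" if note else ""))
    return "\n".join(lines)


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=1)
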