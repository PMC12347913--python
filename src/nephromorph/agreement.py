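"""Pixel-level agreement between two segmentations of the same section.

Per class, the test and reference masks are intersected inside an
evaluation region (by default the union of both tissue silhouettes) and
summarized as false-positive and false-negative percentages of the
evaluation region, precision, sensitivity, and F1 — the standard
validation battery for comparing a model's detections against human
annotations, or annotator pairs against each other.

Panel aggregation supports the two comparisons reported in such
validations: model vs a panel of annotators (mean over pairwise rows with
each annotator as reference) and within-panel variability (mean over all
*ordered* annotator pairs, so the precision/sensitivity swap symmetry is
explicit).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .section import LabeledSection
from .taxonomy import TISSUE

__all__ = ["AgreementStats", "pairwise_agreement", "panel_agreement"]


@dataclass
class AgreementStats:
    """Agreement metrics for one class, all in percent."""

    class_name: str
    fp_pct: float | None
    fn_pct: float | None
    precision: float | None
    sensitivity: float | None
    f1: float | None
    eval_area_um2: float
    defined: bool = True

    def to_dict(self) -> dict:
        return {
            "class_name": self.class_name,
            "fp_pct": self.fp_pct,
            "fn_pct": self.fn_pct,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f1": self.f1,
            "eval_area_um2": self.eval_area_um2,
        }


def _evaluation_mask(
    test: LabeledSection,
    reference: LabeledSection,
    class_name: str,
    region: str,
) -> np.ndarray:
    if region == "tissue":
        return test.mask(TISSUE) | reference.mask(TISSUE)
    if region == "frame":
        return np.ones(test.shape, dtype=bool)
    if region == "class-union":
        return test.mask(class_name) | reference.mask(class_name)
    raise ValueError(f"unknown evaluation region {region!r}")


def pairwise_agreement(
    test: LabeledSection,
    reference: LabeledSection,
    class_name: str,
    region: str = "tissue",
) -> AgreementStats:
    """Agreement of ``test`` against ``reference`` for one class.

    Precision = 100·TP/(TP+FP), sensitivity = 100·TP/(TP+FN), F1 their
    harmonic mean; FP% and FN% are referred to the evaluation-region
    area.  Both sections must share the raster frame and calibration.
    A class empty in both sections has no defined metrics.
    """
    if test.shape != reference.shape:
        raise ValueError(
            f"raster frames differ: {test.shape} vs {reference.shape}"
        )
    if test.calibration.microns_per_pixel != reference.calibration.microns_per_pixel:
        raise ValueError("calibrations differ between sections")
    ev = _evaluation_mask(test, reference, class_name, region)
    ev_area = float(ev.sum()) * test.calibration.um2_per_px
    t = test.mask(class_name) & ev
    r = reference.mask(class_name) & ev
    tp = float((t & r).sum())
    fp = float((t & ~r).sum())
    fn = float((~t & r).sum())
    if tp + fp + fn == 0:
        return AgreementStats(class_name, None, None, None, None, None,
                              ev_area, defined=False)
    ev_px = float(ev.sum())
    fp_pct = 100.0 * fp / ev_px if ev_px else None
    fn_pct = 100.0 * fn / ev_px if ev_px else None
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity > 0
        else 0.0
    )
    return AgreementStats(class_name, fp_pct, fn_pct, precision, sensitivity,
                          f1, ev_area)


def _mean_stats(rows: list[AgreementStats], class_name: str) -> AgreementStats:
    defined = [r for r in rows if r.defined]
    if not defined:
        return AgreementStats(class_name, None, None, None, None, None,
                              rows[0].eval_area_um2 if rows else 0.0,
                              defined=False)

    def mean(attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in defined]))

    return AgreementStats(
        class_name,
        mean("fp_pct"),
        mean("fn_pct"),
        mean("precision"),
        mean("sensitivity"),
        mean("f1"),
        mean("eval_area_um2"),
    )


def panel_agreement(
    model: LabeledSection,
    annotators: list[LabeledSection],
    class_name: str,
    region: str = "tissue",
    aggregation: str = "mean-of-pairs",
) -> tuple[AgreementStats, AgreementStats]:
    """(model-vs-panel, within-panel) agreement rows for one class.

    Model-vs-panel averages the pairwise rows with each annotator as the
    reference; within-panel averages all ordered annotator pairs (n·(n−1)
    comparisons).  ``aggregation="pooled"`` instead sums TP/FP/FN areas
    over comparisons before forming the metrics.
    """
    if len(annotators) < 2:
        raise ValueError("within-panel agreement needs at least 2 annotators")
    if aggregation not in ("mean-of-pairs", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    model_rows = [
        pairwise_agreement(model, ann, class_name, region) for ann in annotators
    ]
    panel_rows = [
        pairwise_agreement(a, b, class_name, region)
        for a, b in permutations(annotators, 2)
    ]
    if aggregation == "mean-of-pairs":
        return _mean_stats(model_rows, class_name), _mean_stats(panel_rows, class_name)
    return (
        _pooled_stats(model, annotators, class_name, region),
        _pooled_panel_stats(annotators, class_name, region),
    )


def _counts(test, reference, class_name, region):
    ev = _evaluation_mask(test, reference, class_name, region)
    t = test.mask(class_name) & ev
    r = reference.mask(class_name) & ev
    return (
        float((t & r).sum()),
        float((t & ~r).sum()),
        float((~t & r).sum()),
        float(ev.sum()),
    )


def _stats_from_counts(class_name, tp, fp, fn, ev_px, um2):
    if tp + fp + fn == 0:
        return AgreementStats(class_name, None, None, None, None, None,
                              ev_px * um2, defined=False)
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity > 0
        else 0.0
    )
    return AgreementStats(class_name, 100 * fp / ev_px, 100 * fn / ev_px,
                          precision, sensitivity, f1, ev_px * um2)


def _pooled_stats(model, annotators, class_name, region):
    tot = np.zeros(4)
    for ann in annotators:
        tot += _counts(model, ann, class_name, region)
    return _stats_from_counts(class_name, *tot, model.calibration.um2_per_px)


def _pooled_panel_stats(annotators, class_name, region):
    tot = np.zeros(4)
    for a, b in permutations(annotators, 2):
        tot += _counts(a, b, class_name, region)
    return _stats_from_counts(
        class_name, *tot, annotators[0].calibration.um2_per_px
    )
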