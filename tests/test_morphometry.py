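import math

import numpy as np
import pytest

from nephromorph import (
    Calibration,
    LabeledSection,
    MorphometryConfig,
    cortex_per_glomerulus_mm3,
    extract_components,
    glomerular_volume_mm3,
    merge_ah_lesions,
    pct_gsg,
    quantify,
)
from nephromorph.taxonomy import (
    AH,
    ARTERIAL_LUMEN,
    ARTERIES,
    CORTEX,
    DISTAL_TUBULE,
    INTIMA,
    NSG,
    PROXIMAL_TUBULE,
    TA_CLUSTER,
    TISSUE,
    TUBULES,
    TUBULOINTERSTITIUM,
)

from conftest import build_section
from oracles import transitive_merge_count


class TestGlomerularVolume:
    def test_weibel_gomez_formula_at_default_coefficients(self):
        # (1.38/1.01) * 10000^1.5 um^3 = 1.366e6 um^3
        v = glomerular_volume_mm3(10_000.0)
        assert v == pytest.approx(1.3663366e6 / 1e9, rel=1e-6)

    def test_unit_coefficients_unit_area(self):
        assert glomerular_volume_mm3(1.0, beta=1.0, d=1.0) == pytest.approx(1e-9)

    def test_mean_area_implied_by_donor_scale_volume_is_plausible(self):
        # invert V = (beta/d) A^(3/2) at V = 0.0028 mm^3
        a = (0.0028e9 * 1.01 / 1.38) ** (2.0 / 3.0)
        assert 15_000 <= a <= 17_500
        assert glomerular_volume_mm3(a) == pytest.approx(0.0028, rel=1e-9)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            glomerular_volume_mm3(0.0)


class TestCortexPerGlomerulus:
    def test_donor_scale_inputs_bracket_published_mean(self):
        # N_A = 2.46 per mm^2, V = 0.0028 mm^3, T = 2.5 um
        out = cortex_per_glomerulus_mm3(100.0, 246, 0.0028, 2.5)
        assert 0.066 <= out <= 0.078

    def test_linear_in_cortex_area_at_fixed_count(self):
        a = cortex_per_glomerulus_mm3(10.0, 25, 0.0028)
        b = cortex_per_glomerulus_mm3(20.0, 25, 0.0028)
        assert b == pytest.approx(2 * a)

    def test_unit_volumetric_density_identity(self):
        # N_A = count/cortex = (D+T) makes N_V = 1, so the result is 1 mm^3
        v, t_um = 0.003, 2.5
        d = (6 * v / math.pi) ** (1 / 3)
        out = cortex_per_glomerulus_mm3(1.0 / (d + t_um / 1000.0), 1, v, t_um)
        assert out == pytest.approx(1.0)


class TestPctGsg:
    @pytest.mark.parametrize(
        "nsg,gsg,expected", [(18, 2, 10.0), (7, 0, 0.0), (0, 5, 100.0)]
    )
    def test_fraction_of_glomeruli_globally_sclerosed(self, nsg, gsg, expected):
        assert pct_gsg(nsg, gsg) == pytest.approx(expected)

    def test_no_glomeruli_rejected(self):
        with pytest.raises(ValueError):
            pct_gsg(0, 0)


def _section_with_squares(positions, size_px, mpp=0.5, cls=AH, width=None):
    """Squares of a class at given (row, col) top-left corners."""
    rows = max(p[0] for p in positions) + size_px + 4
    cols = (width or (max(p[1] for p in positions) + size_px)) + 4
    m = np.zeros((rows, cols), dtype=bool)
    for r, c in positions:
        m[r : r + size_px, c : c + size_px] = True
    return build_section({cls: m}, mpp=mpp,
                         tissue=np.ones((rows, cols), dtype=bool))


class TestAhMerge:
    def test_lesions_300um_apart_count_once(self):
        # gap of 600 px at 0.5 um/px = 300 um boundary distance
        sec = _section_with_squares([(10, 10), (10, 10 + 20 + 600)], 20)
        merged = merge_ah_lesions(extract_components(sec, AH))
        assert len(merged) == 1

    def test_lesions_exactly_500um_apart_count_twice(self):
        sec = _section_with_squares([(10, 10), (10, 10 + 20 + 1000)], 20)
        merged = merge_ah_lesions(extract_components(sec, AH))
        assert len(merged) == 2

    def test_chain_merges_by_transitive_closure(self):
        # A-B and B-C 400 um apart, A-C far: one counted lesion
        gap = 800  # px = 400 um
        sec = _section_with_squares(
            [(10, 10), (10, 10 + 20 + gap), (10, 10 + 2 * (20 + gap))], 20
        )
        comps = merge_ah_lesions(extract_components(sec, AH))
        dists = {}
        raw = extract_components(sec, AH)
        for i in range(len(raw)):
            for j in range(i + 1, len(raw)):
                dists[(i, j)] = raw[i].boundary.distance(raw[j].boundary)
        assert len(comps) == transitive_merge_count(dists, 500.0)
        assert len(comps) == 1

    def test_merge_is_idempotent_and_keeps_largest_representative(self):
        sec = _section_with_squares([(10, 10), (40, 10 + 30 + 200)], 30)
        small = np.zeros(sec.shape, dtype=bool)
        small[12:22, 300:310] = True  # 10x10 near the first 30x30 square
        sec.masks[AH] |= small
        merged = merge_ah_lesions(extract_components(sec, AH))
        assert merge_ah_lesions(merged) == merged
        # representative area is the largest member's own area, not a sum
        assert {round(c.area_um2, 3) for c in merged} <= {
            round(30 * 30 * 0.25, 3)
        }


class TestTubularAtrophyMeasures:
    def test_no_atrophy_reports_interstitial_fraction_only(self):
        # TI 100x100, tubules fill 70 rows: %TA=0, %ITA=30
        ti = np.ones((100, 100), dtype=bool)
        tub = np.zeros_like(ti)
        tub[:70] = True
        sec = build_section(
            {CORTEX: ti, TUBULOINTERSTITIUM: ti, TUBULES: tub}, mpp=1.0
        )
        res = quantify(sec)
        assert res.pct_ta == pytest.approx(0.0)
        assert res.pct_ita == pytest.approx(30.0)
        assert res.ta_foci_density_per_mm2 == pytest.approx(0.0)

    def test_atrophy_fraction_uses_tubules_plus_ta_denominator(self):
        ti = np.ones((100, 100), dtype=bool)
        tub = np.zeros_like(ti)
        tub[:95] = True
        ta = np.zeros_like(ti)
        ta[97:98, :50] = True  # 50 px; tubules 9500 px
        sec = build_section(
            {CORTEX: ti, TUBULOINTERSTITIUM: ti, TUBULES: tub, TA_CLUSTER: ta},
            mpp=1.0,
        )
        res = quantify(sec)
        assert res.pct_ta == pytest.approx(100.0 * 50 / 9550)

    def test_foci_density_per_tubular_area(self):
        # 10 foci of 1 px at 50 um/px (2500 um^2 each); denominator 2.5 mm^2
        shape = (40, 40)
        tub = np.zeros(shape, dtype=bool)
        tub.flat[:990] = True
        ta = np.zeros(shape, dtype=bool)
        for i in range(10):
            ta[30, 2 * i] = True
        sec = build_section(
            {CORTEX: np.ones(shape, bool), TUBULOINTERSTITIUM: np.ones(shape, bool),
             TUBULES: tub & ~ta, TA_CLUSTER: ta},
            mpp=50.0,
        )
        res = quantify(sec)
        assert res.ta_foci_count == 10
        denom_mm2 = (int((tub & ~ta).sum()) + 10) * 2500 / 1e6
        assert res.ta_foci_density_per_mm2 == pytest.approx(10 / denom_mm2)


class TestLuminalStenosis:
    @staticmethod
    def _artery_section(side_px, intima_px=0, lumen_px=0, mpp=1.0):
        shape = (side_px + 8, side_px + 8)
        art = np.zeros(shape, dtype=bool)
        art[4 : 4 + side_px, 4 : 4 + side_px] = True
        intima = np.zeros(shape, dtype=bool)
        intima.flat[: 0] = False
        lumen = np.zeros(shape, dtype=bool)
        r0 = 4 + side_px // 2
        placed = 0
        it = np.ndindex(side_px, side_px)
        for rr, cc in it:
            if placed < intima_px:
                intima[4 + rr, 4 + cc] = True
            elif placed < intima_px + lumen_px:
                lumen[4 + rr, 4 + cc] = True
            else:
                break
            placed += 1
        return build_section(
            {CORTEX: np.ones(shape, bool), ARTERIES: art, INTIMA: intima,
             ARTERIAL_LUMEN: lumen},
            mpp=mpp,
        )

    def test_small_artery_is_excluded_and_measure_missing(self):
        sec = self._artery_section(70)  # 4900 um^2 < 7850 gate
        res = quantify(sec)
        assert res.pct_luminal_stenosis is None
        assert "pct_luminal_stenosis" in res.missing

    def test_stenosis_is_intima_over_intima_plus_lumen(self):
        sec = self._artery_section(90, intima_px=200, lumen_px=800)  # 8100 um^2
        res = quantify(sec)
        assert res.pct_luminal_stenosis == pytest.approx(20.0)

    def test_qualifying_artery_without_intima_scores_zero(self):
        sec = self._artery_section(90, intima_px=0, lumen_px=800)
        res = quantify(sec)
        assert res.pct_luminal_stenosis == pytest.approx(0.0)


class TestQuantify:
    def test_empty_section_counts_zero_and_ratios_missing(self):
        sec = build_section({TISSUE: np.zeros((32, 32), dtype=bool)})
        res = quantify(sec)
        assert res.nsg_count == res.gsg_count == res.ta_foci_count == 0
        for name in ("pct_gsg", "pct_ta", "pct_ita", "glomerular_volume_mm3",
                     "mean_ah_area_um2", "pct_luminal_stenosis"):
            assert getattr(res, name) is None
            assert name in res.missing

    def test_mean_tubular_area_of_equal_tubules(self):
        shape = (100, 200)
        prox = np.zeros(shape, dtype=bool)
        for c in (10, 70, 130, 180):
            prox[40:60, c - 10 : c + 10] = True  # 400 px each
        sec = build_section(
            {CORTEX: np.ones(shape, bool), PROXIMAL_TUBULE: prox},
            mpp=math.sqrt(5.0),  # 400 px * 5 um^2 = 2000 um^2
            tissue=np.ones(shape, bool),
        )
        res = quantify(sec)
        assert res.mean_proximal_tubular_area_um2 == pytest.approx(2000.0)
        assert res.mean_distal_tubular_area_um2 is None

    def test_edge_clipped_tubule_does_not_shift_the_mean(self):
        shape = (60, 200)
        tissue = np.zeros(shape, dtype=bool)
        tissue[5:55, 5:195] = True
        dist = np.zeros(shape, dtype=bool)
        dist[20:30, 40:50] = True
        dist[20:30, 80:90] = True
        clipped = np.zeros(shape, dtype=bool)
        clipped[20:30, 0:9] = True  # touches the cut edge
        sec = build_section(
            {DISTAL_TUBULE: dist | (clipped & tissue)}, mpp=1.0, tissue=tissue
        )
        res = quantify(sec)
        assert res.mean_distal_tubular_area_um2 == pytest.approx(100.0)
        off = quantify(
            sec, MorphometryConfig(exclude_edge_bisected_from_means=False)
        )
        assert off.mean_distal_tubular_area_um2 < 100.0

    def test_scale_equivariance_of_areas_and_invariance_of_ratios(
        self, donor_scene
    ):
        section, _ = donor_scene
        small = LabeledSection(
            taxonomy=section.taxonomy,
            calibration=Calibration(
                section.calibration.microns_per_pixel * 2,
                section.calibration.section_thickness_um,
            ),
            masks=section.masks,
            capsule=section.capsule,
            kind=section.kind,
        )
        a, b = quantify(section), quantify(small)
        assert b.cortex_area_mm2 == pytest.approx(4 * a.cortex_area_mm2)
        assert b.nsg_count == a.nsg_count
        assert b.pct_gsg == pytest.approx(a.pct_gsg)
        assert b.pct_ita == pytest.approx(a.pct_ita)

    def test_adding_sclerosed_glomerulus_never_lowers_pct_gsg(self, donor_scene):
        section, _ = donor_scene
        before = quantify(section)
        import nephromorph.taxonomy as tx

        grown = {k: v.copy() for k, v in section.masks.items()}
        blob = np.zeros(section.shape, dtype=bool)
        blob[400:420, 200:220] = True
        grown[tx.GSG] |= blob
        grown[tx.GLOMERULAR_AREA] |= blob
        sec2 = LabeledSection(section.taxonomy, section.calibration, grown,
                              section.capsule, section.kind)
        after = quantify(sec2)
        assert after.pct_gsg >= before.pct_gsg

    def test_isolated_ah_lesion_never_lowers_density(self, donor_scene):
        section, _ = donor_scene
        before = quantify(section)
        grown = {k: v.copy() for k, v in section.masks.items()}
        blob = np.zeros(section.shape, dtype=bool)
        blob[60:66, 60:66] = True  # far from existing lesions
        grown[AH] |= blob
        grown[ARTERIES] |= blob
        sec2 = LabeledSection(section.taxonomy, section.calibration, grown,
                              section.capsule, section.kind)
        after = quantify(sec2)
        assert after.ah_density_per_mm2 >= before.ah_density_per_mm2
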