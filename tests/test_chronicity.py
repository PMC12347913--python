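import numpy as np
import pandas as pd
import pytest

from nephromorph import (
    DEFAULT_BANDS,
    BandSpec,
    MorphometryResult,
    band_score,
    hypertrophy_score,
    nephrosclerosis_score,
    reference_report,
    score,
)


def _measures(gsg=None, ita=None, ta=None, ah=None, cpg=None, **kw):
    return MorphometryResult(
        pct_gsg=gsg,
        pct_ita=ita,
        ta_foci_density_per_mm2=ta,
        mean_ah_area_um2=ah,
        cortex_per_glomerulus_mm3=cpg,
        **kw,
    )


class TestBandScore:
    @pytest.mark.parametrize(
        "value,expected",
        [(0, 0), (4.9, 0), (5.0, 0), (5.01, 1), (10.0, 1), (15, 2),
         (20.0, 2), (20.01, 3), (100, 3)],
    )
    def test_ta_density_bands_are_upper_inclusive(self, value, expected):
        assert band_score(value, DEFAULT_BANDS["ta_foci_density_per_mm2"]) == expected

    @pytest.mark.parametrize(
        "value,expected",
        [(499, 0), (500, 0), (501, 1), (750, 1), (800, 2), (1000, 2), (1001, 3)],
    )
    def test_ah_area_bands(self, value, expected):
        assert band_score(value, DEFAULT_BANDS["mean_ah_area_um2"]) == expected

    @pytest.mark.parametrize(
        "value,expected",
        [(0.05, 0), (0.075, 0), (0.08, 1), (0.125, 1), (0.15, 2),
         (0.175, 2), (0.2, 3)],
    )
    def test_cortex_per_glomerulus_bands(self, value, expected):
        assert band_score(
            value, DEFAULT_BANDS["cortex_per_glomerulus_mm3"]
        ) == expected

    @pytest.mark.parametrize(
        "value,expected",
        [(0, 0), (9.9, 0), (10.0, 1), (25.5, 1), (26.0, 2), (30, 2),
         (50.0, 2), (50.1, 3), (90, 3)],
    )
    def test_percent_bands_are_half_open_with_inclusive_band2_top(
        self, value, expected
    ):
        assert band_score(value, DEFAULT_BANDS["pct_gsg"]) == expected

    def test_missing_value_propagates(self):
        assert band_score(None, DEFAULT_BANDS["pct_gsg"]) is None

    def test_cuts_must_ascend(self):
        with pytest.raises(ValueError):
            BandSpec("x", (5.0, 5.0, 10.0))

    def test_exactly_three_jump_points_per_measure(self):
        for spec in DEFAULT_BANDS.values():
            hi = spec.cuts[2] * 2
            grid = np.linspace(0.0, hi, 20001)
            scores = np.array([band_score(v, spec) for v in grid])
            jumps = np.flatnonzero(np.diff(scores) != 0)
            assert len(jumps) == 3
            assert set(np.unique(scores)) == {0, 1, 2, 3}
            for j in jumps:  # each jump brackets a printed cut point
                lo, hi_ = grid[j], grid[j + 1]
                assert any(lo <= c <= hi_ or lo < c <= hi_ for c in spec.cuts)


class TestCompositeScores:
    def test_all_measures_below_first_cuts_total_zero(self):
        cs = score(_measures(gsg=2.0, ita=5.0, ta=3.0, ah=100.0, cpg=0.05))
        assert cs.nephrosclerosis_total == 0
        assert cs.hypertrophy_total == 0

    def test_all_measures_above_top_cuts_total_twelve(self):
        cs = score(_measures(gsg=90.0, ita=90.0, ta=50.0, ah=5000.0, cpg=0.5))
        assert cs.nephrosclerosis_total == 12
        assert cs.hypertrophy_total == 12

    def test_worked_mixed_example_totals_eight(self):
        cs = score(_measures(gsg=30.0, ita=30.0, ta=15.0, ah=800.0, cpg=0.15))
        assert (cs.gsg_score, cs.ita_score, cs.ta_density_score,
                cs.ah_area_score, cs.cortex_per_glom_score) == (2, 2, 2, 2, 2)
        assert cs.nephrosclerosis_total == 8
        assert cs.hypertrophy_total == 8

    def test_boundary_values_at_first_cuts_score_zero(self):
        cs = hypertrophy_score(
            _measures(gsg=9.0, ta=5.0, ah=500.0, cpg=0.075, ita=None)
        )
        assert cs.hypertrophy_total == 0

    def test_missing_component_propagates_by_default(self):
        cs = nephrosclerosis_score(
            _measures(gsg=30.0, ita=None, ta=15.0, ah=800.0, cpg=0.15)
        )
        assert cs.nephrosclerosis_total is None
        assert "nephrosclerosis_total" in cs.missing
        assert cs.hypertrophy_total == 8  # unaffected by the missing %ITA

    def test_missing_component_can_be_imputed_zero(self):
        cs = score(
            _measures(gsg=30.0, ita=None, ta=15.0, ah=800.0, cpg=0.15),
            missing_policy="treat-as-0",
        )
        assert cs.nephrosclerosis_total == 6

    def test_totals_are_monotone_in_every_measure(self):
        rng = np.random.default_rng(1)
        base = dict(gsg=20.0, ita=20.0, ta=8.0, ah=600.0, cpg=0.1)
        scales = {"gsg": 100, "ita": 100, "ta": 40, "ah": 2000, "cpg": 0.4}
        for key in base:
            values = np.sort(rng.uniform(0, scales[key], 50))
            totals = []
            for v in values:
                kw = dict(base)
                kw[key] = float(v)
                cs = score(_measures(**kw))
                totals.append((cs.nephrosclerosis_total, cs.hypertrophy_total))
            for a, b in zip(totals, totals[1:]):
                assert b[0] >= a[0] and b[1] >= a[1]

    def test_swapping_ita_and_cortex_per_glom_bands_swaps_the_scores(self):
        # choose values whose bands differ: ita->1, cpg->3
        a = score(_measures(gsg=30.0, ta=15.0, ah=800.0, ita=12.0, cpg=0.5))
        assert a.nephrosclerosis_total != a.hypertrophy_total
        # feed measures whose bands are exchanged
        b = score(_measures(gsg=30.0, ta=15.0, ah=800.0, ita=60.0, cpg=0.1))
        assert b.nephrosclerosis_total == a.hypertrophy_total
        assert b.hypertrophy_total == a.nephrosclerosis_total


class TestReferenceReport:
    @staticmethod
    def _reference(n=100, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "pct_gsg": rng.uniform(0, 10, n),
                "mean_ah_area_um2": rng.uniform(50, 300, n),
            }
        )

    def test_patient_below_all_limits_has_no_flags(self):
        res = _measures(gsg=1.0, ah=60.0)
        rep = reference_report(res, self._reference())
        flagged = [
            n for n, e in rep["measures"].items() if e.get("out_of_range")
        ]
        assert flagged == []

    def test_value_just_above_a_degenerate_reference_is_flagged(self):
        ref = pd.DataFrame({"pct_gsg": [7.0] * 100})
        rep = reference_report(_measures(gsg=8.0), ref)
        assert rep["measures"]["pct_gsg"]["upper_reference_limit"] == 7.0
        assert rep["measures"]["pct_gsg"]["out_of_range"] is True
        rep2 = reference_report(_measures(gsg=7.0), ref)
        assert rep2["measures"]["pct_gsg"]["out_of_range"] is False

    def test_limit_is_the_95th_percentile_of_the_reference(self):
        rng = np.random.default_rng(12345)
        ref = pd.DataFrame({"pct_gsg": rng.uniform(0, 1, 10_000)})
        rep = reference_report(_measures(gsg=0.5), ref)
        assert rep["measures"]["pct_gsg"]["upper_reference_limit"] == pytest.approx(
            0.95, abs=0.02
        )

    def test_sparse_or_absent_reference_columns_are_noted(self):
        ref = pd.DataFrame({"pct_gsg": [1.0] * 5})
        rep = reference_report(_measures(gsg=2.0, ta=1.0), ref)
        assert "pct_gsg" in rep["notes"]  # too few observations
        assert "upper_reference_limit" not in rep["measures"]["pct_gsg"]
        assert "absent" in rep["notes"]["ta_foci_density_per_mm2"]
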