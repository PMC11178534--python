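"""Zone partition, NPI computation, transforms and correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import retnpi as rn
from retnpi.npi_metrics import ZONE_FAR, ZONE_MID, ZONE_POSTERIOR
from retnpi.segmentation import PerfusionMask, STATE_NONPERFUSED, STATE_PERFUSED


def uniform_mask(model, state=STATE_PERFUSED):
    from retnpi.eye_geometry import inside_field

    field = inside_field(model)
    arr = np.zeros(model.image_size, dtype=np.uint8)
    arr[field] = state
    return PerfusionMask(arr, np.zeros_like(arr))


class TestAssignZones:
    def test_zone_membership_by_geodesic_distance(self, model_256, area_256):
        zones = rn.assign_zones(model_256, area_256)
        from retnpi.eye_geometry import sphere_to_image, SpherePoint

        for mm, expected in [(5.0, ZONE_POSTERIOR), (12.0, ZONE_MID), (17.0, ZONE_FAR)]:
            r, c = sphere_to_image(model_256, SpherePoint(mm / 12.0, 0.3))
            assert zones.zone_label[int(round(r)), int(round(c))] == expected

    def test_zone_fractions_match_reference_split(self, model_512, area_512):
        zones = rn.assign_zones(model_512, area_512)
        fractions = 100 * zones.ta / zones.ta_total
        np.testing.assert_allclose(fractions, [32.0, 35.0, 33.0], atol=1.0)

    def test_zone_tas_sum_to_total(self, model_256, area_256):
        zones = rn.assign_zones(model_256, area_256)
        assert zones.ta.sum() == pytest.approx(zones.ta_total, rel=1e-12)

    def test_voxel_dialect_counts_pixels(self, model_256, area_256):
        zones = rn.assign_zones(model_256, area_256, dialect="voxel")
        assert zones.ta_total == area_256.inside_field.sum()

    def test_shape_mismatch_raises(self, model_256):
        other = rn.pixel_area_map(rn.default_eye_model((64, 64)))
        with pytest.raises(ValueError):
            rn.assign_zones(model_256, other)


class TestComputeNPI:
    def test_all_perfused_gives_zero_everywhere(self, model_256, area_256):
        mask = uniform_mask(model_256, STATE_PERFUSED)
        zones = rn.assign_zones(model_256, area_256, mask)
        m = rn.compute_npi(mask, zones, area_256)
        np.testing.assert_allclose(m.npi_zone, 0.0)
        assert m.npi_overall == 0.0

    def test_all_nonperfused_gives_one_everywhere(self, model_256, area_256):
        mask = uniform_mask(model_256, STATE_NONPERFUSED)
        zones = rn.assign_zones(model_256, area_256, mask)
        m = rn.compute_npi(mask, zones, area_256)
        np.testing.assert_allclose(m.npi_zone, 1.0)
        assert m.npi_overall == pytest.approx(1.0)

    def test_overall_is_ta_weighted_mean_of_zone_npis(self, model_256, area_256, rng):
        truth = rn.TruthRegion(model=model_256, frontier_radius=13.0)
        mask = PerfusionMask.from_truth(truth.rasterize(), area_256.inside_field)
        zones = rn.assign_zones(model_256, area_256, mask)
        m = rn.compute_npi(mask, zones, area_256)
        weighted = np.nansum(m.npi_zone * m.ta) / m.ta.sum()
        assert m.npi_overall == pytest.approx(weighted, rel=1e-12)

    def test_partition_conservation_of_nonperfused_area(self, model_256, area_256):
        truth = rn.TruthRegion(model=model_256, frontier_radius=11.0)
        mask = PerfusionMask.from_truth(truth.rasterize(), area_256.inside_field)
        zones = rn.assign_zones(model_256, area_256, mask)
        m = rn.compute_npi(mask, zones, area_256)
        per_zone_sum = float(np.nansum(m.npi_zone * m.ta))
        total = float(area_256.pixel_area[mask.nonperfused].sum())
        assert per_zone_sum == pytest.approx(total, rel=1e-9)

    def test_toy_grid_fraction(self):
        # 10x10 uniform grid, all posterior, 37 nonperfused pixels -> 0.37
        model = rn.build_eye_model(12.0, 5.0, (20, 20), "azimuthal_equidistant")
        area = rn.pixel_area_map(model)
        state = np.zeros((20, 20), dtype=np.uint8)
        state[area.inside_field] = STATE_PERFUSED
        grad = np.flatnonzero(area.inside_field.ravel())[:100]
        flat = state.ravel()
        flat[grad[:37]] = STATE_NONPERFUSED
        # keep only those 100 pixels gradable so counting is exact
        keep = np.zeros(400, dtype=bool)
        keep[grad] = True
        flat[~keep] = 0
        mask = PerfusionMask(flat.reshape(20, 20), np.zeros((20, 20), dtype=np.uint8))
        zones = rn.assign_zones(model, area, mask, dialect="voxel")
        m = rn.compute_npi(mask, zones, area, dialect="voxel")
        assert m.npi_overall == pytest.approx(0.37)


class TestAggregateVisit:
    def _measure(self, overall, post=0.1, visit=0.0):
        zone = np.array([post, overall, overall])
        return rn.NPIMeasurement(
            patient_id="P1", eye="OD", visit_time=visit, npi_zone=zone,
            npi_overall=overall, t_npi_overall=rn.transform_npi(overall),
            t_npi_posterior=rn.transform_npi(post),
        )

    def test_identical_measurements_unchanged(self):
        ms = [self._measure(0.2) for _ in range(3)]
        agg = rn.aggregate_visit(ms)
        assert agg.npi_overall == pytest.approx(0.2)
        assert agg.n_images_averaged == 3

    def test_mean_of_three(self):
        agg = rn.aggregate_visit([self._measure(v) for v in (0.10, 0.20, 0.30)])
        assert agg.npi_overall == pytest.approx(0.20)
        assert agg.t_npi_overall == pytest.approx(rn.transform_npi(0.20))

    def test_singleton_passthrough(self):
        agg = rn.aggregate_visit([self._measure(0.4)])
        assert agg.npi_overall == 0.4
        assert agg.n_images_averaged == 1

    def test_mixed_eyes_rejected(self):
        a = self._measure(0.1)
        b = self._measure(0.1)
        b.eye = "OS"
        with pytest.raises(ValueError):
            rn.aggregate_visit([a, b])


class TestTransformNPI:
    @pytest.mark.parametrize("npi,expected", [(0.0, 0.025), (0.5, 0.5), (1.0, 0.975)])
    def test_boundary_and_fixed_point(self, npi, expected):
        assert rn.transform_npi(npi, 20) == pytest.approx(expected, abs=1e-15)

    @given(st.floats(0.0, 1.0), st.integers(2, 100))
    def test_inverse_round_trip_and_range(self, npi, n):
        t = rn.transform_npi(npi, n)
        assert 0.5 / n - 1e-12 <= t <= 1 - 0.5 / n + 1e-12
        assert rn.inverse_transform_npi(t, n) == pytest.approx(npi, abs=1e-12)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_order_preserving(self, a, b):
        ta, tb = rn.transform_npi(a), rn.transform_npi(b)
        assert (a < b) == (ta < tb) or a == b

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rn.transform_npi(1.2)
        with pytest.raises(ValueError):
            rn.transform_npi(0.5, n_eyes=1)


class TestPctChange:
    def test_flat_series_is_zero(self):
        np.testing.assert_allclose(rn.pct_change_from_baseline([0.2, 0.2, 0.2]), [0.0, 0.0])

    def test_doubling_is_100(self):
        assert rn.pct_change_from_baseline([0.1, 0.2])[0] == pytest.approx(100.0)

    def test_zero_baseline_flagged_nan(self):
        out = rn.pct_change_from_baseline([0.0, 0.2])
        assert np.isnan(out).all()

    def test_mean_across_eyes(self):
        df = pd.DataFrame({
            "patient_id": ["P1", "P1", "P2", "P2"],
            "eye": ["OD", "OD", "OD", "OD"],
            "visit_time": [0.0, 1.0, 0.0, 1.0],
            "npi_overall": [0.10, 0.15, 0.10, 0.17],
        })
        out = rn.mean_pct_change(df)
        assert out.loc[1.0] == pytest.approx((50.0 + 70.0) / 2)


class TestFunctionalTransforms:
    def test_log_oct_worked_values(self):
        assert rn.functional_transforms(cst=270.0).log_oct == pytest.approx(2.43, abs=0.005)
        assert rn.functional_transforms(cst=100.0).log_oct == pytest.approx(2.0)

    def test_snellen_equivalents(self):
        assert rn.functional_transforms(logmar=0.0).snellen_denominator == pytest.approx(20.0)
        denom = rn.functional_transforms(logmar=0.176).snellen_denominator
        assert 25.0 < denom < 30.01
        assert denom == pytest.approx(30.0, abs=0.1)

    def test_nonpositive_cst_rejected(self):
        with pytest.raises(ValueError):
            rn.functional_transforms(cst=0.0)


class TestCorrelations:
    def _table(self, third_overall):
        rows = []
        base = [0.1, 0.2, 0.3, 0.4]
        for rep, vals in ((1, base), (3, third_overall)):
            for k, v in enumerate(vals):
                rows.append({
                    "patient_id": f"P{k}", "eye": "OD", "visit_time": 0.0,
                    "repeat_index": rep, "npi_overall": v,
                    "npi_posterior": v / 2, "npi_mid": v, "npi_far": 2 * v,
                })
        return pd.DataFrame(rows)

    def test_identical_series_give_pearson_one(self):
        out = rn.reliability_and_zone_correlations(self._table([0.1, 0.2, 0.3, 0.4]))
        assert out["pearson_first_third"]["npi_overall"] == pytest.approx(1.0)

    def test_negated_series_give_pearson_minus_one(self):
        out = rn.reliability_and_zone_correlations(self._table([-0.1, -0.2, -0.3, -0.4]))
        assert out["pearson_first_third"]["npi_overall"] == pytest.approx(-1.0)

    def test_spearman_matches_rank_formula(self):
        # ranks (1,2,3,4) vs (1,2,4,3): rho = 1 - 6*2/(4*15) = 0.8
        df = self._table([0.1, 0.2, 0.3, 0.4])
        df.loc[df["repeat_index"] == 1, "npi_mid"] = [0.1, 0.2, 0.4, 0.3]
        df.loc[df["repeat_index"] == 3, "npi_mid"] = [0.1, 0.2, 0.4, 0.3]
        out = rn.reliability_and_zone_correlations(df)
        assert out["spearman_zone_vs_overall"]["npi_mid"] == pytest.approx(0.8)

    def test_constant_series_flagged(self):
        df = self._table([0.1, 0.2, 0.3, 0.4])
        df["npi_far"] = 0.5
        out = rn.reliability_and_zone_correlations(df)
        assert np.isnan(out["spearman_zone_vs_overall"]["npi_far"])
        assert any("npi_far" in f for f in out["flags"])
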