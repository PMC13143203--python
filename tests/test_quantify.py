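import numpy as np
import pandas as pd
import pytest

from organoquant import (
    PolygonROI,
    QuantRecord,
    VolumeStack,
    categorize_marker_counts,
    edu_dapi_ratio,
    max_projection,
    per_mouse_average,
    polygon_area,
)

from oracles import max_projection_bruteforce, polygon_area_raster


class TestEduDapiRatio:
    def test_basic_counts(self):
        edu = np.zeros((5, 10, 10), dtype=bool)
        dapi = np.zeros((5, 10, 10), dtype=bool)
        edu.flat[:100] = True
        dapi.flat[:400] = True
        assert edu_dapi_ratio(edu, dapi) == 0.25

    def test_empty_edu_gives_zero(self):
        dapi = np.ones((3, 3, 3), dtype=bool)
        assert edu_dapi_ratio(np.zeros_like(dapi), dapi) == 0.0

    def test_empty_dapi_rejected(self):
        masks = np.zeros((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError):
            edu_dapi_ratio(masks, masks)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            edu_dapi_ratio(
                np.zeros((3, 3, 3), dtype=bool), np.ones((3, 3, 4), dtype=bool)
            )

    def test_scale_free_under_upsampling(self):
        rng = np.random.default_rng(0)
        edu = rng.uniform(size=(4, 4, 4)) > 0.7
        dapi = edu | (rng.uniform(size=(4, 4, 4)) > 0.5)
        up = lambda m: np.kron(m, np.ones((2, 2, 2), dtype=bool))
        assert edu_dapi_ratio(up(edu), up(dapi)) == edu_dapi_ratio(edu, dapi)


class TestQuantRecord:
    def test_ratio_consistency_enforced(self):
        with pytest.raises(ValueError):
            QuantRecord("o", 10, 100, 0.5)
        with pytest.raises(ValueError):
            QuantRecord("o", 10, 0, 0.0)

    def test_from_masks(self):
        dapi = np.ones((2, 5, 5), dtype=bool)
        edu = np.zeros_like(dapi)
        edu[0] = True
        rec = QuantRecord.from_masks("org", edu, dapi)
        assert rec.edu_dapi_ratio == 0.5
        assert rec.dapi_positive_voxels == 50


class TestMaxProjection:
    def test_single_plane_identity(self):
        data = np.arange(16, dtype=np.uint16).reshape(1, 1, 4, 4)
        stack = VolumeStack(data, ["DAPI"])
        np.testing.assert_array_equal(max_projection(stack, "DAPI"), data[0, 0])

    def test_disjoint_bright_pixels_union(self):
        data = np.zeros((1, 2, 4, 4), dtype=np.uint8)
        data[0, 0, 0, 0] = 200
        data[0, 1, 3, 3] = 100
        proj = max_projection(VolumeStack(data, ["c"]), "c")
        assert proj[0, 0] == 200 and proj[3, 3] == 100
        assert proj.sum() == 300

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_elementwise_max_oracle(self, seed):
        rng = np.random.default_rng(500 + seed)
        data = rng.integers(0, 1000, size=(1, 6, 8, 8)).astype(np.uint16)
        stack = VolumeStack(data, ["c"])
        np.testing.assert_array_equal(
            max_projection(stack, "c"), max_projection_bruteforce(data[0])
        )


class TestPolygonArea:
    def test_square_with_scale(self):
        roi = PolygonROI(((0, 0), (10, 0), (10, 10), (0, 10)), 2.0)
        assert polygon_area(roi) == pytest.approx(25.0)

    def test_triangle_shoelace(self):
        roi = PolygonROI(((0, 0), (4, 0), (0, 3)), 1.0)
        assert polygon_area(roi) == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rasterization_within_2pct(self, seed):
        rng = np.random.default_rng(600 + seed)
        # star-shaped construction (strictly increasing angles) is simple
        n = int(rng.integers(5, 12))
        angles = 2 * np.pi * (np.arange(n) + rng.uniform(0.1, 0.9, n)) / n
        radii = rng.uniform(5, 15, n)
        verts = tuple(
            (20 + r * np.cos(a), 20 + r * np.sin(a)) for r, a in zip(radii, angles)
        )
        roi = PolygonROI(verts, 1.0)
        area = polygon_area(roi)
        raster = polygon_area_raster(verts)
        assert area == pytest.approx(raster, rel=0.02)

    def test_invariant_to_reversal_and_rotation(self):
        verts = ((0, 0), (5, 1), (6, 4), (2, 6), (-1, 3))
        base = polygon_area(PolygonROI(verts, 1.5))
        assert polygon_area(PolygonROI(verts[::-1], 1.5)) == pytest.approx(base)
        rotated = verts[2:] + verts[:2]
        assert polygon_area(PolygonROI(rotated, 1.5)) == pytest.approx(base)


class TestCategorize:
    def test_example_fractions(self):
        out = categorize_marker_counts([0, 3, 12, 0])
        assert out == {"0": 0.5, "1-9": 0.25, ">=10": 0.25}

    def test_all_zero(self):
        assert categorize_marker_counts([0, 0, 0]) == {"0": 1.0, "1-9": 0.0, ">=10": 0.0}

    def test_bin_edges(self):
        out = categorize_marker_counts([1, 9, 10])
        assert out["1-9"] == pytest.approx(2 / 3)
        assert out[">=10"] == pytest.approx(1 / 3)
        assert out["0"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_fractions_sum_to_one_exactly(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=rng.integers(1, 50)).tolist()
        assert sum(categorize_marker_counts(counts).values()) == 1.0

    def test_rejects_negative_or_non_integer(self):
        with pytest.raises(ValueError):
            categorize_marker_counts([1, -2])
        with pytest.raises(ValueError):
            categorize_marker_counts([0.5, 1.5])


class TestPerMouseAverage:
    def _table(self):
        return pd.DataFrame(
            {
                "mouse_id": ["A", "A", "A", "B", "B", "C"],
                "condition": ["ctl", "ctl", "ctl", "ctl", "ctl", "drug"],
                "unit_id": [1, 2, 3, 1, 2, 1],
                "count": [1, 2, 3, 3, 5, 7],
            }
        )

    def test_mouse_means(self):
        mouse_means, _ = per_mouse_average(self._table())
        means = dict(zip(mouse_means["mouse_id"], mouse_means["mean"]))
        assert means == {"A": 2.0, "B": 4.0, "C": 7.0}

    def test_condition_summary_sem_over_mice(self):
        _, summary = per_mouse_average(self._table())
        ctl = summary[summary["condition"] == "ctl"].iloc[0]
        # mouse means 2.0 and 4.0: mean 3.0, sd sqrt(2), sem 1.0
        assert ctl["mean"] == pytest.approx(3.0)
        assert ctl["sem"] == pytest.approx(1.0)
        assert ctl["n_mice"] == 2

    def test_single_mouse_condition_sem_undefined(self):
        _, summary = per_mouse_average(self._table())
        drug = summary[summary["condition"] == "drug"].iloc[0]
        assert drug["mean"] == pytest.approx(7.0)
        assert np.isnan(drug["sem"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            per_mouse_average(self._table().iloc[:0])
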