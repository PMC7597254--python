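"""ROI geometry, masked region means, delta features and boxplot stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sto2stress.hsi_core import Map2D
from sto2stress.roi_features import (
    ROI_NAMES,
    build_feature_table,
    default_geometry,
    delta_scores,
    fraction_below_zero,
    mean_sto2,
    roi_boxplot_stats,
)
from sto2stress.synthetic import CohortConfig, generate_cohort


class TestGeometry:
    def test_seven_disjoint_nonempty_regions(self, small_geometry):
        assert set(small_geometry.names) == set(ROI_NAMES)
        total = np.zeros(small_geometry.canvas_shape, int)
        for roi in small_geometry.names:
            m = small_geometry.mask(roi)
            assert m.any(), roi
            total += m
        assert total.max() == 1  # pairwise disjoint

    def test_area_identical_across_participants_by_construction(self, small_geometry):
        # a single shared raster defines each ROI: every map sees the same area
        a1 = small_geometry.area_px("ROI4")
        a2 = small_geometry.area_px("ROI4")
        assert a1 == a2 > 0

    def test_yaml_round_trip(self, tmp_path, small_geometry):
        path = tmp_path / "geom.yaml"
        small_geometry.to_yaml(path)
        back = type(small_geometry).from_yaml(path)
        assert back.canvas_shape == small_geometry.canvas_shape
        for roi in small_geometry.names:
            assert np.array_equal(back.mask(roi), small_geometry.mask(roi))


class TestMeanSto2:
    def test_constant_map(self, small_geometry, small_shape):
        m = Map2D(np.full(small_shape, 0.7))
        for roi in small_geometry.names:
            assert mean_sto2(m, small_geometry, roi) == pytest.approx(0.7)

    def test_value_inside_polygon_only(self, small_geometry, small_shape):
        """ROI4 mean reflects ROI4 pixels; values elsewhere are invisible.
        Verified against explicit pixel enumeration."""
        vals = np.full(small_shape, 0.9)
        roi4 = small_geometry.mask("ROI4")
        vals[roi4] = 0.6
        m = Map2D(vals)
        assert mean_sto2(m, small_geometry, "ROI4") == pytest.approx(0.6)
        assert mean_sto2(m, small_geometry, "ROI1") == pytest.approx(0.9)
        # oracle: brute-force enumeration over the raster
        assert mean_sto2(m, small_geometry, "ROI4") == pytest.approx(
            np.mean([vals[r, c] for r, c in zip(*np.nonzero(roi4))])
        )

    def test_mask_aware_mean_and_validity_threshold(self, small_geometry, small_shape):
        vals = np.full(small_shape, 0.8)
        mask = np.ones(small_shape, bool)
        roi = small_geometry.mask("ROI1")
        rows, cols = np.nonzero(roi)
        half = len(rows) // 2
        mask[rows[:half], cols[:half]] = False
        m = Map2D(vals, mask)
        assert mean_sto2(m, small_geometry, "ROI1") == pytest.approx(0.8)
        # below 50% valid -> NaN
        mask[rows, cols] = False
        mask[rows[: len(rows) // 3], cols[: len(rows) // 3]] = True
        assert np.isnan(mean_sto2(Map2D(vals, mask), small_geometry, "ROI1"))

    def test_unknown_roi(self, small_geometry, small_shape):
        with pytest.raises(KeyError):
            mean_sto2(Map2D(np.zeros(small_shape)), small_geometry, "ROI9")


class TestFeatureTable:
    def test_full_cohort_yields_84_balanced_rows(self, small_feature_table):
        table = small_feature_table
        assert len(table) == 84
        assert (table["stress"].value_counts() == 42).all()
        assert not table[[f"ROI{i}" for i in range(1, 8)]].isna().any().any()

    def test_identical_stress_and_baseline_give_zero_row(self, small_geometry, small_shape):
        m = Map2D(np.random.default_rng(0).uniform(0.5, 0.8, small_shape))
        cohort = {"P001": {c: m for c in
                           ("ES_baseline", "ES", "PS_baseline", "PS1", "PS2")}}
        table = build_feature_table(cohort, small_geometry)
        assert np.allclose(table[[f"ROI{i}" for i in range(1, 8)]], 0.0)

    def test_incomplete_participant_excluded(self, small_geometry, small_shape):
        m = Map2D(np.full(small_shape, 0.6))
        full = {c: m for c in ("ES_baseline", "ES", "PS_baseline", "PS1", "PS2")}
        partial = {c: m for c in ("ES_baseline", "ES")}
        table = build_feature_table({"A": full, "B": partial}, small_geometry)
        assert set(table["participant"]) == {"A"}

    def test_recovers_configured_effect_means(self, small_cohort, small_feature_table):
        """Cohort-average ES features match the configured per-ROI effect
        means within 2 standard errors."""
        _, truth = small_cohort
        es = small_feature_table[small_feature_table["stress"] == "ES"]
        for roi, (mean, _) in truth.config.es_effects.items():
            col = es[roi]
            se = col.std(ddof=1) / np.sqrt(len(col))
            assert abs(col.mean() - mean) < 2 * se + 1e-3, roi


class TestDeltaScores:
    def test_contrast_additivity(self, small_cohort, small_geometry):
        cohort, _ = small_cohort
        scores = delta_scores(cohort, small_geometry)
        wide = scores.pivot_table(index=["participant", "roi"],
                                  columns="contrast", values="delta")
        np.testing.assert_allclose(
            wide["PS1-PS_baseline"] + wide["PS2-PS1"],
            wide["PS2-PS_baseline"], atol=1e-12,
        )

    def test_ps2_equal_baseline_gives_zero_contrast(self, small_geometry, small_shape):
        rng = np.random.default_rng(3)
        base = Map2D(rng.uniform(0.5, 0.8, small_shape))
        ps1 = Map2D(rng.uniform(0.5, 0.8, small_shape))
        cohort = {"P001": {"ES_baseline": base, "ES": base,
                           "PS_baseline": base, "PS1": ps1, "PS2": base}}
        scores = delta_scores(cohort, small_geometry)
        final = scores[scores["contrast"] == "PS2-PS_baseline"]["delta"]
        np.testing.assert_allclose(final, 0.0, atol=1e-12)

    def test_ps1_negative_fraction_tracks_p_down(self, small_shape):
        """With p_down = 0.6, the fraction of participants whose overall
        PS1 delta is negative falls inside the binomial 95% band."""
        config = CohortConfig(canvas_shape=small_shape, seed=77)
        cohort, truth = generate_cohort(config)
        geometry = default_geometry(small_shape)
        scores = delta_scores(cohort, geometry)
        frac = fraction_below_zero(scores, "PS1-PS_baseline")
        n = config.n_participants
        band = 1.96 * np.sqrt(0.6 * 0.4 / n)
        assert abs(frac - 0.6) <= band + 1e-9
        # and the realised flags agree with the stored truth
        expect = np.mean([p.ps_down for p in truth.participants.values()])
        assert frac == pytest.approx(expect)


class TestBoxplotStats:
    def test_small_closed_form(self):
        stats = roi_boxplot_stats(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert stats == {"min": 1.0, "q1": 2.0, "median": 3.0, "q3": 4.0, "max": 5.0}

    def test_constant_vector(self):
        stats = roi_boxplot_stats(np.full(42, 0.7))
        assert set(stats.values()) == {0.7}

    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="5"):
            roi_boxplot_stats(np.array([1.0, 2.0]))

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=5, max_size=60))
    def test_matches_order_statistics_oracle(self, values):
        """Five-number summary equals brute-force sorted order statistics
        with linear quantile interpolation."""
        v = np.sort(np.asarray(values))
        stats = roi_boxplot_stats(v)

        def quantile(q):  # brute-force linear interpolation on sorted data
            pos = q * (len(v) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            frac = pos - lo
            return v[lo] * (1 - frac) + v[hi] * frac

        assert stats["min"] == v[0] and stats["max"] == v[-1]
        assert stats["q1"] == pytest.approx(quantile(0.25), abs=1e-12)
        assert stats["median"] == pytest.approx(quantile(0.5), abs=1e-12)
        assert stats["q3"] == pytest.approx(quantile(0.75), abs=1e-12)
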