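"""Subset enumeration, CV protocol, classifier comparison and cheek t-test."""

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sto2stress.classify import (
    CLASSIFIERS,
    DIMENSION_COUNTS,
    cheek_ttest,
    compare_classifiers,
    cv_rate,
    enumerate_subsets,
    exhaustive_search,
)


def _make_table(rng, n_per_class=42, offset=0.0, n_rois=7):
    """Two Gaussian classes separated by `offset` SDs in every ROI."""
    rows = []
    for label, shift in (("ES", 0.0), ("PS", offset)):
        X = rng.normal(shift, 1.0, (n_per_class, n_rois))
        for i, x in enumerate(X):
            rows.append({"participant": f"{label}{i}", "stress": label,
                         **{f"ROI{j+1}": x[j] for j in range(n_rois)}})
    return pd.DataFrame(rows)


class TestEnumerateSubsets:
    def test_seven_rois_give_127_subsets_partitioned_binomially(self):
        subsets = enumerate_subsets(7)
        assert len(subsets) == 127
        by_size = [sum(1 for s in subsets if len(s) == k) for k in range(1, 8)]
        assert tuple(by_size) == DIMENSION_COUNTS == (7, 21, 35, 35, 21, 7, 1)

    def test_single_roi(self):
        assert enumerate_subsets(1) == [(1,)]

    def test_size_six_group_lists_all_seven_leave_one_out_subsets(self):
        six = [s for s in enumerate_subsets(7) if len(s) == 6]
        expected = [tuple(sorted(set(range(1, 8)) - {k})) for k in range(7, 0, -1)]
        assert sorted(six) == sorted(expected)
        assert len(six) == 7

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            enumerate_subsets(0)

    @settings(deadline=None, max_examples=10)
    @given(st.integers(min_value=1, max_value=10))
    def test_matches_power_set_oracle(self, n):
        """Enumeration equals the brute-force power set (minus the empty
        set), in by-size lexicographic order."""
        oracle = sorted(
            chain.from_iterable(
                combinations(range(1, n + 1), k) for k in range(1, n + 1)
            ),
            key=lambda s: (len(s), s),
        )
        assert enumerate_subsets(n) == oracle


class TestCVRate:
    def test_no_signal_stays_in_chance_band(self, rng):
        table = _make_table(rng, offset=0.0)
        res = cv_rate(table, (1, 2, 3), folds=5, repeats=20, seed=5)
        assert 40.0 <= res.rate <= 60.0

    def test_separable_classes_classified_almost_perfectly(self, rng):
        table = _make_table(rng, offset=10.0)
        res = cv_rate(table, (1, 2, 3, 4, 5, 6, 7), folds=5, repeats=10, seed=5)
        assert res.rate > 99.0
        assert res.class_rates["ES"] > 99.0 and res.class_rates["PS"] > 99.0

    def test_constant_single_feature_is_uninformative(self, rng):
        table = _make_table(rng, offset=10.0)
        table["ROI1"] = 0.0
        res = cv_rate(table, (1,), folds=5, repeats=20, seed=5)
        assert 40.0 <= res.rate <= 60.0

    def test_seed_determinism(self, rng):
        table = _make_table(rng, offset=1.0)
        a = cv_rate(table, (1, 2), seed=9, repeats=5)
        b = cv_rate(table, (1, 2), seed=9, repeats=5)
        assert a.rate == b.rate and a.class_rates == b.class_rates

    def test_too_few_samples_rejected(self, rng):
        table = _make_table(rng, n_per_class=2)
        with pytest.raises(ValueError, match="folds"):
            cv_rate(table, (1,), folds=5)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            cv_rate(_make_table(rng), ())


class TestExhaustiveSearch:
    def test_signal_only_in_roi_457_is_found(self, rng):
        """Classes differ only in ROI4/5/7, and each third of the PS class
        is displaced in exactly one of those regions: every subset missing
        one of the three overlaps a whole PS subpopulation with ES, so the
        search must name exactly {4, 5, 7} as the global best."""
        table = _make_table(rng, offset=0.0)
        ps_idx = table.index[table["stress"] == "PS"].to_numpy()
        for k, col in enumerate(("ROI4", "ROI5", "ROI7")):
            table.loc[ps_idx[k::3], col] += 6.0
        res = exhaustive_search(table, folds=5, repeats=5, seed=3)
        assert tuple(res.best["subset"]) == (4, 5, 7)
        assert res.best["rate"] > 95.0

    def test_dimension_row_counts(self, rng):
        table = _make_table(rng, offset=1.0)
        res = exhaustive_search(table, folds=5, repeats=2, seed=1)
        assert tuple(res.dimension_counts()) == DIMENSION_COUNTS
        assert len(res.table) == 127

    def test_all_noise_cohort_never_leaves_chance_band(self, rng):
        """Without signal, even the maximum over all 127 subsets stays
        below the upper chance limit for the repeated-CV estimate."""
        table = _make_table(rng, offset=0.0)
        res = exhaustive_search(table, folds=5, repeats=5, seed=2)
        assert res.table["rate"].max() < 70.0
        assert 40.0 <= res.table["rate"].mean() <= 60.0


class TestCompareClassifiers:
    def test_six_algorithms_reported_and_separable_data_easy(self, rng):
        table = _make_table(rng, offset=10.0)
        report = compare_classifiers(table, (4, 5, 7), folds=5, repeats=3, seed=4)
        assert list(report.index) == list(CLASSIFIERS)
        assert len(report) == 6
        assert (report["rate"] > 90.0).all()

    def test_unknown_algorithm_rejected(self, rng):
        with pytest.raises(KeyError):
            compare_classifiers(_make_table(rng), (1,), algorithms=("quantum",))


class TestCheekTTest:
    def test_identical_columns_give_null_result(self, rng):
        table = _make_table(rng)
        table["ROI4"] = table["ROI2"]
        report = cheek_ttest(table)
        for contrast in ("All", "ES", "PS"):
            assert report[contrast].h == 0
            assert report[contrast].t == pytest.approx(0.0, abs=1e-12)
            assert report[contrast].p == pytest.approx(1.0)
            lo, hi = report[contrast].ci
            assert lo < 0 < hi

    def test_strong_lateral_effect_detected(self, rng):
        table = _make_table(rng)
        table["ROI4"] = table["ROI2"] + 5.0
        report = cheek_ttest(table)
        assert report["All"].h == 1 and report["All"].p < 1e-6
        assert report["All"].t < 0  # ROI2 minus ROI4 is negative

    def test_type_i_error_rate_under_null(self, rng):
        """Equal cheek distributions: rejection fraction at alpha=0.05 over
        seeded replicates stays near the nominal level."""
        rejections = 0
        n_rep = 200
        for k in range(n_rep):
            r = np.random.default_rng(k)
            table = _make_table(r, n_per_class=42)
            rejections += cheek_ttest(table)["All"].h
        assert 0.01 <= rejections / n_rep <= 0.10
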