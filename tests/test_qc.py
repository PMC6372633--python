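import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabotyper import qc
from metabotyper.errors import SchemaError

from .conftest import make_feature_table


def blank_frame(values, features):
    return pd.DataFrame(
        np.asarray(values, dtype=float),
        index=[f"blank_{i}" for i in range(len(values))],
        columns=features,
    )


class TestRemoveBackground:
    def test_zero_blanks_change_nothing_but_log(self):
        t = make_feature_table([[1, 2], [3, 4]])
        blanks = blank_frame([[0, 0]], t.features)
        out = qc.remove_background(t, blanks, 0.5)
        # 0 >= 0.5 * mean is false for positive means -> nothing dropped
        assert list(out.features) == list(t.features)

    def test_equal_mean_dropped_at_half_threshold(self):
        t = make_feature_table([[2, 2], [2, 4]])
        blanks = blank_frame([[2, 0.1]], t.features)  # blank mean == sample mean for F001
        out = qc.remove_background(t, blanks, 0.5)
        assert list(out.features) == ["F002"]
        assert out.log[-1]["removed"] == ["F001"]

    def test_disjoint_axes_error(self):
        t = make_feature_table([[1.0]])
        blanks = pd.DataFrame([[1.0]], columns=["other"], index=["blank_0"])
        with pytest.raises(SchemaError):
            qc.remove_background(t, blanks)

    def test_synthetic_background_exactly_removed(self, small_study):
        out = qc.remove_background(small_study.table, small_study.blanks)
        removed = set(out.log[-1]["removed"])
        assert removed == set(small_study.truth.background_features)


class TestZerosToMissing:
    def test_counts(self):
        t = make_feature_table([[0, 1], [2, 0], [0, 3]])
        out = qc.zeros_to_missing(t)
        assert int(out.values.isna().sum().sum()) == 3
        assert out.log[-1]["n_nulled"] == 3

    def test_zero_free_identity(self):
        t = make_feature_table([[1, 2], [3, 4]])
        out = qc.zeros_to_missing(t)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_idempotent(self):
        t = make_feature_table([[0, 1], [2, 0]])
        once = qc.zeros_to_missing(t)
        twice = qc.zeros_to_missing(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert twice.log[-1]["n_nulled"] == 0


def _two_cell_table(col_values_by_cell):
    """Build a table with two genotype cells (5 samples each), one feature."""
    rows = []
    vals = []
    i = 0
    for g, cell_vals in col_values_by_cell.items():
        for v in cell_vals:
            rows.append(dict(plant_id=f"p{i}", genotype=g, tissue="aboveground",
                             regime="control", replicate=i + 1))
            vals.append([v])
            i += 1
    return make_feature_table(np.array(vals, dtype=float), rows)


class TestPresenceFilter:
    def test_one_qualifying_cell_keeps_feature(self):
        t = _two_cell_table({"G1": [1, 2, 3, 4, 5], "G2": [np.nan] * 5})
        out = qc.presence_filter(t, min_present=3)
        assert list(out.features) == ["F001"]

    def test_no_qualifying_cell_removes_feature(self):
        t = _two_cell_table({"G1": [1, 2, np.nan, np.nan, np.nan],
                             "G2": [1, np.nan, np.nan, np.nan, np.nan]})
        out = qc.presence_filter(t, min_present=3)
        assert out.n_features == 0
        assert out.log[-1]["removed"] == ["F001"]

    def test_complete_table_nothing_removed(self, small_study):
        clean = qc.zeros_to_missing(small_study.table)
        # drop injected NAs by refilling: use the no-injection variant instead
        t = make_feature_table(np.ones((4, 3)))
        out = qc.presence_filter(t, min_present=3)
        assert out.n_features == 3

    def test_empty_table_errors(self):
        t = make_feature_table(np.ones((2, 2)))
        t.values = t.values.iloc[:, :0]
        with pytest.raises(SchemaError):
            qc.presence_filter(t)

    def test_matches_bruteforce_recount(self, small_study):
        t = qc.zeros_to_missing(small_study.table)
        out = qc.presence_filter(t, min_present=3)
        # brute force: feature kept iff some cell holds >= 3 values
        meta = t.meta
        kept_bf = []
        for f in t.features:
            keep = False
            for (_g, _r, _t), sub in meta.groupby(["genotype", "regime", "tissue"]):
                if t.values.loc[sub.index, f].notna().sum() >= 3:
                    keep = True
                    break
            if keep:
                kept_bf.append(f)
        assert list(out.features) == kept_bf


class TestFlagOutliers:
    def test_constant_cell_no_outliers(self):
        t = _two_cell_table({"G1": [5, 5, 5, 5, 5]})
        out = qc.flag_outliers(t)
        assert not out.values.isna().any().any()

    def test_hand_computed_fence(self):
        # cell {1,2,3,4,100}: type-7 Q1=2, Q3=4, IQR=2 -> upper fence 10
        t = _two_cell_table({"G1": [1, 2, 3, 4, 100]})
        out = qc.flag_outliers(t)
        assert out.values.isna().sum().sum() == 1
        assert np.isnan(out.values.iloc[4, 0])

    def test_value_at_fence_not_flagged(self):
        # strict inequality: exactly Q3 + 3*IQR survives
        t = _two_cell_table({"G1": [1, 2, 3, 4, 10]})
        # Q1=2, Q3=4, IQR=2 -> fence = 10; 10 is not > 10
        out = qc.flag_outliers(t)
        assert not out.values.isna().any().any()

    def test_never_creates_values(self, small_study):
        t = qc.zeros_to_missing(small_study.table)
        out = qc.flag_outliers(t)
        before = t.values.notna()
        after = out.values.notna()
        assert not (after & ~before).any().any()

    def test_injected_outliers_recovered(self, small_study):
        filt = qc.run_qc(small_study.table, small_study.blanks)
        inj = {(s, f) for s, f in small_study.truth.outlier_cells
               if f in set(filt.features)}
        flagged = {
            (s, f)
            for f in filt.features
            for s in filt.values.index[filt.values[f].isna()]
            if small_study.table.values.at[s, f] != 0
        }
        assert inj <= flagged  # full recall on this fixture

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=4, max_size=12))
    def test_matches_bruteforce_fences(self, vals):
        t = _two_cell_table({"G1": vals})
        out = qc.flag_outliers(t)
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        iqr = q3 - q1
        upper, lower = q3 + 3 * iqr, q1 - 3 * iqr
        got_flag = out.values["F001"].isna().tolist()
        eps = 1e-9 * (1 + abs(upper) + abs(lower))
        for v, got in zip(vals, got_flag):
            if v > upper + eps or v < lower - eps:
                assert got
            elif lower + eps < v < upper - eps:
                assert not got
            # values within eps of a fence are float ties; strictness is
            # checked exactly in test_value_at_fence_not_flagged


class TestLog2Transform:
    def test_values(self):
        t = make_feature_table([[8, 1], [2, np.nan]])
        out = qc.log2_transform(t)
        assert out.values.iloc[0, 0] == 3
        assert out.values.iloc[0, 1] == 0
        assert out.values.iloc[1, 0] == 1
        assert np.isnan(out.values.iloc[1, 1])

    def test_nonpositive_names_cell(self):
        t = make_feature_table([[0.0, 1.0]])
        with pytest.raises(ValueError, match="F001"):
            qc.log2_transform(t)

    def test_pseudocount(self):
        t = make_feature_table([[0.0, 3.0]])
        out = qc.log2_transform(t, pseudocount=1.0)
        assert out.values.iloc[0, 0] == 0
        assert out.values.iloc[0, 1] == 2


class TestAnovaPresenceFilter:
    def test_complete_table_zero_removals(self):
        rows = []
        vals = []
        i = 0
        for g in ("G1", "G2"):
            for regime in ("control", "drought"):
                for r in range(3):
                    rows.append(dict(plant_id=f"p{i}", genotype=g,
                                     tissue="aboveground", regime=regime,
                                     replicate=r + 1))
                    vals.append([1.0, 2.0])
                    i += 1
        t = make_feature_table(np.array(vals), rows)
        rep = qc.anova_presence_filter(t)
        assert rep.n_removed == {"aboveground": 0}

    def test_single_value_group_untestable(self):
        rows = []
        vals = []
        i = 0
        for regime, cell in (("control", [1.0, np.nan, np.nan]), ("drought", [1.0, 2.0, 3.0])):
            for v in cell:
                rows.append(dict(plant_id=f"p{i}", genotype="G1",
                                 tissue="aboveground", regime=regime,
                                 replicate=i + 1))
                vals.append([v])
                i += 1
        t = make_feature_table(np.array(vals), rows)
        rep = qc.anova_presence_filter(t)
        assert not rep.testable["aboveground"].loc["G1", "F001"]
        assert rep.n_removed["aboveground"] == 1

    def test_reproducible_counts(self, small_spec):
        from metabotyper import synthetic as syn

        b = syn.generate_study(small_spec, missing_rate=0.3)
        t = qc.zeros_to_missing(b.table)
        r1 = qc.anova_presence_filter(t)
        r2 = qc.anova_presence_filter(t)
        assert r1.n_removed == r2.n_removed
        assert all(v >= 0 for v in r1.n_removed.values())


class TestPipelineProperties:
    def test_canonical_order_logged(self, small_study):
        out = qc.run_qc(small_study.table, small_study.blanks)
        steps = [e["step"] for e in out.log if e["step"] != "simulate"]
        assert steps == ["remove_background", "zeros_to_missing",
                         "presence_filter", "flag_outliers"]

    def test_idempotence_on_own_output(self, small_study):
        once = qc.run_qc(small_study.table, small_study.blanks)
        twice = qc.run_qc(once, None)  # background already removed
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_nonmissing_count_never_increases(self, small_study):
        t = small_study.table
        counts = [t.values.notna().sum().sum()]
        t1 = qc.remove_background(t, small_study.blanks)
        t2 = qc.zeros_to_missing(t1)
        t3 = qc.presence_filter(t2)
        t4 = qc.flag_outliers(t3)
        for step in (t1, t2, t3, t4):
            counts.append(step.values.notna().sum().sum())
        assert all(a >= b for a, b in zip(counts, counts[1:]))
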