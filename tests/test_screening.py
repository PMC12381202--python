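"""Screening, winsorization, imputation, scoring and redundancy tests."""

import numpy as np
import pandas as pd
import pytest

from symptomnet.screening import (goldbricker_redundancy, impute_chained,
                                  score_dass, score_psqi, score_swls,
                                  screen_records, winsorize_z)
from symptomnet.simulate import DASS_LABELS


def _record(**over):
    row = {c: 1 for c in DASS_LABELS}
    row.update({"duration_min": 25.0, "trap_ok": 1, "child_id": 0})
    row["D1"] = 2  # break the straight-line pattern
    row.update(over)
    return pd.DataFrame([row])


class TestScreenRecords:
    def test_clean_record_passes(self):
        report, valid = screen_records(_record())
        assert len(valid) == 1
        assert not report.flags.drop(columns="invalid").iloc[0].any()

    def test_too_fast_below_ten_minutes(self):
        report, valid = screen_records(_record(duration_min=9.5))
        assert report.flags.too_fast.iloc[0]
        assert len(valid) == 0

    def test_boundary_duration_is_valid(self):
        report, _ = screen_records(_record(duration_min=10.0))
        assert not report.flags.too_fast.iloc[0]

    def test_trap_failure(self):
        report, _ = screen_records(_record(trap_ok=0))
        assert report.flags.trap_failed.iloc[0]

    def test_excess_missing_five_of_21(self):
        # 5/21 = 23.8% > 20%
        over = {c: np.nan for c in DASS_LABELS[:5]}
        report, _ = screen_records(_record(**over))
        assert report.flags.excess_missing.iloc[0]
        # 4/21 = 19.0% passes
        over = {c: np.nan for c in DASS_LABELS[:4]}
        report, _ = screen_records(_record(**over))
        assert not report.flags.excess_missing.iloc[0]

    def test_straight_line_full_instrument(self):
        report, _ = screen_records(_record(D1=1))  # all 21 items equal
        assert report.flags.straight_lined.iloc[0]

    def test_duplicate_row(self):
        df = pd.concat([_record(child_id=0), _record(child_id=1)],
                       ignore_index=True)
        report, valid = screen_records(df)
        assert report.flags.duplicate.tolist() == [False, True]
        assert len(valid) == 1

    def test_missing_metadata_named(self):
        with pytest.raises(ValueError, match="duration_min"):
            screen_records(_record().drop(columns="duration_min"))

    def test_idempotent(self, small_cohort):
        report, valid = screen_records(small_cohort.frame)
        report2, valid2 = screen_records(valid.reset_index(drop=True))
        assert report2.n_excluded == 0
        assert len(valid2) == len(valid)

    def test_validity_rate_definition(self, small_cohort):
        report, _ = screen_records(small_cohort.frame)
        assert report.validity_rate == pytest.approx(
            100.0 * report.n_valid / report.n_total)
        assert 0 <= report.validity_rate <= 100


class TestWinsorize:
    def test_identity_without_outliers(self, rng):
        x = rng.normal(size=200)
        x = np.clip(x, -2.5, 2.5)
        np.testing.assert_array_equal(winsorize_z(x), x)

    def test_extreme_replaced_by_99th_percentile(self):
        x = np.array([0.0] * 99 + [1000.0])
        out = winsorize_z(x)
        assert out[-1] == pytest.approx(np.percentile(x, 99))
        np.testing.assert_array_equal(out[:-1], 0.0)

    def test_constant_vector_warns_unchanged(self):
        x = np.full(10, 3.0)
        with pytest.warns(UserWarning):
            out = winsorize_z(x)
        np.testing.assert_array_equal(out, x)

    def test_preserves_rank_and_never_widens_range(self, rng):
        x = np.concatenate([rng.normal(size=500), [25.0, -25.0]])
        out = winsorize_z(x)
        assert out.max() <= x.max() and out.min() >= x.min()
        keep = np.abs((x - x.mean()) / x.std()) <= 3
        orig_order = np.argsort(x[keep], kind="stable")
        np.testing.assert_array_equal(np.argsort(out[keep], kind="stable"),
                                      orig_order)


class TestImputeChained:
    def test_no_missing_identity(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        outs = impute_chained(df, n_imputations=2, seed=0)
        for out in outs:
            pd.testing.assert_frame_equal(out, df)

    def test_determinism(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        df.loc[::7, "a"] = np.nan
        a = impute_chained(df, n_imputations=2, n_iterations=5, seed=3)
        b = impute_chained(df, n_imputations=2, n_iterations=5, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert not a[0].equals(a[1])  # imputations differ among themselves

    def test_mcar_mean_recovery(self, rng):
        """10% MCAR on correlated normal data: the imputed-column mean stays
        within 2 standard errors of the complete-data mean."""
        n = 800
        z = rng.normal(size=n)
        df = pd.DataFrame({"a": z + rng.normal(scale=0.5, size=n),
                           "b": z + rng.normal(scale=0.5, size=n),
                           "c": rng.normal(size=n)})
        full_mean = df["a"].mean()
        se = df["a"].std() / np.sqrt(n)
        amp = df.copy()
        amp.loc[rng.choice(n, n // 10, replace=False), "a"] = np.nan
        out = impute_chained(amp, n_imputations=3, n_iterations=10, seed=1)
        for done in out:
            assert abs(done["a"].mean() - full_mean) < 2 * se

    def test_binary_column_stays_binary(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=200),
                           "b": (rng.random(200) < 0.4).astype(float)})
        df.loc[:20, "b"] = np.nan
        out = impute_chained(df, n_imputations=1, n_iterations=5, seed=2)[0]
        assert set(out["b"].unique()) <= {0.0, 1.0}

    def test_fully_missing_column_errors(self):
        df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="missing"):
            impute_chained(df)


class TestScoring:
    def test_dass_all_zero(self):
        s = score_dass(pd.DataFrame(np.zeros((1, 21)), columns=DASS_LABELS))
        assert s["dass_depression"].iloc[0] == 0
        assert not s["depression_case"].iloc[0]
        assert not s["anxiety_case"].iloc[0]
        assert not s["stress_case"].iloc[0]

    @pytest.mark.parametrize("subscale,cutoff", [("depression", 9),
                                                 ("anxiety", 7),
                                                 ("stress", 4)])
    def test_dass_cutoffs_strict(self, subscale, cutoff):
        """Scores at the cut-off are normal; one point above is a case."""
        prefix = {"depression": "D", "anxiety": "A", "stress": "S"}[subscale]
        for total, is_case in [(cutoff, False), (cutoff + 1, True)]:
            items = pd.DataFrame(np.zeros((1, 21)), columns=DASS_LABELS)
            q, r = divmod(total, 3)
            for i in range(q):
                items[f"{prefix}{i + 1}"] = 3
            if r:
                items[f"{prefix}{q + 1}"] = r
            s = score_dass(items)
            assert s[f"dass_{subscale}"].iloc[0] == total
            assert bool(s[f"{subscale}_case"].iloc[0]) is is_case

    def test_dass_out_of_range_errors(self):
        items = pd.DataFrame(np.zeros((1, 21)), columns=DASS_LABELS)
        items["D1"] = 5
        with pytest.raises(ValueError):
            score_dass(items)

    def test_dass_permutation_invariant_within_subscale(self, rng):
        items = pd.DataFrame(rng.integers(0, 4, (20, 21)),
                             columns=DASS_LABELS)
        base = score_dass(items).frame
        perm = items.copy()
        cols = [f"D{i}" for i in range(1, 8)]
        perm[cols] = perm[cols[::-1]].to_numpy()
        pd.testing.assert_series_equal(score_dass(perm)["dass_depression"],
                                       base["dass_depression"])

    def test_psqi(self):
        out = score_psqi([[0] * 7, [1, 1, 1, 1, 1, 1, 0], [1, 1, 1, 1, 1, 0, 0]])
        assert out.psqi_global.tolist() == [0, 6, 5]
        # strictly greater than 5
        assert out.sleep_disorder.tolist() == [False, True, False]

    def test_psqi_wrong_count(self):
        with pytest.raises(ValueError):
            score_psqi([[1, 2, 3]])

    def test_swls_bands(self):
        out = score_swls([[7] * 5, [4] * 5, [1] * 5])
        assert out.swls_total.tolist() == [35, 20, 5]
        assert out.swls_band.tolist() == ["satisfied", "neutral",
                                          "dissatisfied"]

    def test_swls_out_of_range(self):
        with pytest.raises(ValueError):
            score_swls([[0, 4, 4, 4, 4]])

    def test_case_flags_monotone_in_score(self, rng):
        items = pd.DataFrame(rng.integers(0, 4, (100, 21)),
                             columns=DASS_LABELS)
        s = score_dass(items).frame.sort_values("dass_depression")
        flags = s["depression_case"].to_numpy()
        assert (np.diff(flags.astype(int)) >= 0).all()


class TestGoldbricker:
    def test_duplicated_item_flagged(self, rng):
        base = rng.normal(size=(300, 5))
        df = pd.DataFrame(base, columns=list("abcde"))
        df["a_copy"] = df["a"] + rng.normal(scale=0.05, size=300)
        out = goldbricker_redundancy(df)
        flagged = out[out.redundant]
        assert {"a", "a_copy"} in [set(t) for t in
                                   zip(flagged.node_i, flagged.node_j)]

    def test_independent_items_empty(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 6)), columns=list("abcdef"))
        out = goldbricker_redundancy(df)
        assert len(out) == 0

    def test_default_cohort_has_no_redundancy(self, sdg_items_3000):
        """Items generated from the default truth are conceptually distinct:
        the 25%-proportion rule flags no pair."""
        out = goldbricker_redundancy(sdg_items_3000[list(DASS_LABELS)])
        assert not out.redundant.any()

    def test_too_few_items(self, rng):
        with pytest.raises(ValueError):
            goldbricker_redundancy(
                pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc")))
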