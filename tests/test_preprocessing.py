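"""Splitting, winsorization, imputation, resampling, standardization."""

import numpy as np
import pandas as pd
import pytest

from fedperiop.datatypes import FeatureSchema, SiteDataset, OUTCOMES
from fedperiop.preprocessing import (
    ChannelStats,
    ContinuousStats,
    chronological_split,
    encode_categorical,
    fit_preprocessor,
    impute,
    pool_datasets,
    resample_timeseries,
    standardize,
    transform,
    winsorize,
    PreprocessorState,
)
from fedperiop.synthetic import generate_multisite_cohort, gnv_like


def _toy_dataset(n=100, n_patients=None, dates=None, schema=None):
    schema = schema or FeatureSchema(
        continuous=("c0",), binary=("b0",), highcard={"pc": 4}, channels=("hr",)
    )
    rng = np.random.default_rng(0)
    n_patients = n_patients or n
    pid = [f"P{i % n_patients}" for i in range(n)]
    if dates is None:
        dates = pd.date_range("2015-01-01", periods=n, freq="D")
    df = pd.DataFrame(
        {
            "patient_id": pid,
            "surgery_id": [f"S{i:04d}" for i in range(n)],
            "surgery_date": dates,
            "sex": "male", "race": "white", "age": 50, "surgery_type": "general",
            "c0": rng.standard_normal(n),
            "b0": rng.integers(0, 2, n),
            "pc": rng.integers(0, 4, n).astype(float),
            "_t": np.linspace(0, 1, n),
        }
    )
    for o in OUTCOMES:
        df[f"y_{o}"] = rng.integers(0, 2, n)
        df[f"_eta_{o}"] = 0.0
    return SiteDataset("T", df, schema)


# ------------------------------------------------------------------ split


def test_split_sizes_and_chronology_with_distinct_dates():
    ds = _toy_dataset(n=100)
    split = chronological_split(ds)
    assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (63, 7, 30)
    dates = ds.preop.set_index("surgery_id")["surgery_date"]
    assert dates[split.train_ids].max() < dates[split.test_ids].min()


def test_patient_grouping_assigns_all_surgeries_to_earliest_cohort():
    ds = _toy_dataset(n=100)
    # patient of the first surgery also has the last surgery (test window)
    ds.preop.loc[99, "patient_id"] = ds.preop.loc[0, "patient_id"]
    split = chronological_split(ds)
    assert "S0000" in split.train_ids and "S0099" in split.train_ids
    assert len(split.train_ids) == 64


def test_split_tie_break_on_shared_date_is_deterministic():
    ds = _toy_dataset(n=100, dates=[pd.Timestamp("2015-06-01")] * 100)
    a = chronological_split(ds)
    b = chronological_split(ds)
    assert (len(a.train_ids), len(a.val_ids), len(a.test_ids)) == (63, 7, 30)
    assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
    with pytest.raises(ValueError):
        chronological_split(ds.subset([]))


# ---------------------------------------------------------------- fitting


def _order_stat_percentile(values, q):
    """Sort-based linear-interpolation percentile oracle."""
    s = np.sort(values)
    h = (len(s) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def test_percentiles_match_order_statistic_oracle():
    rng = np.random.default_rng(5)
    for values in [np.arange(1.0, 1001.0), rng.standard_normal(357), rng.exponential(2, 1000)]:
        ds = _toy_dataset(n=len(values))
        ds.preop["c0"] = values
        state = fit_preprocessor(ds)
        st = state.continuous["c0"]
        for attr, q in (("p05", 0.5), ("p1", 1), ("p5", 5), ("p95", 95), ("p99", 99), ("p995", 99.5)):
            assert getattr(st, attr) == pytest.approx(_order_stat_percentile(values, q), rel=1e-12)
        assert st.p05 <= st.p1 <= st.p5 <= st.p95 <= st.p99 <= st.p995


def test_constant_feature_degenerates_to_identity_winsorization():
    ds = _toy_dataset(n=50)
    ds.preop["c0"] = 3.14
    state = fit_preprocessor(ds)
    st = state.continuous["c0"]
    assert st.p05 == st.p995 == 3.14
    out = winsorize(np.full(10, 3.14), st, np.random.default_rng(0))
    np.testing.assert_array_equal(out, np.full(10, 3.14))


def test_even_n_median_uses_midpoint_convention():
    ds = _toy_dataset(n=4)
    ds.preop["c0"] = [1.0, 2.0, 3.0, 4.0]
    assert fit_preprocessor(ds).continuous["c0"].median == 2.5


def test_all_missing_feature_flagged_and_maps_to_zero():
    ds = _toy_dataset(n=20)
    ds.preop["c0"] = np.nan
    state = fit_preprocessor(ds)
    st = state.continuous["c0"]
    assert st.all_missing
    vals, flags = impute(np.array([np.nan, np.nan]), st)
    assert (vals == 0).all() and (flags == 0).all()
    assert (standardize(vals, st) == 0).all()


# ------------------------------------------------------------- transforms


def test_winsorize_tails_identity_region_and_determinism():
    st = ContinuousStats(p05=0.5, p1=1, p5=5, p95=95, p99=99, p995=99.5,
                         median=50, mean=50, sd=10)
    vals = np.array([0.2, 50.0, 120.0, np.nan])
    a = winsorize(vals, st, np.random.default_rng(7))
    b = winsorize(vals, st, np.random.default_rng(7))
    np.testing.assert_array_equal(a, b)  # seeded determinism
    assert 0.5 <= a[0] <= 5.0       # low tail -> Uniform(p0.5, p5)
    assert a[1] == 50.0             # in-range untouched
    assert 95.0 <= a[2] <= 99.5     # high tail -> Uniform(p95, p99.5)
    assert np.isnan(a[3])           # missing marks pass through


def test_impute_rule_and_presence_flags():
    st = ContinuousStats(0, 0, 0, 0, 0, 0, median=2.0, mean=0, sd=1)
    vals, flags = impute(np.array([1.0, 2.0, np.nan, 4.0]), st)
    np.testing.assert_array_equal(vals, [1, 2, 2, 4])
    np.testing.assert_array_equal(flags, [1, 1, 0, 1])
    vals, flags = impute(np.array([1.0, 2.0]), st)
    np.testing.assert_array_equal(flags, [1, 1])


def test_categorical_missing_and_unseen_map_to_missing_index():
    mapping = {0: 0, 2: 1, 5: 2}
    out = encode_categorical(np.array([0.0, 2.0, np.nan, 7.0, 5.0]), mapping)
    np.testing.assert_array_equal(out, [0, 1, 3, 3, 2])


def test_standardize_arithmetic_and_self_normalization():
    st = ContinuousStats(0, 0, 0, 0, 0, 0, median=0, mean=5.0, sd=2.0)
    assert standardize(np.array([9.0]), st)[0] == 2.0
    rng = np.random.default_rng(3)
    x = rng.standard_normal(500) * 4 + 7
    st2 = ContinuousStats(0, 0, 0, 0, 0, 0, median=0, mean=float(x.mean()), sd=float(x.std()))
    z = standardize(x, st2)
    assert z.mean() == pytest.approx(0, abs=1e-12)
    assert z.std() == pytest.approx(1, abs=1e-12)
    st0 = ContinuousStats(0, 0, 0, 0, 0, 0, median=0, mean=1.0, sd=0.0)
    assert (standardize(x, st0) == 0).all()


# ------------------------------------------------------------ time series


def _state_with_channel(median=42.0):
    return PreprocessorState(
        continuous={}, category_maps={},
        channels={"hr": ChannelStats(median=median, mean=0.0, sd=1.0)},
        median_duration=5, fitted_on="T",
    )


def test_resample_linear_interpolation_midpoint():
    state = _state_with_channel()
    vals, pres = resample_timeseries({"hr": (np.array([0, 2]), np.array([10.0, 14.0]))},
                                     state, ("hr",))
    assert vals[0, 1] == 12.0
    np.testing.assert_array_equal(pres[0], [1, 0, 1])


def test_resample_empty_channel_gets_training_median():
    state = _state_with_channel(median=42.0)
    vals, pres = resample_timeseries({}, state, ("hr",))
    assert vals.shape == (1, 5)  # training median duration
    assert (vals == 42.0).all() and (pres == 0).all()


def test_resample_within_minute_mean_matches_bin_oracle():
    rng = np.random.default_rng(8)
    times = np.sort(rng.uniform(0, 10, 40))
    values = rng.standard_normal(40)
    state = _state_with_channel()
    vals, pres = resample_timeseries({"hr": (times, values)}, state, ("hr",))
    bins = np.floor(times).astype(int)
    for b in np.unique(bins):
        assert vals[0, b] == pytest.approx(values[bins == b].mean(), rel=1e-12)
        assert pres[0, b] == 1


def test_resample_edges_fill_nearest_and_negative_times_error():
    state = _state_with_channel()
    vals, _ = resample_timeseries({"hr": (np.array([2, 3]), np.array([5.0, 7.0]))},
                                  state, ("hr",))
    assert vals[0, 0] == vals[0, 1] == 5.0  # leading gap: nearest observation
    with pytest.raises(ValueError):
        resample_timeseries({"hr": (np.array([-1.0]), np.array([1.0]))}, state, ("hr",))


# ------------------------------------------------------------- invariants


def test_no_leakage_statistics_ignore_val_and_test(small_cohort):
    split = chronological_split(small_cohort)
    state_a = fit_preprocessor(small_cohort.subset(split.train_ids))
    mutated = SiteDataset(small_cohort.site_id, small_cohort.preop.copy(), small_cohort.schema)
    in_test = mutated.preop["surgery_id"].isin(split.test_ids + split.val_ids)
    for name in mutated.schema.continuous:
        mutated.preop.loc[in_test, name] = 1e9
    state_b = fit_preprocessor(mutated.subset(split.train_ids))
    assert state_a.to_json() == state_b.to_json()


def test_transform_bounds_flags_and_full_pipeline(small_cohort, small_prepared):
    designs, split, state = small_prepared
    train = designs["train"]
    for j, name in enumerate(small_cohort.schema.continuous):
        st = state.continuous[name]
        raw = train.x_cont[:, j] * st.sd + st.mean  # undo standardization
        observed = train.f_cont[:, j] == 1
        assert raw[observed].min() >= st.p05 - 1e-9
        assert raw[observed].max() <= st.p995 + 1e-9
    # presence flag is 0 exactly where the raw input was missing
    sub = small_cohort.subset(split.train_ids).preop
    for j, name in enumerate(small_cohort.schema.continuous):
        np.testing.assert_array_equal(
            train.f_cont[:, j], sub[name].notna().to_numpy().astype(float)
        )


def test_pooled_preprocessing_equals_local_on_identical_sites(small_cohort):
    twin = SiteDataset("T2", small_cohort.preop.copy(), small_cohort.schema)
    split = chronological_split(small_cohort)
    local_state = fit_preprocessor(small_cohort.subset(split.train_ids))
    pooled = pool_datasets([small_cohort, twin])
    pooled_split = chronological_split(pooled)
    pooled_state = fit_preprocessor(pooled.subset(pooled_split.train_ids))
    for name in small_cohort.schema.continuous:
        a, b = local_state.continuous[name], pooled_state.continuous[name]
        assert a.median == pytest.approx(b.median, rel=1e-9)
        assert a.mean == pytest.approx(b.mean, rel=1e-9)


def test_preprocessor_state_json_roundtrip(small_prepared):
    _, _, state = small_prepared
    back = PreprocessorState.from_json(state.to_json())
    assert back.to_json() == state.to_json()
    assert back.percentile_method == "linear"
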