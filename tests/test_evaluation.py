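"""Metrics vs brute-force oracles, DeLong, bootstrap, subgroups, sensitivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from fedperiop.evaluation import (
    UndefinedMetricError,
    auprc,
    auroc,
    auroc_variance,
    bonferroni,
    bootstrap_ci,
    compare_models,
    delong_test,
    subgroup_eval,
    subgroup_labels,
    undersampling_sensitivity,
)
from fedperiop.federated import FedConfig
from fedperiop.model import ModelConfig
from fedperiop.synthetic import generate_multisite_cohort, gnv_like, jax_like


def pairwise_auroc(scores, labels):
    """Exhaustive oracle: mean over all (pos, neg) pairs with half-credit ties."""
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    return float(((pos > neg) + 0.5 * (pos == neg)).mean())


def sweep_auprc(scores, labels):
    """Exhaustive oracle: precision/recall at every distinct threshold."""
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for thr in sorted(set(scores), reverse=True):
        sel = scores >= thr
        tp = int(labels[sel].sum())
        precision = tp / sel.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def _random_instance(rng, n_max=200, ties=True):
    n = int(rng.integers(10, n_max))
    scores = rng.random(n)
    if ties and rng.random() < 0.5:
        scores = np.round(scores, 1)  # force ties
    labels = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
    if labels.sum() in (0, n):
        labels[0], labels[-1] = 0, 1
    return scores, labels


def test_auroc_worked_examples():
    assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75
    assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auroc([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1]) == 0.5
    with pytest.raises(UndefinedMetricError):
        auroc([0.1, 0.2], [1, 1])


def test_auroc_matches_pairwise_oracle_and_sklearn():
    rng = np.random.default_rng(42)
    for _ in range(300):
        scores, labels = _random_instance(rng)
        ours = auroc(scores, labels)
        assert ours == pytest.approx(pairwise_auroc(scores, labels), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_auprc_worked_examples():
    assert auprc([0.3, 0.6, 0.9], [1, 1, 1]) == 1.0
    assert auprc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auprc([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(0.5 + 0.5 * 2 / 3)
    with pytest.raises(UndefinedMetricError):
        auprc([0.1, 0.2], [0, 0])


def test_auprc_matches_threshold_sweep_oracle_and_sklearn():
    rng = np.random.default_rng(43)
    for _ in range(300):
        scores, labels = _random_instance(rng)
        ours = auprc(scores, labels)
        assert ours == pytest.approx(sweep_auprc(scores, labels), abs=1e-12)
        assert ours == pytest.approx(average_precision_score(labels, scores), abs=1e-12)


# ---------------------------------------------------------------- bootstrap


def test_bootstrap_degenerate_metric_gives_point_interval():
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([0, 0, 1, 1])
    lo, hi = bootstrap_ci(auroc, scores, labels, n_boot=50, rng=np.random.default_rng(0))
    assert lo == hi == 1.0


def test_bootstrap_is_seeded_and_stratified():
    rng = np.random.default_rng(3)
    scores, labels = _random_instance(rng, n_max=100)
    a = bootstrap_ci(auroc, scores, labels, n_boot=100, rng=np.random.default_rng(5))
    b = bootstrap_ci(auroc, scores, labels, n_boot=100, rng=np.random.default_rng(5))
    assert a == b
    # stratification keeps the metric defined even with a single positive
    few = np.array([0.9, 0.1, 0.2, 0.3, 0.8])
    ylab = np.array([1, 0, 0, 0, 0])
    lo, hi = bootstrap_ci(auroc, few, ylab, n_boot=200, rng=np.random.default_rng(1))
    assert 0.0 <= lo <= hi <= 1.0


def test_bootstrap_interval_width_shrinks_with_sample_size():
    rng = np.random.default_rng(7)

    def width(n):
        widths = []
        for _ in range(10):
            pos = rng.normal(1.0, 1, n // 2)
            neg = rng.normal(0.0, 1, n - n // 2)
            scores = np.concatenate([pos, neg])
            labels = np.repeat([1, 0], [n // 2, n - n // 2])
            lo, hi = bootstrap_ci(auroc, scores, labels, n_boot=200, rng=rng)
            widths.append(hi - lo)
        return np.median(widths)

    assert width(2000) < width(200)


# ------------------------------------------------------------------ DeLong


def jackknife_variance(scores, labels):
    """Grouped delete-one jackknife: within-class pseudovalue variance with
    the (m-1)/m convention per class, summed over classes."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    total = 0.0
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        m = idx.size
        thetas = []
        for i in idx:
            keep = np.ones(labels.size, bool)
            keep[i] = False
            thetas.append(auroc(scores[keep], labels[keep]))
        thetas = np.array(thetas)
        total += (m - 1) / m * ((thetas - thetas.mean()) ** 2).sum()
    return total


def test_delong_single_model_variance_equals_jackknife_oracle():
    rng = np.random.default_rng(9)
    for _ in range(25):
        scores, labels = _random_instance(rng, n_max=50)
        assert auroc_variance(scores, labels) == pytest.approx(
            jackknife_variance(scores, labels), abs=1e-10
        )


def test_delong_identical_models_and_variance_nonnegative():
    rng = np.random.default_rng(10)
    scores, labels = _random_instance(rng, n_max=100)
    delta, var, p = delong_test(scores, scores, labels)
    assert delta == 0.0 and p == 1.0
    for _ in range(50):
        a, labels = _random_instance(rng, n_max=80)
        b = a + rng.normal(0, 0.1, a.size)
        _, var, p = delong_test(a, b, labels)
        assert var >= 0.0
        assert 0.0 <= p <= 1.0


def test_delong_p_decreases_as_separation_grows():
    rng = np.random.default_rng(11)
    n = 300
    labels = np.repeat([1, 0], [100, 200])
    base = rng.normal(0, 1, n)
    noise = rng.normal(0, 1, n)
    ps = []
    for shift in (0.1, 0.5, 1.0, 2.0):
        a = base + shift * labels  # model A improves with shift
        b = base + 0.05 * labels + 0.5 * noise
        _, _, p = delong_test(a, b, labels)
        ps.append(p)
    assert all(x >= y - 1e-12 for x, y in zip(ps, ps[1:]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(p=st.floats(0, 1), m=st.integers(1, 40))
def test_bonferroni_properties(p, m):
    adj = bonferroni(p, m)
    assert adj >= p
    assert adj <= 1.0
    if m * p >= 1:
        assert adj == 1.0


def test_compare_models_family_size_and_adjustment(small_prepared):
    rng = np.random.default_rng(12)
    n = 400
    y = (rng.random((n, 9)) < 0.2).astype(float)
    y[0] = 1  # ensure both classes everywhere
    preds = {"a": rng.random((n, 9)), "b": rng.random((n, 9))}
    table = compare_models(preds, y, [("a", "b")])
    assert len(table) == 9
    assert (table["family_size"] == 9).all()
    assert (table["p_adjusted"] >= table["p_raw"] - 1e-15).all()


# --------------------------------------------------------------- subgroups


def test_subgroups_partition_cohort_and_age_rule():
    attrs = pd.DataFrame(
        {
            "sex": ["male", "female"] * 50,
            "race": ["white", "african_american", "other", "missing"] * 25,
            "age": np.r_[np.full(50, 65), np.full(50, 66)],
            "surgery_type": ["general", "cardiothoracic"] * 50,
        }
    )
    labels = subgroup_labels(attrs, "age")
    assert (labels[:50] == "<=65").all() and (labels[50:] == ">65").all()
    race = subgroup_labels(attrs, "race")
    assert set(race) == {"african_american", "non_african_american"}
    rng = np.random.default_rng(13)
    probs = rng.random((100, 9))
    y = (rng.random((100, 9)) < 0.3).astype(float)
    for grouping in ("sex", "race", "age", "surgery_type"):
        table = subgroup_eval(probs, y, attrs, grouping, n_boot=20,
                              rng=np.random.default_rng(0))
        sizes = table.groupby("subgroup")["n"].first()
        assert sizes.sum() == 100  # union of subgroups = cohort
    with pytest.raises(KeyError):
        subgroup_labels(attrs, "insurance")


def test_single_class_subgroup_flagged_undefined():
    attrs = pd.DataFrame(
        {"sex": ["male"] * 5 + ["female"] * 5, "race": ["white"] * 10,
         "age": [50] * 10, "surgery_type": ["general"] * 10}
    )
    probs = np.random.default_rng(0).random((10, 9))
    y = np.zeros((10, 9))
    y[5:, :] = 1  # males all-negative, females all-positive
    table = subgroup_eval(probs, y, attrs, "sex", n_boot=10)
    assert not table["defined"].any()
    assert table["auroc"].isna().all()


# ------------------------------------------------------------- sensitivity


def test_undersampling_has_exact_repeat_rows_and_equalized_sizes():
    datasets = generate_multisite_cohort([gnv_like(400), jax_like(150)], seed=19)
    mc = ModelConfig(cont_width=4, bin_width=3, embed_dim=2, hc_width=3,
                     fusion_width=4, final_width=4)
    fed = FedConfig("fedavg", rounds=1, seed=19)
    table = undersampling_sensitivity(datasets, mc, fed, seed=19, repeats=10)
    assert len(table) == 10 * 2
    assert (table.groupby("repeat").size() == 2).all()
    per_repeat = table.groupby("repeat")["n_train"].nunique()
    assert (per_repeat == 1).all()  # both clients equal n_k after undersampling
    summary = table.attrs["summary"]
    assert set(summary["site"]) == {"GNV", "JAX"}
    # seeded determinism: identical subsample draws and results
    again = undersampling_sensitivity(datasets, mc, fed, seed=19, repeats=10)
    pd.testing.assert_frame_equal(table, again)
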