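"""Discrimination metrics and statistical comparisons.

AUROC is the Mann-Whitney statistic (ties get half credit), computed via
midranks.  AUPRC is average precision: the step-wise sum of precision times
recall increments over descending score thresholds, with tied scores
processed as one threshold group.  Confidence intervals come from a
class-stratified percentile bootstrap (default B = 1000); AUROC differences
of paired models are tested with DeLong's structural-components estimator,
and families of p-values are Bonferroni-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._seeding import stage_rng
from .datatypes import N_OUTCOMES, OUTCOMES


class UndefinedMetricError(ValueError):
    """Raised when a metric's preconditions (both classes present, at least
    one positive) are not met."""


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    return scores, labels.astype(np.int64)


def auroc(scores, labels) -> float:
    """P(score_pos > score_neg) + 1/2 P(tie) over all positive-negative pairs."""
    scores, labels = _check(scores, labels)
    m = int(labels.sum())
    n = labels.size - m
    if m == 0 or n == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def auprc(scores, labels) -> float:
    """Average precision over descending-score threshold groups."""
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AUPRC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # threshold groups: runs of tied scores processed together
    boundary = np.flatnonzero(np.diff(s)) + 1
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    ends = np.append(boundary - 1, y.size - 1)  # last index of each group
    tp_g, fp_g = tp[ends], fp[ends]
    precision = tp_g / (tp_g + fp_g)
    recall = tp_g / n_pos
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * precision))


def mean_auroc(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean AUROC over the outcomes with both classes present (nan if none)."""
    vals = []
    for k in range(probs.shape[1]):
        col = y[:, k]
        if 0 < col.sum() < col.size:
            vals.append(auroc(probs[:, k], col))
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------- bootstrap


@dataclass
class MetricResult:
    outcome: str
    metric: str
    point: float
    ci_low: float
    ci_high: float
    n_bootstrap: int = 1000


def bootstrap_ci(
    metric_fn,
    scores,
    labels,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Class-stratified percentile bootstrap interval.

    Resampling within each class preserves the class counts, so the metric
    is defined on every resample.
    """
    scores, labels = _check(scores, labels)
    rng = rng if rng is not None else np.random.default_rng()
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        stats[b] = metric_fn(scores[idx], labels[idx])
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def metric_with_ci(
    metric_fn, scores, labels, outcome: str, metric_name: str,
    n_boot: int = 1000, rng: np.random.Generator | None = None,
) -> MetricResult:
    point = metric_fn(scores, labels)
    lo, hi = bootstrap_ci(metric_fn, scores, labels, n_boot=n_boot, rng=rng)
    return MetricResult(outcome, metric_name, float(point), lo, hi, n_boot)


# ------------------------------------------------------------------ DeLong


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos, neg = scores[labels == 1], scores[labels == 0]
    m, n = pos.size, neg.size
    tx = rankdata(pos)
    ty = rankdata(neg)
    tz = rankdata(np.concatenate([pos, neg]))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    theta = float(v10.mean())
    return v10, v01, theta


def auroc_variance(scores, labels) -> float:
    """DeLong variance of a single AUROC: S10/m + S01/n."""
    scores, labels = _check(scores, labels)
    v10, v01, _ = _delong_components(scores, labels)
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return float(s10 / v10.size + s01 / v01.size)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Paired DeLong test; returns (AUROC_a - AUROC_b, variance, two-sided p)."""
    scores_a, labels = _check(scores_a, labels)
    scores_b, _ = _check(scores_b, labels)
    if labels.sum() in (0, labels.size):
        raise UndefinedMetricError("DeLong test needs both classes present")
    va10, va01, ta = _delong_components(scores_a, labels)
    vb10, vb01, tb = _delong_components(scores_b, labels)
    m, n = va10.size, va01.size
    s10 = np.cov(np.stack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    delta = ta - tb
    if var <= 0:
        return float(delta), float(max(var, 0.0)), 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return float(delta), float(var), p


def bonferroni(p_raw: float, m: int) -> float:
    """Family-wise adjustment: min(1, m * p)."""
    if not (0.0 <= p_raw <= 1.0) or m < 1:
        raise ValueError("need p in [0,1] and family size >= 1")
    return min(1.0, m * p_raw)


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    outcome: str
    delta_auroc: float
    p_raw: float
    p_adjusted: float
    family_size: int


def compare_models(
    preds: dict[str, np.ndarray],
    y: np.ndarray,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """DeLong comparisons for the given model pairs over all nine outcomes;
    Bonferroni family = all comparisons in this table."""
    rows = []
    family = 0
    for a, b in pairs:
        for k, outcome in enumerate(OUTCOMES):
            col = y[:, k]
            if 0 < col.sum() < col.size:
                family += 1
    for a, b in pairs:
        for k, outcome in enumerate(OUTCOMES):
            col = y[:, k]
            if not (0 < col.sum() < col.size):
                continue
            delta, _, p = delong_test(preds[a][:, k], preds[b][:, k], col)
            rows.append(
                ComparisonResult(a, b, outcome, delta, p, bonferroni(p, family), family)
            )
    return pd.DataFrame([vars(r) for r in rows])


# --------------------------------------------------------------- subgroups


def subgroup_labels(attrs: pd.DataFrame, grouping: str) -> pd.Series:
    """Partition labels for one grouping; age 65 exactly falls in '<=65'."""
    if grouping == "sex":
        return attrs["sex"].astype(str)
    if grouping == "race":
        return pd.Series(
            np.where(
                attrs["race"].astype(str) == "african_american",
                "african_american",
                "non_african_american",
            ),
            index=attrs.index,
        )
    if grouping == "age":
        return pd.Series(
            np.where(attrs["age"] <= 65, "<=65", ">65"), index=attrs.index
        )
    if grouping == "surgery_type":
        return attrs["surgery_type"].astype(str)
    raise KeyError(f"unknown grouping {grouping!r}")


def subgroup_eval(
    probs: np.ndarray,
    y: np.ndarray,
    attrs: pd.DataFrame,
    grouping: str,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-subgroup AUROC/AUPRC with bootstrap CIs.

    Subgroups partition the cohort; single-class subgroups are reported with
    ``defined=False`` rather than dropped.
    """
    groups = subgroup_labels(attrs, grouping)
    rows = []
    for level in sorted(groups.unique()):
        idx = np.flatnonzero((groups == level).to_numpy())
        for k, outcome in enumerate(OUTCOMES):
            col = y[idx, k]
            defined = 0 < col.sum() < col.size
            row = {
                "grouping": grouping, "subgroup": level, "n": idx.size,
                "outcome": outcome, "defined": bool(defined),
                "auroc": np.nan, "auroc_lo": np.nan, "auroc_hi": np.nan,
                "auprc": np.nan, "auprc_lo": np.nan, "auprc_hi": np.nan,
            }
            if defined:
                s = probs[idx, k]
                row["auroc"] = auroc(s, col)
                row["auroc_lo"], row["auroc_hi"] = bootstrap_ci(
                    auroc, s, col, n_boot=n_boot, rng=rng
                )
                row["auprc"] = auprc(s, col)
                row["auprc_lo"], row["auprc_hi"] = bootstrap_ci(
                    auprc, s, col, n_boot=n_boot, rng=rng
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------- undersampling sensitivity


def undersampling_sensitivity(
    datasets,
    model_config,
    fed_config,
    seed: int,
    repeats: int = 10,
    fractions=(0.63, 0.07, 0.30),
) -> pd.DataFrame:
    """Equalize client training sizes by undersampling the larger site.

    Each repeat draws, without replacement, a subset of the larger site's
    training cohort equal in size to the smaller site's, retrains the
    federated model, and evaluates the test AUROC (mean over outcomes) at
    both sites.  Returns ``repeats`` rows per site plus a mean +- sd summary.
    """
    from .federated import run_federated  # deferred: avoids an import cycle
    from .model import predict
    from .training import prepare_site

    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    prepared = [prepare_site(d, seed, fractions)[0] for d in datasets]
    sizes = [p["train"].n for p in prepared]
    big = int(np.argmax(sizes))
    target = min(sizes)
    if sizes[big] == target:
        import warnings

        warnings.warn("sites already equal-sized; undersampling is a no-op")
    schema = datasets[0].schema
    rows = []
    for r in range(repeats):
        rng = stage_rng(seed, "undersample", r)
        designs = []
        for i, p in enumerate(prepared):
            train = p["train"]
            if i == big and train.n > target:
                keep = np.sort(rng.choice(train.n, size=target, replace=False))
                train = train.take(keep)
            designs.append((train, p["val"]))
        params, _ = run_federated(designs, model_config, fed_config, schema)
        for i, (d, p) in enumerate(zip(datasets, prepared)):
            probs = predict(params, p["test"], model_config)
            rows.append(
                {
                    "repeat": r, "site": d.site_id, "n_train": designs[i][0].n,
                    "test_auroc": mean_auroc(probs, p["test"].y),
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("site")["test_auroc"].agg(["mean", "std"]).reset_index()
    )
    table.attrs["summary"] = summary
    return table
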