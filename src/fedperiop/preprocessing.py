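"""Preprocessing stack fitted on training data only.

Pipeline, applied per site (local / federated) or on pooled data (central):

1. chronological 63/7/30 train/validation/test split on surgery dates, with
   every patient assigned wholly to the cohort containing their earliest
   surgery;
2. tail winsorization of continuous features: values outside the training
   [p1, p99] band are replaced by uniform draws from [p0.5, p5] (low tail) or
   [p95, p99.5] (high tail);
3. imputation: missing continuous values take the training median and get a
   presence flag of 0; missing or unseen categorical levels map to a
   dedicated "missing" index;
4. intraoperative series are binned to a 1-minute grid (within-minute mean),
   linearly interpolated across interior gaps, nearest-filled at the edges,
   and replaced by the training median when a channel is entirely absent;
5. standardization of continuous features and channels by training mean/sd.

Every statistic lives in :class:`PreprocessorState` and depends only on the
training cohort — validation/test records never leak into it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import N_OUTCOMES, OUTCOMES, FeatureSchema, SiteDataset

DEFAULT_FRACTIONS = (0.63, 0.07, 0.30)

_PCTS = (0.5, 1.0, 5.0, 95.0, 99.0, 99.5)


@dataclass
class CohortSplit:
    """Disjoint train/validation/test surgery-id sets."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("cohorts must be disjoint")


def chronological_split(
    dataset: SiteDataset, fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
) -> CohortSplit:
    """Split by surgery start date at cumulative-fraction boundaries.

    Ties on date break by surgery_id (stable).  Each patient's records are
    all assigned to the cohort containing their earliest surgery, so cohort
    sizes can deviate from the nominal fractions by at most the patient
    multiplicity.
    """
    n = dataset.n_records
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    df = dataset.preop[["surgery_id", "patient_id", "surgery_date"]].copy()
    df = df.sort_values(["surgery_date", "surgery_id"], kind="stable").reset_index(drop=True)
    b1 = int(round(fractions[0] * n))
    b2 = int(round((fractions[0] + fractions[1]) * n))
    nominal = np.full(n, 2, dtype=np.int64)
    nominal[:b1] = 0
    nominal[b1:b2] = 1
    df["nominal"] = nominal
    # cohort of each patient's earliest (first-sorted) surgery
    patient_cohort = df.groupby("patient_id", sort=False)["nominal"].first()
    assigned = df["patient_id"].map(patient_cohort).to_numpy()
    ids = df["surgery_id"].to_numpy()
    return CohortSplit(
        train_ids=list(ids[assigned == 0]),
        val_ids=list(ids[assigned == 1]),
        test_ids=list(ids[assigned == 2]),
        fractions=tuple(fractions),
    )


# ----------------------------------------------------------------- fitting


@dataclass
class ContinuousStats:
    p05: float
    p1: float
    p5: float
    p95: float
    p99: float
    p995: float
    median: float
    mean: float
    sd: float
    all_missing: bool = False


@dataclass
class ChannelStats:
    median: float
    mean: float
    sd: float


@dataclass
class PreprocessorState:
    """Training-cohort statistics for every feature and channel.

    ``percentile_method`` records the convention (linear interpolation
    between order statistics, numpy default).
    """

    continuous: dict[str, ContinuousStats]
    category_maps: dict[str, dict[int, int]]  # raw level -> dense index
    channels: dict[str, ChannelStats]
    median_duration: int
    fitted_on: str
    percentile_method: str = "linear"

    def missing_index(self, feature: str) -> int:
        return len(self.category_maps[feature])

    # ------------------------------------------------------------- JSON I/O
    def to_json(self) -> str:
        return json.dumps(
            {
                "continuous": {k: vars(v) for k, v in self.continuous.items()},
                "category_maps": {
                    k: {str(lvl): idx for lvl, idx in m.items()}
                    for k, m in self.category_maps.items()
                },
                "channels": {k: vars(v) for k, v in self.channels.items()},
                "median_duration": self.median_duration,
                "fitted_on": self.fitted_on,
                "percentile_method": self.percentile_method,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PreprocessorState":
        d = json.loads(text)
        return cls(
            continuous={k: ContinuousStats(**v) for k, v in d["continuous"].items()},
            category_maps={
                k: {int(lvl): idx for lvl, idx in m.items()}
                for k, m in d["category_maps"].items()
            },
            channels={k: ChannelStats(**v) for k, v in d["channels"].items()},
            median_duration=d["median_duration"],
            fitted_on=d["fitted_on"],
            percentile_method=d["percentile_method"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PreprocessorState":
        return cls.from_json(Path(path).read_text())


def pool_datasets(datasets: list[SiteDataset], site_id: str = "pooled") -> SiteDataset:
    """Concatenate sites (canonical surgery_id sort) for central learning."""
    if not datasets:
        raise ValueError("no datasets to pool")
    schema = datasets[0].schema
    preop = pd.concat([d.preop for d in datasets], ignore_index=True)
    preop = preop.sort_values("surgery_id", kind="stable").reset_index(drop=True)
    intraop = None
    if all(d.intraop is not None for d in datasets):
        intraop = pd.concat([d.intraop for d in datasets], ignore_index=True)
        intraop = intraop.sort_values(
            ["surgery_id", "channel", "minute"], kind="stable"
        ).reset_index(drop=True)
    return SiteDataset(site_id, preop, schema, intraop)


def fit_preprocessor(train: SiteDataset) -> PreprocessorState:
    """Compute all statistics on the supplied training records only."""
    if train.n_records == 0:
        raise ValueError("training cohort is empty")
    schema = train.schema
    cont: dict[str, ContinuousStats] = {}
    for name in schema.continuous:
        vals = train.preop[name].to_numpy(dtype=float)
        obs = vals[np.isfinite(vals)]
        if obs.size == 0:
            cont[name] = ContinuousStats(*([0.0] * 9), all_missing=True)
            continue
        p = np.percentile(obs, _PCTS)  # linear interpolation between order stats
        cont[name] = ContinuousStats(
            p05=float(p[0]), p1=float(p[1]), p5=float(p[2]), p95=float(p[3]),
            p99=float(p[4]), p995=float(p[5]),
            median=float(np.median(obs)), mean=float(obs.mean()),
            sd=float(obs.std()),
        )

    maps: dict[str, dict[int, int]] = {}
    for name in schema.highcard:
        vals = train.preop[name].to_numpy(dtype=float)
        levels = np.unique(vals[np.isfinite(vals)]).astype(np.int64)
        maps[name] = {int(lvl): i for i, lvl in enumerate(levels)}

    chans: dict[str, ChannelStats] = {}
    median_duration = 60
    if train.intraop is not None and len(train.intraop):
        for channel in schema.channels:
            obs = train.intraop.loc[train.intraop["channel"] == channel, "value"].to_numpy()
            if obs.size:
                chans[channel] = ChannelStats(
                    median=float(np.median(obs)), mean=float(obs.mean()),
                    sd=float(obs.std()),
                )
            else:
                chans[channel] = ChannelStats(0.0, 0.0, 0.0)
        durations = train.intraop.groupby("surgery_id")["minute"].max() + 1
        median_duration = int(np.median(durations))
    return PreprocessorState(
        continuous=cont, category_maps=maps, channels=chans,
        median_duration=median_duration, fitted_on=train.site_id,
    )


# ------------------------------------------------------------- transforms


def winsorize(
    values: np.ndarray, stats: ContinuousStats, rng: np.random.Generator
) -> np.ndarray:
    """Replace tail outliers by uniform draws from the adjacent band.

    Values below the training p1 become Uniform(p0.5, p5); values above p99
    become Uniform(p95, p99.5).  In-range values and missing marks pass
    through unchanged.
    """
    out = np.asarray(values, dtype=float).copy()
    if stats.all_missing:
        return out
    finite = np.isfinite(out)
    low = finite & (out < stats.p1)
    high = finite & (out > stats.p99)
    out[low] = rng.uniform(stats.p05, stats.p5, size=int(low.sum()))
    out[high] = rng.uniform(stats.p95, stats.p995, size=int(high.sum()))
    return out


def impute(values: np.ndarray, stats: ContinuousStats) -> tuple[np.ndarray, np.ndarray]:
    """Median-impute missing continuous values; flags: 1 observed, 0 imputed."""
    out = np.asarray(values, dtype=float).copy()
    flags = np.isfinite(out).astype(np.float64)
    out[~np.isfinite(out)] = 0.0 if stats.all_missing else stats.median
    return out, flags


def standardize(values: np.ndarray, stats: ContinuousStats) -> np.ndarray:
    """(x - mean)/sd with training statistics; zero-variance features map to 0."""
    vals = np.asarray(values, dtype=float)
    if stats.all_missing or stats.sd == 0.0:
        return np.zeros_like(vals)
    return (vals - stats.mean) / stats.sd


def encode_categorical(values: np.ndarray, mapping: dict[int, int]) -> np.ndarray:
    """Map raw levels to dense indices; missing or unseen -> the missing index."""
    missing_idx = len(mapping)
    vals = np.asarray(values, dtype=float)
    out = np.full(vals.shape, missing_idx, dtype=np.int64)
    finite = np.isfinite(vals)
    lv = vals[finite].astype(np.int64)
    out[finite] = np.array([mapping.get(int(v), missing_idx) for v in lv], dtype=np.int64)
    return out


def resample_timeseries(
    channel_obs: dict[str, tuple[np.ndarray, np.ndarray]],
    state: PreprocessorState,
    channels: tuple[str, ...],
    duration: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Regularize one surgery's observations onto a 1-minute grid.

    ``channel_obs`` maps channel name to (times, values) in minutes from
    incision.  Returns (values, presence), each (C, T): within-minute
    observations are averaged into their bin, interior gaps are linearly
    interpolated between flanking bins, leading/trailing gaps take the
    nearest observed bin, and entirely absent channels are filled with the
    training median (presence 0 everywhere imputed).
    """
    for times, _ in channel_obs.values():
        if len(times) and np.min(times) < 0:
            raise ValueError("observation times must be nonnegative")
    if duration is None:
        tmax = max(
            (int(math.floor(np.max(t))) + 1 for t, _ in channel_obs.values() if len(t)),
            default=state.median_duration,
        )
    else:
        tmax = int(duration)
    C = len(channels)
    values = np.empty((C, tmax))
    presence = np.zeros((C, tmax))
    for c, channel in enumerate(channels):
        times, vals = channel_obs.get(channel, (np.array([]), np.array([])))
        if len(times) == 0:
            values[c] = state.channels[channel].median if channel in state.channels else 0.0
            continue
        bins = np.floor(np.asarray(times, dtype=float)).astype(np.int64)
        bins = np.minimum(bins, tmax - 1)
        sums = np.bincount(bins, weights=np.asarray(vals, dtype=float), minlength=tmax)
        counts = np.bincount(bins, minlength=tmax)
        observed = counts > 0
        grid_idx = np.flatnonzero(observed)
        binned = sums[grid_idx] / counts[grid_idx]
        # np.interp: linear inside, nearest (edge value) outside
        values[c] = np.interp(np.arange(tmax), grid_idx, binned)
        presence[c, grid_idx] = 1.0
    return values, presence


# --------------------------------------------------------------- design


@dataclass
class DesignMatrices:
    """Model-ready arrays for one cohort."""

    surgery_ids: np.ndarray
    x_cont: np.ndarray      # (B, nc) winsorized/imputed/standardized
    f_cont: np.ndarray      # (B, nc) presence flags
    x_bin: np.ndarray       # (B, nb)
    x_high: np.ndarray      # (B, nh) dense category indices
    y: np.ndarray           # (B, 9)
    attrs: pd.DataFrame     # subgroup attributes (sex, race, age, surgery type)
    series: np.ndarray | None = None       # (B, T, C) standardized grid
    series_presence: np.ndarray | None = None  # (B, T, C)
    series_mask: np.ndarray | None = None      # (B, T) valid-timestep mask

    @property
    def n(self) -> int:
        return len(self.surgery_ids)

    def take(self, idx: np.ndarray) -> "DesignMatrices":
        return DesignMatrices(
            surgery_ids=self.surgery_ids[idx],
            x_cont=self.x_cont[idx], f_cont=self.f_cont[idx],
            x_bin=self.x_bin[idx], x_high=self.x_high[idx], y=self.y[idx],
            attrs=self.attrs.iloc[idx].reset_index(drop=True),
            series=None if self.series is None else self.series[idx],
            series_presence=None
            if self.series_presence is None
            else self.series_presence[idx],
            series_mask=None if self.series_mask is None else self.series_mask[idx],
        )


def transform(
    dataset: SiteDataset,
    surgery_ids,
    state: PreprocessorState,
    rng: np.random.Generator,
    with_intraop: bool = False,
) -> DesignMatrices:
    """Apply the fitted preprocessing to a cohort and assemble model inputs."""
    sub = dataset.subset(surgery_ids)
    schema = dataset.schema
    df = sub.preop
    B = len(df)
    nc, nb, nh = len(schema.continuous), len(schema.binary), len(schema.highcard)

    x_cont = np.empty((B, nc))
    f_cont = np.empty((B, nc))
    for j, name in enumerate(schema.continuous):
        stats = state.continuous[name]
        vals = winsorize(df[name].to_numpy(dtype=float), stats, rng)
        vals, flags = impute(vals, stats)
        x_cont[:, j] = standardize(vals, stats)
        f_cont[:, j] = flags

    x_bin = np.nan_to_num(
        df[list(schema.binary)].to_numpy(dtype=float), nan=0.0
    )
    # columns in sorted-name order, matching the model's embedding ordering
    x_high = np.empty((B, nh), dtype=np.int64)
    for j, name in enumerate(sorted(schema.highcard)):
        x_high[:, j] = encode_categorical(df[name].to_numpy(), state.category_maps[name])

    y = sub.outcome_matrix().astype(np.float64)
    attrs = df[["sex", "race", "age", "surgery_type"]].reset_index(drop=True)

    series = presence = mask = None
    if with_intraop:
        if sub.intraop is None:
            raise ValueError("dataset has no intraoperative series")
        grids = []
        for sid in df["surgery_id"]:
            rec = sub.intraop[sub.intraop["surgery_id"] == sid]
            obs = {
                ch: (g["minute"].to_numpy(), g["value"].to_numpy())
                for ch, g in rec.groupby("channel")
            }
            grids.append(resample_timeseries(obs, state, schema.channels))
        tmax = max(g[0].shape[1] for g in grids)
        C = len(schema.channels)
        series = np.zeros((B, tmax, C))
        presence = np.zeros((B, tmax, C))
        mask = np.zeros((B, tmax))
        for i, (vals, pres) in enumerate(grids):
            T = vals.shape[1]
            for c, channel in enumerate(schema.channels):
                st = state.channels.get(channel)
                if st is not None and st.sd > 0:
                    vals[c] = (vals[c] - st.mean) / st.sd
            series[i, :T] = vals.T
            presence[i, :T] = pres.T
            mask[i, :T] = 1.0
    return DesignMatrices(
        surgery_ids=df["surgery_id"].to_numpy(),
        x_cont=x_cont, f_cont=f_cont, x_bin=x_bin, x_high=x_high, y=y,
        attrs=attrs, series=series, series_presence=presence, series_mask=mask,
    )
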