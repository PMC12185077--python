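"""Two-site synthetic perioperative cohort generator.

The generator emulates the statistical structure a two-hospital comparative
study of local / central / federated learning assumes, without any real
patient data:

* a shared low-dimensional latent severity vector ``z ~ N(0, I_L)`` per
  surgery drives both the observed preoperative features and the nine binary
  complication labels, giving the labels a learnable signal and mutual
  correlation;
* the two sites differ in feature means, binary rates, high-cardinality
  category popularity, outcome prevalence, and the missingness rate of the
  primary procedure code (5% at the large "GNV-like" site vs 36% at the
  smaller "JAX-like" site) — the non-IID ingredients of the study;
* outcome prevalence drifts linearly (on the logit scale) over calendar time,
  so chronological train/test splits face prevalence shift;
* intraoperative vitals are Gaussian AR(1) walks around per-channel baselines
  with per-minute observation gaps, weakly coupled to the latent vector.

Outcome intercepts are calibrated by quadrature so the *marginal* prevalence
of each label over a generated cohort (latent effect and temporal drift
integrated out) equals the configured rate, e.g. 29% prolonged ICU stay at
the GNV-like site and 24% at the JAX-like site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from ._seeding import stage_seed
from .datatypes import (
    DEFAULT_CHANNELS,
    N_OUTCOMES,
    OUTCOMES,
    SURGERY_TYPES,
    FeatureSchema,
    SiteDataset,
    default_schema,
)

#: Documented default seed for the reference cohorts (study start date).
DEFAULT_SEED = 20120101

#: Training-cohort complication prevalences at the two sites.
GNV_PREVALENCE = {
    "prolonged_icu": 0.29,
    "sepsis": 0.08,
    "cardiovascular": 0.12,
    "vte": 0.05,
    "prolonged_mv": 0.09,
    "neurological": 0.17,
    "wound": 0.16,
    "aki": 0.15,
    "mortality": 0.02,
}
JAX_PREVALENCE = {
    "prolonged_icu": 0.24,
    "sepsis": 0.09,
    "cardiovascular": 0.11,
    "vte": 0.04,
    "prolonged_mv": 0.08,
    "neurological": 0.12,
    "wound": 0.14,
    "aki": 0.14,
    "mortality": 0.02,
}

#: Primary procedure-code missing rates at the two sites.
GNV_PROCEDURE_MISSING = 0.05
JAX_PROCEDURE_MISSING = 0.36

LATENT_DIM = 6

# Outcome loading directions on the latent vector (rows: OUTCOMES order).
# Prolonged ICU stay and prolonged MV share latents 0-1, which also drive the
# procedure code, making that feature crucial for exactly those outcomes.
_OUTCOME_DIRECTIONS = np.array(
    [
        [1.0, 0.8, 0.2, 0.0, 0.3, 0.0],  # prolonged_icu
        [0.2, 0.0, 1.0, 0.5, 0.0, 0.3],  # sepsis
        [0.5, 0.2, 0.0, 1.0, 0.2, 0.0],  # cardiovascular
        [0.0, 0.5, 0.3, 0.0, 1.0, 0.2],  # vte
        [0.9, 1.0, 0.0, 0.2, 0.0, 0.3],  # prolonged_mv
        [0.4, 0.0, 0.6, 0.0, 0.2, 1.0],  # neurological
        [0.0, 0.3, 0.2, 0.6, 0.5, 0.4],  # wound
        [0.3, 0.4, 0.5, 0.3, 0.0, 0.6],  # aki
        [0.7, 0.6, 0.4, 0.3, 0.3, 0.3],  # mortality
    ]
)
# Latent-score scale per outcome; larger scale -> higher Bayes-optimal AUROC.
_OUTCOME_SCALES = np.array([3.0, 2.6, 1.6, 1.8, 3.0, 2.2, 1.4, 1.6, 3.0])


def default_outcome_coeffs() -> np.ndarray:
    """(9, L) coefficient matrix of the latent outcome model."""
    dirs = _OUTCOME_DIRECTIONS / np.linalg.norm(_OUTCOME_DIRECTIONS, axis=1, keepdims=True)
    return _OUTCOME_SCALES[:, None] * dirs


# ------------------------------------------------------------------ specs


@dataclass(frozen=True)
class FeatureSpec:
    """Per-feature generative parameters (all arrays in schema order)."""

    cont_mean: np.ndarray        # (nc,) site-specific feature means
    cont_loading: np.ndarray     # (nc,) loading on the assigned latent dim
    cont_latent: np.ndarray      # (nc,) int latent index
    cont_noise_sd: np.ndarray    # (nc,)
    bin_base: np.ndarray         # (nb,) base logits
    bin_coef: np.ndarray         # (nb,) latent coefficient
    bin_latent: np.ndarray       # (nb,) int latent index
    hc_probs: dict[str, np.ndarray]    # name -> category probabilities
    hc_weights: dict[str, np.ndarray]  # name -> latent weight vector (L,)
    hc_noise_sd: dict[str, float]      # name -> ordinal noise scale


@dataclass(frozen=True)
class ChannelSpec:
    """Intraoperative channel parameters: AR(1) around a baseline."""

    baseline: np.ndarray      # (C,)
    scale: np.ndarray         # (C,) innovation sd
    phi: float = 0.9          # autocorrelation
    latent_coupling: float = 0.5  # baseline shift per unit of latent 0, x scale
    gap_rate: float = 0.3     # per-minute probability a value is unobserved
    duration_minutes: tuple[int, int] = (45, 150)  # uniform surgery duration


def default_channel_spec(channels: tuple[str, ...] = DEFAULT_CHANNELS) -> ChannelSpec:
    base = {
        "sbp": (120.0, 6.0), "dbp": (70.0, 4.0), "map": (90.0, 5.0),
        "hr": (80.0, 4.0), "temp": (36.5, 0.15), "etco2": (35.0, 1.5),
        "spo2": (98.0, 0.7), "pip": (20.0, 1.5), "rr": (12.0, 1.0),
        "mac": (1.0, 0.08),
    }
    baseline = np.array([base.get(c, (0.0, 1.0))[0] for c in channels])
    scale = np.array([base.get(c, (0.0, 1.0))[1] for c in channels])
    return ChannelSpec(baseline=baseline, scale=scale)


def _default_feature_spec(schema: FeatureSchema, site: str) -> FeatureSpec:
    """Deterministic per-site feature parameters.

    The JAX-like site shifts continuous means by +-0.35 SD, binary logits by
    +-0.3, and mixes the category popularity of high-cardinality features
    with a uniform distribution — the "significantly different feature
    distributions" ingredient.
    """
    nc, nb = len(schema.continuous), len(schema.binary)
    j = np.arange(nc)
    cont_mean = np.zeros(nc)
    if site == "jax":
        cont_mean = 0.35 * np.where(j % 2 == 0, 1.0, -1.0)
    cont_loading = np.array([1.0, 0.7, 0.5])[j % 3]
    cont_latent = j % LATENT_DIM
    cont_noise_sd = np.ones(nc)

    k = np.arange(nb)
    bin_base = -1.0 + 0.1 * (k % 5)
    if site == "jax":
        bin_base = bin_base + 0.3 * np.where(k % 2 == 0, 1.0, -1.0)
    bin_coef = np.where(k % 2 == 0, 0.8, 0.4)
    bin_latent = (k + 1) % LATENT_DIM

    hc_probs: dict[str, np.ndarray] = {}
    hc_weights: dict[str, np.ndarray] = {}
    hc_noise: dict[str, float] = {}
    for i, (name, card) in enumerate(schema.highcard.items()):
        zipf = 1.0 / (np.arange(card) + 2.0)
        zipf /= zipf.sum()
        if site == "jax":
            probs = 0.5 * zipf + 0.5 * np.full(card, 1.0 / card)
        else:
            probs = zipf
        hc_probs[name] = probs
        w = np.zeros(LATENT_DIM)
        if name == "procedure_code":
            # strongly informative of latents 0-1 (the ICU/MV drivers)
            w[0], w[1] = 1.2, 1.0
            hc_noise[name] = 0.6
        else:
            w[(i + 2) % LATENT_DIM] = 0.4
            hc_noise[name] = 1.0
        hc_weights[name] = w
    return FeatureSpec(
        cont_mean=cont_mean, cont_loading=cont_loading, cont_latent=cont_latent,
        cont_noise_sd=cont_noise_sd, bin_base=bin_base, bin_coef=bin_coef,
        bin_latent=bin_latent, hc_probs=hc_probs, hc_weights=hc_weights,
        hc_noise_sd=hc_noise,
    )


def _default_missingness(schema: FeatureSchema, procedure_rate: float) -> dict[str, float]:
    rates = {"procedure_code": float(procedure_rate)}
    for j, name in enumerate(schema.continuous):
        if j % 4 == 0:
            rates[name] = 0.15
        elif j % 4 == 1:
            rates[name] = 0.05
    return rates


@dataclass(frozen=True)
class SiteConfig:
    """Full generative configuration for one site."""

    site_id: str
    n_surgeries: int
    n_patients: int
    schema: FeatureSchema
    feature_spec: FeatureSpec
    channel_spec: ChannelSpec
    outcome_intercepts: np.ndarray       # (9,) calibrated logit intercepts
    outcome_coeffs: np.ndarray           # (9, L) latent coefficients
    outcome_prevalence: np.ndarray       # (9,) target marginal prevalences
    missingness_rates: dict[str, float]  # feature name -> masking probability
    drift: np.ndarray                    # (9,) logit slope over normalized time
    date_range: tuple[str, str] = ("2012-01-01", "2021-05-01")
    latent_dim: int = LATENT_DIM
    include_intraop: bool = True
    demographics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.n_surgeries >= self.n_patients >= 1):
            raise ValueError(
                f"n_surgeries ({self.n_surgeries}) must be >= n_patients "
                f"({self.n_patients}) >= 1"
            )
        if self.n_surgeries > 3 * self.n_patients:
            raise ValueError("n_surgeries exceeds 3 admissions per patient")
        if self.outcome_intercepts.shape != (N_OUTCOMES,):
            raise ValueError("outcome_intercepts must have exactly 9 entries")
        if self.outcome_coeffs.shape != (N_OUTCOMES, self.latent_dim):
            raise ValueError(
                f"outcome_coeffs must be (9, {self.latent_dim}), "
                f"got {self.outcome_coeffs.shape}"
            )
        if self.drift.shape != (N_OUTCOMES,):
            raise ValueError("drift must have exactly 9 entries")
        for name, r in self.missingness_rates.items():
            if name not in self.schema.feature_names:
                raise KeyError(f"missingness rate for unknown feature {name!r}")
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"missingness_rates[{name!r}]={r} outside [0, 1]")
        for name, p in self.feature_spec.hc_probs.items():
            if abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
                raise ValueError(f"category probabilities of {name!r} must sum to 1")
        if ((self.outcome_prevalence <= 0) | (self.outcome_prevalence >= 1)).any():
            raise ValueError("outcome_prevalence entries must lie in (0, 1)")


# ------------------------------------------------------ intercept calibration

_GH_X, _GH_W = hermgauss(64)
_GL_X, _GL_W = leggauss(16)
_T_NODES = 0.5 * (_GL_X + 1.0)   # map [-1, 1] -> [0, 1]
_T_WEIGHTS = 0.5 * _GL_W


def marginal_prevalence(intercept: float, scale: float, slope: float) -> float:
    """E[sigmoid(b + s*Z + d*t)] with Z ~ N(0,1), t ~ U(0,1), by quadrature."""
    z = np.sqrt(2.0) * scale * _GH_X          # Gauss-Hermite for the normal
    grid = intercept + z[:, None] + slope * _T_NODES[None, :]
    vals = expit(grid)
    return float((_GH_W / np.sqrt(np.pi)) @ vals @ _T_WEIGHTS)


def calibrate_intercept(prevalence: float, scale: float, slope: float = 0.0) -> float:
    """Solve for the logit intercept giving the requested marginal prevalence."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence {prevalence} outside (0, 1)")
    return float(
        brentq(lambda b: marginal_prevalence(b, scale, slope) - prevalence, -40.0, 40.0)
    )


def calibrated_intercepts(
    prevalences: np.ndarray, coeffs: np.ndarray, drift: np.ndarray
) -> np.ndarray:
    scales = np.linalg.norm(coeffs, axis=1)
    return np.array(
        [
            calibrate_intercept(p, s, d)
            for p, s, d in zip(prevalences, scales, drift, strict=True)
        ]
    )


# -------------------------------------------------------------- site presets

_GNV_DRIFT = np.array([0.25, 0.10, 0.15, 0.20, 0.20, -0.20, -0.15, 0.10, 0.0])
_JAX_DRIFT = np.array([0.0, 0.0, 0.25, 0.25, 0.20, 0.0, 0.0, 0.0, 0.30])

_GNV_DEMOGRAPHICS = {
    "p_male": 0.50, "age_mean": 57.0, "age_sd": 17.0,
    "race_probs": {"white": 0.78, "african_american": 0.14, "other": 0.06, "missing": 0.02},
}
_JAX_DEMOGRAPHICS = {
    "p_male": 0.51, "age_mean": 52.0, "age_sd": 17.0,
    "race_probs": {"white": 0.59, "african_american": 0.35, "other": 0.06, "missing": 0.00},
}


def _make_config(
    site: str,
    site_id: str,
    n_surgeries: int,
    prevalence: dict[str, float],
    procedure_missing: float,
    drift: np.ndarray,
    demographics: dict,
    schema: FeatureSchema | None,
    include_intraop: bool,
) -> SiteConfig:
    schema = schema if schema is not None else default_schema()
    coeffs = default_outcome_coeffs()
    prev = np.array([prevalence[o] for o in OUTCOMES])
    intercepts = calibrated_intercepts(prev, coeffs, drift)
    # ~1.31 surgeries per patient, multiplicity capped at 3
    n_patients = max(1, int(round(n_surgeries / 1.31)))
    return SiteConfig(
        site_id=site_id,
        n_surgeries=n_surgeries,
        n_patients=n_patients,
        schema=schema,
        feature_spec=_default_feature_spec(schema, site),
        channel_spec=default_channel_spec(schema.channels),
        outcome_intercepts=intercepts,
        outcome_coeffs=coeffs,
        outcome_prevalence=prev,
        missingness_rates=_default_missingness(schema, procedure_missing),
        drift=drift.copy(),
        include_intraop=include_intraop,
        demographics=dict(demographics),
    )


def gnv_like(
    n_surgeries: int = 50_000,
    schema: FeatureSchema | None = None,
    include_intraop: bool = False,
) -> SiteConfig:
    """Default large-site configuration (29% prolonged ICU, 5% code missing)."""
    return _make_config(
        "gnv", "GNV", n_surgeries, GNV_PREVALENCE, GNV_PROCEDURE_MISSING,
        _GNV_DRIFT, _GNV_DEMOGRAPHICS, schema, include_intraop,
    )


def jax_like(
    n_surgeries: int = 18_000,
    schema: FeatureSchema | None = None,
    include_intraop: bool = False,
) -> SiteConfig:
    """Default small-site configuration (24% prolonged ICU, 36% code missing)."""
    return _make_config(
        "jax", "JAX", n_surgeries, JAX_PREVALENCE, JAX_PROCEDURE_MISSING,
        _JAX_DRIFT, _JAX_DEMOGRAPHICS, schema, include_intraop,
    )


# ----------------------------------------------------------------- sampling


def sample_outcomes(
    latent_features: np.ndarray,
    intercepts: np.ndarray,
    coeffs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the nine labels: y_k ~ Bernoulli(sigmoid(b_k + c_k . z)).

    ``latent_features`` may be a single (L,) vector or an (n, L) matrix; the
    nine outcomes of one record share the latent vector, which induces their
    correlation.  Returns {0,1} with shape (9,) or (n, 9).
    """
    z = np.atleast_2d(np.asarray(latent_features, dtype=float))
    intercepts = np.asarray(intercepts, dtype=float)
    coeffs = np.asarray(coeffs, dtype=float)
    if not (np.isfinite(z).all() and np.isfinite(intercepts).all() and np.isfinite(coeffs).all()):
        raise ValueError("non-finite inputs to sample_outcomes")
    if coeffs.shape[1] != z.shape[1]:
        raise ValueError(
            f"coeffs dim {coeffs.shape[1]} not conformable with latent dim {z.shape[1]}"
        )
    logits = intercepts[None, :] + z @ coeffs.T
    y = (rng.random(logits.shape) < expit(logits)).astype(np.int8)
    return y[0] if np.asarray(latent_features).ndim == 1 else y


def inject_missingness(
    dataset: SiteDataset, rates: dict[str, float], rng: np.random.Generator
) -> SiteDataset:
    """Mask each targeted feature value independently with its rate.

    Outcome labels are never masked; record count is unchanged.
    """
    preop = dataset.preop.copy()
    for name, rate in rates.items():
        if name not in dataset.schema.feature_names:
            raise KeyError(f"missingness rate for unknown feature {name!r}")
        if rate == 0.0:
            continue
        mask = rng.random(len(preop)) < rate
        col = preop[name].astype(float)
        col[mask] = np.nan
        preop[name] = col
    return SiteDataset(dataset.site_id, preop, dataset.schema, dataset.intraop)


def apply_temporal_drift(
    dataset: SiteDataset, drift: np.ndarray, rng: np.random.Generator
) -> SiteDataset:
    """Resample outcomes with logit eta_k + slope_k * t, t = normalized date.

    ``eta_k`` (intercept + latent score) is carried by the generator in the
    ``_eta_*`` columns.  Outcomes with slope exactly 0 are left untouched, so
    zero drift is the identity.
    """
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (N_OUTCOMES,):
        raise ValueError("drift must have exactly 9 entries")
    preop = dataset.preop.copy()
    t = preop["_t"].to_numpy()
    for k, name in enumerate(OUTCOMES):
        if drift[k] == 0.0:
            continue
        eta = preop[f"_eta_{name}"].to_numpy()
        p = expit(eta + drift[k] * t)
        preop[f"y_{name}"] = (rng.random(len(preop)) < p).astype(np.int8)
    return SiteDataset(dataset.site_id, preop, dataset.schema, dataset.intraop)


def _sample_patients(config: SiteConfig, rng: np.random.Generator) -> np.ndarray:
    """Assign surgeries to patients; each patient gets 1-3 admissions."""
    n, m = config.n_surgeries, config.n_patients
    counts = np.ones(m, dtype=np.int64)
    extra = n - m
    while extra > 0:
        room = np.flatnonzero(counts < 3)
        take = room if len(room) <= extra else rng.choice(room, size=extra, replace=False)
        counts[take] += 1
        extra = n - counts.sum()
    pid = np.repeat(np.arange(m), counts)
    return rng.permutation(pid)


def _sample_intraop(
    config: SiteConfig, z: np.ndarray, surgery_ids: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """AR(1) vitals at 1-minute cadence with per-minute observation gaps."""
    cs = config.channel_spec
    n = len(surgery_ids)
    lo, hi = cs.duration_minutes
    durations = rng.integers(lo, hi + 1, size=n)
    tmax = int(durations.max())
    frames = []
    for c, channel in enumerate(config.schema.channels):
        base = cs.baseline[c] + cs.latent_coupling * cs.scale[c] * z[:, 0]
        x = base + cs.scale[c] * rng.standard_normal(n)
        vals = np.empty((n, tmax))
        for t in range(tmax):
            if t > 0:
                x = base + cs.phi * (x - base) + cs.scale[c] * rng.standard_normal(n)
            vals[:, t] = x
        observed = rng.random((n, tmax)) >= cs.gap_rate
        observed &= np.arange(tmax)[None, :] < durations[:, None]
        rec_idx, minute = np.nonzero(observed)
        frames.append(
            pd.DataFrame(
                {
                    "surgery_id": surgery_ids[rec_idx],
                    "channel": channel,
                    "minute": minute.astype(np.int64),
                    "value": np.round(vals[rec_idx, minute], 4),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["surgery_id", "channel", "minute"], kind="stable").reset_index(
        drop=True
    )


def generate_site(config: SiteConfig, seed_seq: np.random.SeedSequence) -> SiteDataset:
    """Generate one site's cohort; fully determined by (config, seed_seq)."""
    rng = np.random.default_rng(seed_seq)
    n, L = config.n_surgeries, config.latent_dim
    fs = config.feature_spec
    schema = config.schema

    patient_idx = _sample_patients(config, rng)
    surgery_ids = np.array([f"{config.site_id}-S{i:06d}" for i in range(n)])
    patient_ids = np.array([f"{config.site_id}-P{i:06d}" for i in patient_idx])

    start = pd.Timestamp(config.date_range[0])
    end = pd.Timestamp(config.date_range[1])
    span_days = (end - start).days
    day_offsets = rng.integers(0, span_days + 1, size=n)
    dates = start + pd.to_timedelta(day_offsets, unit="D")
    t_norm = day_offsets / span_days

    z = rng.standard_normal((n, L))

    data: dict[str, np.ndarray] = {
        "patient_id": patient_ids,
        "surgery_id": surgery_ids,
        "surgery_date": dates,
    }

    demo = config.demographics or _GNV_DEMOGRAPHICS
    data["sex"] = np.where(rng.random(n) < demo["p_male"], "male", "female")
    races = list(demo["race_probs"])
    race_p = np.array([demo["race_probs"][r] for r in races])
    data["race"] = rng.choice(races, size=n, p=race_p / race_p.sum())
    age = demo["age_mean"] + demo["age_sd"] * (
        0.5 * z[:, 0] + np.sqrt(0.75) * rng.standard_normal(n)
    )
    data["age"] = np.clip(np.round(age), 18, 95).astype(np.int64)
    data["surgery_type"] = rng.choice(
        SURGERY_TYPES, size=n, p=[0.15, 0.35, 0.15, 0.2, 0.15]
    )

    for j, name in enumerate(schema.continuous):
        data[name] = np.round(
            fs.cont_mean[j]
            + fs.cont_loading[j] * z[:, fs.cont_latent[j]]
            + fs.cont_noise_sd[j] * rng.standard_normal(n),
            4,
        )
    for k, name in enumerate(schema.binary):
        p = expit(fs.bin_base[k] + fs.bin_coef[k] * z[:, fs.bin_latent[k]])
        data[name] = (rng.random(n) < p).astype(np.int8)
    for name, card in schema.highcard.items():
        w = fs.hc_weights[name]
        tau = fs.hc_noise_sd[name]
        u = z @ w + tau * rng.standard_normal(n)
        u = u / np.sqrt(w @ w + tau * tau)
        edges = norm.ppf(np.cumsum(fs.hc_probs[name])[:-1])
        data[name] = np.searchsorted(edges, u).astype(np.int64)

    data["_t"] = np.round(t_norm, 6)
    eta = config.outcome_intercepts[None, :] + z @ config.outcome_coeffs.T
    for k, name in enumerate(OUTCOMES):
        data[f"_eta_{name}"] = np.round(eta[:, k], 6)

    y = sample_outcomes(z, config.outcome_intercepts, config.outcome_coeffs, rng)
    for k, name in enumerate(OUTCOMES):
        data[f"y_{name}"] = y[:, k]

    preop = pd.DataFrame(data)
    intraop = _sample_intraop(config, z, surgery_ids, rng) if config.include_intraop else None
    dataset = SiteDataset(config.site_id, preop, schema, intraop)
    dataset = apply_temporal_drift(dataset, config.drift, rng)
    dataset = inject_missingness(dataset, config.missingness_rates, rng)
    return dataset


def generate_multisite_cohort(
    configs: list[SiteConfig], seed: int = DEFAULT_SEED
) -> list[SiteDataset]:
    """Generate one :class:`SiteDataset` per config, deterministically in
    (configs, seed)."""
    if not configs:
        raise ValueError("configs must be nonempty")
    out = []
    for i, config in enumerate(configs):
        out.append(generate_site(config, stage_seed(seed, "generate", i)))
    return out


def bayes_scores(dataset: SiteDataset, drift: np.ndarray | None = None) -> np.ndarray:
    """(n, 9) generator-optimal risk scores eta_k (+ slope_k * t if given).

    The Bayes-optimal ranking for each outcome under the generative model —
    the oracle against which learned models' discrimination is compared.
    """
    eta = dataset.preop[[f"_eta_{o}" for o in OUTCOMES]].to_numpy()
    if drift is not None:
        eta = eta + np.asarray(drift)[None, :] * dataset.preop["_t"].to_numpy()[:, None]
    return eta
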