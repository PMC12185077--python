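# Methods

## Synthetic two-site cohorts

The generator produces one row per surgery with typed preoperative features,
nine binary complication labels, subgroup attributes, and (optionally)
intraoperative vitals. Its purpose is structural realism — the non-IID,
missingness and drift phenomena a two-hospital federated study must cope
with — not physiological realism.

**Latent outcome model.** Each surgery draws a latent severity vector
`z ~ N(0, I_L)` (default `L = 6`). Outcome `k` is Bernoulli with logit
`b_k + c_k·z + d_k·t`, where `t ∈ [0, 1]` is the normalized surgery date and
`d_k` a per-outcome drift slope. Sharing one `z` across the nine outcomes
induces their correlation; no cross-outcome correlation structure beyond
this is modeled. The coefficient directions are fixed so that prolonged ICU
stay and prolonged mechanical ventilation load on the same two latent
dimensions that drive the procedure code (see below), and the scales
`‖c_k‖ ∈ [1.4, 3.0]` put the Bayes-optimal AUROC of the latent score between
about 0.81 (wound complications) and 0.96 (mortality), mirroring the typical
ordering of difficulty across these outcomes.

**Calibration.** The intercepts `b_k` are solved by Brent's method so that
the *marginal* prevalence `E_{z,t}[σ(b_k + c_k·z + d_k t)]`, evaluated with
64-node Gauss–Hermite × 16-node Gauss–Legendre quadrature, equals the
configured rate. Site defaults: 29%/24% prolonged ICU stay, 8%/9% sepsis,
12%/11% cardiovascular, 5%/4% VTE, 9%/8% prolonged MV, 17%/12% neurological,
16%/14% wound, 15%/14% AKI, 2%/2% mortality for the GNV-like/JAX-like sites.
Empirical prevalence at n = 50,000 then deviates from the target only by
binomial noise.

**Features.** Continuous features are `mean + a_j z_{l(j)} + ε`; the JAX-like
site shifts means by ±0.35 SD. Binary features are Bernoulli with
latent-tilted logits, site-shifted by ±0.3. High-cardinality features are
sampled ordinally: a noisy latent projection is cut at the Gaussian quantiles
of the configured category-probability vector, so the marginal matches that
vector exactly while the category remains informative of `z`. The primary
procedure code (cardinality 50) projects strongly on the ICU/MV latents with
noise 0.6 — it is the most informative single feature for exactly those
outcomes, and masking it (5% of records at the GNV-like site, 36% at the
JAX-like site, the study's key missingness asymmetry) removes real signal.
A handful of continuous features also carry 5–15% missingness. Labels are
never masked.

**Temporal drift** is linear on the logit scale in normalized date (the
simplest monotone form); `apply_temporal_drift` resamples labels from the
stored per-record latent logit, so a zero slope is the exact identity and
records at `t = 0` follow the undrifted intercept.

**Patients and vitals.** Patients receive 1–3 surgeries (mean ≈ 1.31,
matching the surgeries-per-patient ratio of the cohorts being emulated);
dates are uniform over 2012-01-01..2021-05-01. The ten vitals channels are
Gaussian AR(1) walks (autocorrelation 0.9) around clinically plausible
baselines, weakly coupled to the first latent dimension, observed each
minute with probability 0.7 over a 45–150-minute surgery. Real vitals'
nonstationarity, artifacts and interventions are not modeled, so passing
tests say nothing about signal-processing robustness — only that the
pipeline handles irregular, gappy multichannel series correctly.

What the generator does *not* emulate: real code vocabularies, informative
(outcome-dependent) missingness, inter-feature causal structure, site
differences in label definitions. Conclusions from this testbed are about
the algorithms' mechanics under distribution shift, not clinical validity.

## Preprocessing

All statistics are fitted on the training cohort only. Percentiles use
linear interpolation between order statistics (recorded in the state).
The outlier rule is "outside the training [p1, p99]"; such values are
replaced with uniform draws from [p0.5, p5] / [p95, p99.5]. Missing
continuous values take the training median with a presence flag of 0
(1 = observed); missing or previously unseen categorical levels map to a
dedicated "missing" index. Vitals are binned to 1-minute cells
(within-minute mean), linearly interpolated across interior gaps,
nearest-filled at the edges (linear interpolation is undefined there), and
entirely absent channels take the training median with presence 0.
Continuous features and channels are standardized by training mean/sd;
zero-variance features map to 0. The chronological split places boundaries
at the 63%/70% cumulative positions of the date-sorted records (ties broken
by surgery id) and then assigns each patient wholly to the cohort of their
earliest surgery; with multi-admission patients spread over the full study
window this inflates the training cohort by a few percent beyond nominal,
bounded by the number of repeat admissions.

## Model and training

Default widths are deliberately small (continuous 32, binary 16, embeddings
8, fusion 32, GRU hidden 16, attention 16, final 32): the cohorts are
desk-scale and the study's questions concern paradigm differences, not
capacity. Dropout exists as a config option but defaults off. Training is
plain mini-batch SGD (lr 0.1, batch 64, 20 epochs/rounds by default) —
adaptive optimizers would break the exact FedProx/SCAFFOLD identities the
tests rely on. Model selection takes the epoch (round) with the best mean
validation AUROC. Batch order for epoch `e` of client `i` is seeded
`(seed, "batches", e, i)`, which makes single-client federated runs consume
the same batch stream as local training; every other stage likewise derives
its RNG from the master seed and a stage name, so stages re-run
reproducibly in isolation.

Probabilities are clamped to `[1e-12, 1 − 1e-12]` before logs. Gradients are
exact analytic reverse-mode (including BPTT through the masked bidirectional
GRU) and are checked against central finite differences at 1e-4 relative
tolerance.

## Federated specifics

Two clients, full participation, server step `η_g = 1`. SCAFFOLD uses the
cheap "option II" control-variate update. The server interface accepts only
flat delta vectors and sample counts — the privacy contract is structural
and tested with a sentinel-value check. FedProx's `μ` defaults to 0.1 when
the algorithm is selected. Round/epoch budgets (T = 20–30, E = 1) were
chosen for desk-scale runtime; they are config fields, not claims about any
particular deployment.

## Evaluation

AUROC is computed by midranks (ties half-credit); AUPRC is average
precision with tied scores processed as one threshold group. Bootstrap CIs
are percentile intervals from 1000 class-stratified resamples —
stratification preserves class counts so the metric is defined on every
resample; note percentile intervals need not contain the point estimate in
pathological cases, only `lo ≤ hi`. DeLong comparisons are paired,
two-sided, with the Bonferroni family being all comparisons in one results
table. The single-model DeLong variance equals the grouped (within-class)
delete-one jackknife exactly, which the tests exploit as an oracle.
Record-level (not patient-cluster) bootstrap resampling is used. Subgroups:
age 65 falls in "≤65"; race is dichotomized African American vs
non-African American; single-class subgroups are reported as undefined
rather than dropped. The undersampling sensitivity draws the large site's
training subset without replacement, matched to the small site's size, ten
times.

## Problem sizes

Default study sizes: 6,000 + 2,000 surgeries for the analysis drivers;
50,000/18,000 for the calibration checks (the generator is vectorized, ~1 s
per 50k cohort without vitals); 8,000 total for the IID-recovery check and
6,000 + 2,000 for the non-IID generalizability check, each averaged over
three seeds. The perioperative (GRU) mode is exercised on small fixtures;
the paradigm-comparison experiments use the preoperative mode, where the
sequence model contributes nothing to the questions under study but
dominates runtime.

## Known limitations

Single-process simulation only (no networking, encryption, or secure
aggregation); two clients with full participation; no calibration-of-
probabilities assessment; the generator's linear-logit outcome model gives
learnable, well-specified signal — real EHR nonlinearities may favor
different architectures and erode the near-equality of central and
federated training observed here.
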