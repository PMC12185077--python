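"""End-to-end experiment orchestration.

``run_experiment`` drives the full desk-scale study: generate the two-site
synthetic cohorts, split and preprocess (per-site for local/federated
paradigms, pooled for central), train every requested paradigm, and evaluate
per-site test AUROC/AUPRC with bootstrap confidence intervals plus DeLong
comparisons against the central model.  Every stage draws its randomness
from a child of the master seed keyed by the stage name, so any stage re-run
from its on-disk inputs reproduces its outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeding import stage_rng
from .datatypes import OUTCOMES, SiteDataset
from .evaluation import (
    auprc,
    auroc,
    compare_models,
    mean_auroc,
    metric_with_ci,
    subgroup_eval,
    undersampling_sensitivity,
)
from .federated import ALGORITHMS, FedConfig, run_federated
from .model import ModelConfig, flatten_params, predict
from .preprocessing import DEFAULT_FRACTIONS, fit_preprocessor, pool_datasets
from .synthetic import DEFAULT_SEED, SiteConfig, generate_multisite_cohort, gnv_like, jax_like
from .training import OptimizerConfig, prepare_site, train_central, train_local

PARADIGMS = ("local", "central", "fedavg", "fedprox", "scaffold")


@dataclass
class ExperimentConfig:
    n_large: int = 6000
    n_small: int = 2000
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    paradigms: tuple[str, ...] = PARADIGMS
    model: ModelConfig = field(default_factory=ModelConfig)
    opt: OptimizerConfig = field(default_factory=OptimizerConfig)
    fed_rounds: int = 20
    fed_local_epochs: int = 1
    fed_client_lr: float = 0.1
    fed_batch_size: int = 64
    proximal_mu: float = 0.1
    n_boot: int = 1000
    subgroups: tuple[str, ...] = ("sex", "race", "age", "surgery_type")
    sensitivity_repeats: int = 0  # 0 disables the undersampling experiment
    seed: int = DEFAULT_SEED
    with_intraop: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if not self.paradigms:
            raise ValueError("paradigm list must be nonempty")
        for p in self.paradigms:
            if p not in PARADIGMS:
                raise ValueError(f"unknown paradigm {p!r}")

    def fed_config(self, algorithm: str) -> FedConfig:
        return FedConfig(
            algorithm=algorithm,
            rounds=self.fed_rounds,
            local_epochs=self.fed_local_epochs,
            batch_size=self.fed_batch_size,
            client_lr=self.fed_client_lr,
            proximal_mu=self.proximal_mu if algorithm == "fedprox" else 0.0,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        model = ModelConfig(**raw.pop("model", {}))
        opt = OptimizerConfig(**raw.pop("opt", {}))
        for key in ("fractions", "paradigms", "subgroups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(model=model, opt=opt, **raw)


def _metric_table(
    probs: np.ndarray, y: np.ndarray, model: str, site: str, n_boot: int, seed: int
) -> pd.DataFrame:
    rows = []
    for k, outcome in enumerate(OUTCOMES):
        col = y[:, k]
        if not (0 < col.sum() < col.size):
            continue
        for name, fn in (("AUROC", auroc), ("AUPRC", auprc)):
            rng = stage_rng(seed, f"boot-{model}-{site}-{outcome}-{name}")
            res = metric_with_ci(fn, probs[:, k], col, outcome, name, n_boot, rng)
            rows.append(
                {
                    "model": model, "site": site, "outcome": outcome,
                    "metric": name, "point": round(res.point, 6),
                    "ci_low": round(res.ci_low, 6), "ci_high": round(res.ci_high, 6),
                    "n_bootstrap": n_boot,
                }
            )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig, outdir: str | Path) -> dict:
    """Generate, preprocess, train all paradigms, evaluate; write artifacts.

    Returns the report dict (also written as report.json).  Deterministic in
    the master seed: re-running with the same config yields byte-identical
    report JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log = lambda stage, msg: print(f"[{stage}] +{time.time() - t0:6.1f}s {msg}")

    configs = [
        gnv_like(config.n_large, include_intraop=config.with_intraop),
        jax_like(config.n_small, include_intraop=config.with_intraop),
    ]
    datasets = generate_multisite_cohort(configs, seed=config.seed)
    for ds in datasets:
        ds.write(outdir / "data" / ds.site_id)
    log("generate", f"sites {[d.site_id for d in datasets]} n={[d.n_records for d in datasets]}")

    # per-site preprocessing (local + federated paradigms)
    prepared = {}
    for ds in datasets:
        designs, split, state = prepare_site(
            ds, config.seed, config.fractions, with_intraop=config.with_intraop
        )
        prepared[ds.site_id] = designs
        state.save(outdir / f"preprocessor_{ds.site_id}.json")
    log("preprocess", "per-site states fitted on training cohorts")

    schema = datasets[0].schema
    models: dict[str, dict] = {}

    for paradigm in config.paradigms:
        if paradigm == "local":
            for ds in datasets:
                res, _ = train_local(
                    ds, config.model, config.opt, config.seed,
                    config.fractions, config.with_intraop,
                )
                models[f"local_{ds.site_id}"] = {"params": res.params, "scope": ds.site_id}
                log("train", f"local_{ds.site_id} best epoch {res.best_epoch}")
        elif paradigm == "central":
            res, central_designs = train_central(
                datasets, config.model, config.opt, config.seed,
                config.fractions, config.with_intraop,
            )
            models["central"] = {"params": res.params, "scope": "pooled"}
            log("train", f"central best epoch {res.best_epoch}")
        else:
            fed = config.fed_config(paradigm)
            client_designs = [
                (prepared[ds.site_id]["train"], prepared[ds.site_id]["val"])
                for ds in datasets
            ]
            params, state = run_federated(client_designs, config.model, fed, schema)
            models[paradigm] = {"params": params, "scope": "federated"}
            pd.DataFrame(state.history[:-1]).to_csv(
                outdir / f"rounds_{paradigm}.csv", index=False
            )
            log("train", f"{paradigm} rounds={fed.rounds}")

    # central evaluation designs use pooled preprocessing at each site's test cohort
    central_prepared = None
    if "central" in models:
        pooled = pool_datasets(datasets)
        pooled_designs, _, pooled_state = prepare_site(
            pooled, config.seed, config.fractions, with_intraop=config.with_intraop
        )
        pooled_state.save(outdir / "preprocessor_pooled.json")
        central_prepared = pooled_designs

    metric_frames, preds_by_site = [], {ds.site_id: {} for ds in datasets}
    for name, entry in models.items():
        for ds in datasets:
            test = prepared[ds.site_id]["test"]
            probs = predict(entry["params"], test, config.model)
            preds_by_site[ds.site_id][name] = probs
            metric_frames.append(
                _metric_table(probs, test.y, name, ds.site_id, config.n_boot, config.seed)
            )
    metrics = pd.concat(metric_frames, ignore_index=True)
    metrics.to_csv(outdir / "metrics.csv", index=False)
    log("evaluate", f"{len(metrics)} metric rows")

    comparisons = pd.DataFrame()
    if "central" in models and len(models) > 1:
        frames = []
        for ds in datasets:
            test = prepared[ds.site_id]["test"]
            pairs = [(m, "central") for m in models if m != "central"]
            cmp_df = compare_models(preds_by_site[ds.site_id], test.y, pairs)
            cmp_df.insert(0, "site", ds.site_id)
            frames.append(cmp_df)
        comparisons = pd.concat(frames, ignore_index=True)
        comparisons.to_csv(outdir / "comparisons.csv", index=False)

    subgroup_frames = []
    sub_model = "scaffold" if "scaffold" in models else sorted(models)[0]
    for ds in datasets:
        test = prepared[ds.site_id]["test"]
        for grouping in config.subgroups:
            rng = stage_rng(config.seed, f"subgroup-{ds.site_id}-{grouping}")
            tbl = subgroup_eval(
                preds_by_site[ds.site_id][sub_model], test.y, test.attrs,
                grouping, n_boot=min(config.n_boot, 200), rng=rng,
            )
            tbl.insert(0, "site", ds.site_id)
            tbl.insert(1, "model", sub_model)
            subgroup_frames.append(tbl)
    subgroups = pd.concat(subgroup_frames, ignore_index=True)
    subgroups.to_csv(outdir / "subgroups.csv", index=False)
    log("evaluate", "subgroup tables written")

    sensitivity = None
    if config.sensitivity_repeats > 0:
        sensitivity = undersampling_sensitivity(
            datasets, config.model, config.fed_config("scaffold"), config.seed,
            repeats=config.sensitivity_repeats, fractions=config.fractions,
        )
        sensitivity.to_csv(outdir / "sensitivity.csv", index=False)
        log("evaluate", f"undersampling sensitivity x{config.sensitivity_repeats}")

    report = {
        "seed": config.seed,
        "sites": {ds.site_id: ds.n_records for ds in datasets},
        "paradigms": sorted(models),
        "mean_test_auroc": {
            name: {
                ds.site_id: round(
                    mean_auroc(preds_by_site[ds.site_id][name], prepared[ds.site_id]["test"].y), 6
                )
                for ds in datasets
            }
            for name in sorted(models)
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log("done", "report.json written")
    return report
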