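#!/usr/bin/env python
"""Train every learning paradigm on the generated two-site cohorts.

Local models per site, a central model on pooled data, and the three
federated algorithms (FedAvg, FedProx, SCAFFOLD) with per-site
preprocessing.  Writes per-site test-set risk predictions and round/epoch
histories under results/training/ and prints each model's mean test AUROC.
"""

from pathlib import Path

import pandas as pd

from fedperiop.datatypes import OUTCOMES, SiteDataset
from fedperiop.evaluation import mean_auroc
from fedperiop.federated import FedConfig, run_federated
from fedperiop.model import ModelConfig, predict
from fedperiop.synthetic import DEFAULT_SEED
from fedperiop.training import OptimizerConfig, prepare_site, train_central, train_local

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "training"
SEED = DEFAULT_SEED
MODEL = ModelConfig()
OPT = OptimizerConfig(epochs=20)
ROUNDS = 20


def main() -> None:
    sites = [SiteDataset.read(p) for p in sorted((ROOT / "data").iterdir()) if p.is_dir()]
    OUT.mkdir(parents=True, exist_ok=True)
    prepared = {ds.site_id: prepare_site(ds, SEED)[0] for ds in sites}

    models = {}
    for ds in sites:
        res, _ = train_local(ds, MODEL, OPT, SEED)
        models[f"local_{ds.site_id}"] = res.params
    res, _ = train_central(sites, MODEL, OPT, SEED)
    models["central"] = res.params
    designs = [(prepared[ds.site_id]["train"], prepared[ds.site_id]["val"]) for ds in sites]
    for alg in ("fedavg", "fedprox", "scaffold"):
        fed = FedConfig(alg, rounds=ROUNDS, seed=SEED,
                        proximal_mu=0.1 if alg == "fedprox" else 0.0)
        params, state = run_federated(designs, MODEL, fed, sites[0].schema)
        models[alg] = params
        pd.DataFrame(state.history[:-1]).to_csv(OUT / f"rounds_{alg}.csv", index=False)

    summary = []
    for name, params in models.items():
        for ds in sites:
            test = prepared[ds.site_id]["test"]
            probs = predict(params, test, MODEL)
            df = pd.DataFrame(probs, columns=[f"p_{o}" for o in OUTCOMES])
            df.insert(0, "surgery_id", test.surgery_ids)
            df.to_csv(OUT / f"preds_{name}_{ds.site_id}.csv", index=False)
            score = mean_auroc(probs, test.y)
            summary.append({"model": name, "site": ds.site_id,
                            "mean_test_auroc": round(score, 4)})
            print(f"{name:12s} @ {ds.site_id}: mean test AUROC {score:.4f}")
    pd.DataFrame(summary).to_csv(OUT / "summary.csv", index=False)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
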