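#!/usr/bin/env python
"""Per-outcome discrimination tables, model comparisons, and subgroups.

Reads the stored test-set predictions from results/training/, computes
AUROC/AUPRC with 1000-sample stratified-bootstrap 95% CIs for every model,
site and complication; runs Bonferroni-adjusted DeLong tests of each model
against central learning; and tabulates SCAFFOLD's subgroup performance
(sex, race, age band, surgery type).  Writes results/evaluation/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fedperiop._seeding import stage_rng
from fedperiop.datatypes import OUTCOMES, SiteDataset
from fedperiop.evaluation import auprc, auroc, compare_models, metric_with_ci, subgroup_eval
from fedperiop.synthetic import DEFAULT_SEED
from fedperiop.training import prepare_site

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "evaluation"
SEED = DEFAULT_SEED
N_BOOT = 1000


def main() -> None:
    sites = [SiteDataset.read(p) for p in sorted((ROOT / "data").iterdir()) if p.is_dir()]
    OUT.mkdir(parents=True, exist_ok=True)
    prepared = {ds.site_id: prepare_site(ds, SEED)[0] for ds in sites}

    pred_files = sorted((ROOT / "training").glob("preds_*.csv"))
    metric_rows, cmp_frames, sub_frames = [], [], []
    for ds in sites:
        test = prepared[ds.site_id]["test"]
        order = pd.Series(np.arange(test.n), index=test.surgery_ids)
        preds = {}
        for f in pred_files:
            stem = f.stem[len("preds_"):]
            if not stem.endswith(f"_{ds.site_id}"):
                continue
            name = stem[: -len(f"_{ds.site_id}")]
            df = pd.read_csv(f).set_index("surgery_id").loc[order.index]
            preds[name] = df[[f"p_{o}" for o in OUTCOMES]].to_numpy()
        for name, probs in preds.items():
            for k, outcome in enumerate(OUTCOMES):
                y = test.y[:, k]
                if not (0 < y.sum() < y.size):
                    continue
                for metric, fn in (("AUROC", auroc), ("AUPRC", auprc)):
                    rng = stage_rng(SEED, f"boot-{name}-{ds.site_id}-{outcome}-{metric}")
                    r = metric_with_ci(fn, probs[:, k], y, outcome, metric, N_BOOT, rng)
                    metric_rows.append(
                        {"site": ds.site_id, "model": name, "outcome": outcome,
                         "metric": metric, "point": round(r.point, 4),
                         "ci_low": round(r.ci_low, 4), "ci_high": round(r.ci_high, 4)}
                    )
        pairs = [(m, "central") for m in preds if m != "central"]
        cmp_df = compare_models(preds, test.y, pairs)
        cmp_df.insert(0, "site", ds.site_id)
        cmp_frames.append(cmp_df)
        for grouping in ("sex", "race", "age", "surgery_type"):
            rng = stage_rng(SEED, f"subgroup-{ds.site_id}-{grouping}")
            tbl = subgroup_eval(preds["scaffold"], test.y, test.attrs, grouping,
                                n_boot=200, rng=rng)
            tbl.insert(0, "site", ds.site_id)
            sub_frames.append(tbl)

    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(OUT / "metrics.csv", index=False)
    pd.concat(cmp_frames, ignore_index=True).to_csv(OUT / "delong_vs_central.csv", index=False)
    pd.concat(sub_frames, ignore_index=True).to_csv(OUT / "subgroups_scaffold.csv", index=False)

    wide = metrics[metrics.metric == "AUROC"].pivot_table(
        index=["site", "outcome"], columns="model", values="point"
    ).round(3)
    print(wide.to_string())
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
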