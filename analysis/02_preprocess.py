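#!/usr/bin/env python
"""Chronological splits and fitted preprocessing states.

Reads the generated sites from results/data/, performs the 63/7/30
patient-grouped chronological split per site, fits per-site preprocessing
states (for local and federated learning) and a pooled state (for central
learning), and writes everything under results/preprocessing/.
"""

import json
from pathlib import Path

from fedperiop.datatypes import SiteDataset
from fedperiop.preprocessing import chronological_split, fit_preprocessor, pool_datasets
from fedperiop.synthetic import DEFAULT_SEED

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "preprocessing"


def main() -> None:
    sites = [SiteDataset.read(p) for p in sorted((ROOT / "data").iterdir()) if p.is_dir()]
    OUT.mkdir(parents=True, exist_ok=True)
    splits = {}
    for ds in sites + [pool_datasets(sites)]:
        split = chronological_split(ds)
        state = fit_preprocessor(ds.subset(split.train_ids))
        state.save(OUT / f"preprocessor_{ds.site_id}.json")
        splits[ds.site_id] = {
            "train": len(split.train_ids),
            "val": len(split.val_ids),
            "test": len(split.test_ids),
        }
        icu_med = state.continuous["cont_00"]
        print(
            f"{ds.site_id}: train/val/test = "
            f"{splits[ds.site_id]['train']}/{splits[ds.site_id]['val']}"
            f"/{splits[ds.site_id]['test']}; cont_00 train median "
            f"{icu_med.median:+.3f}, p1/p99 = {icu_med.p1:+.3f}/{icu_med.p99:+.3f}"
        )
    (OUT / "splits.json").write_text(json.dumps(splits, indent=1, sort_keys=True))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
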