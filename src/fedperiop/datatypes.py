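"""Core containers shared across the pipeline.

A site's cohort is held as two pandas tables: one row per surgery for
preoperative features, subgroup attributes and the nine outcome labels, and an
optional long-format table of intraoperative observations
(surgery_id, channel, minute, value).  A :class:`FeatureSchema` names the
features and their types; every module downstream (preprocessing, model,
federated training) keys off it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Fixed outcome order used everywhere (labels, model heads, report tables).
OUTCOMES: tuple[str, ...] = (
    "prolonged_icu",
    "sepsis",
    "cardiovascular",
    "vte",
    "prolonged_mv",
    "neurological",
    "wound",
    "aki",
    "mortality",
)

N_OUTCOMES = len(OUTCOMES)

#: Intraoperative vital-sign channels (systolic/diastolic/mean arterial
#: pressure, heart rate, temperature, end-tidal CO2, SpO2, peak inspiratory
#: pressure, respiratory rate, minimum alveolar concentration).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "sbp", "dbp", "map", "hr", "temp", "etco2", "spo2", "pip", "rr", "mac",
)

SUBGROUP_ATTRS = ("sex", "race", "age", "surgery_type")

SURGERY_TYPES = (
    "cardiothoracic", "general", "neurological", "specialty", "other",
)


@dataclass(frozen=True)
class FeatureSchema:
    """Names and types of preoperative features and intraoperative channels.

    Features are typed ``continuous``, ``binary`` or ``high-cardinality``
    (many-level categorical, e.g. the primary procedure code), each routed to
    its own model branch.
    """

    continuous: tuple[str, ...]
    binary: tuple[str, ...]
    highcard: dict[str, int]  # name -> cardinality (excluding "missing")
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        names = list(self.continuous) + list(self.binary) + list(self.highcard)
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique across types")
        for name, card in self.highcard.items():
            if card < 2:
                raise ValueError(f"cardinality of {name!r} must be >= 2, got {card}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.continuous) + list(self.binary) + list(self.highcard)

    def type_of(self, name: str) -> str:
        if name in self.continuous:
            return "continuous"
        if name in self.binary:
            return "binary"
        if name in self.highcard:
            return "high-cardinality"
        raise KeyError(f"unknown feature {name!r}")

    def to_dict(self) -> dict:
        return {
            "continuous": list(self.continuous),
            "binary": list(self.binary),
            "highcard": dict(self.highcard),
            "channels": list(self.channels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            continuous=tuple(d["continuous"]),
            binary=tuple(d["binary"]),
            highcard={k: int(v) for k, v in d["highcard"].items()},
            channels=tuple(d["channels"]),
        )


def default_schema(
    n_continuous: int = 40,
    n_binary: int = 30,
    highcard: dict[str, int] | None = None,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> FeatureSchema:
    """Desk-scale schema: 40 continuous, 30 binary, 5 high-cardinality
    features (the first being the primary procedure code) and 10 channels."""
    if highcard is None:
        highcard = {
            "procedure_code": 50,
            "admission_source": 12,
            "provider_specialty": 8,
            "insurance_plan": 6,
            "admission_type": 4,
        }
    return FeatureSchema(
        continuous=tuple(f"cont_{i:02d}" for i in range(n_continuous)),
        binary=tuple(f"bin_{i:02d}" for i in range(n_binary)),
        highcard=dict(highcard),
        channels=tuple(channels),
    )


@dataclass
class SiteDataset:
    """One site's cohort.

    ``preop`` columns: patient_id, surgery_id, surgery_date, the subgroup
    attributes, feature columns named by the schema, outcome columns ``y_*``
    in :data:`OUTCOMES` order, plus generator-internal latent-score columns
    prefixed ``_eta_`` (never used by models; needed to resample labels under
    temporal drift and for Bayes-score oracles).

    ``intraop`` (optional): long table (surgery_id, channel, minute, value).
    """

    site_id: str
    preop: pd.DataFrame
    schema: FeatureSchema
    intraop: pd.DataFrame | None = None

    @property
    def n_records(self) -> int:
        return len(self.preop)

    def outcome_matrix(self) -> np.ndarray:
        return self.preop[[f"y_{o}" for o in OUTCOMES]].to_numpy(dtype=np.int8)

    def subset(self, surgery_ids) -> "SiteDataset":
        ids = set(surgery_ids)
        preop = self.preop[self.preop["surgery_id"].isin(ids)].reset_index(drop=True)
        intraop = None
        if self.intraop is not None:
            intraop = self.intraop[self.intraop["surgery_id"].isin(ids)].reset_index(
                drop=True
            )
        return SiteDataset(self.site_id, preop, self.schema, intraop)

    # ---------------------------------------------------------------- I/O
    def write(self, outdir: str | Path) -> None:
        """Write preop.csv (+ intraop.csv if present) and schema.json.

        Missing values are encoded as empty CSV fields.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.preop.to_csv(outdir / "preop.csv", index=False)
        if self.intraop is not None:
            self.intraop.to_csv(outdir / "intraop.csv", index=False)
        meta = {"site_id": self.site_id, "schema": self.schema.to_dict()}
        (outdir / "schema.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def read(cls, indir: str | Path) -> "SiteDataset":
        indir = Path(indir)
        meta = json.loads((indir / "schema.json").read_text())
        preop = pd.read_csv(indir / "preop.csv", parse_dates=["surgery_date"])
        intraop = None
        if (indir / "intraop.csv").exists():
            intraop = pd.read_csv(indir / "intraop.csv")
        return cls(
            site_id=meta["site_id"],
            preop=preop,
            schema=FeatureSchema.from_dict(meta["schema"]),
            intraop=intraop,
        )


def outcome_columns() -> list[str]:
    return [f"y_{o}" for o in OUTCOMES]
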