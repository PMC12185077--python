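"""Local and central training.

Plain mini-batch SGD inside clients (so the FedProx / SCAFFOLD algebraic
identities hold exactly), with per-epoch validation and best-validation model
selection.  The batch order of epoch ``e`` for client ``i`` is seeded as
``stage_seed(seed, "batches", e, i)``, so a single-client federated run with
one local epoch per round consumes the identical batch stream as local
training — the basis of the exact-equivalence tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeding import stage_rng, stage_seed
from .datatypes import SiteDataset
from .evaluation import mean_auroc
from .model import ModelConfig, build_model, loss_and_grad, flatten_params, predict, unflatten_params
from .preprocessing import (
    DEFAULT_FRACTIONS,
    DesignMatrices,
    CohortSplit,
    PreprocessorState,
    chronological_split,
    fit_preprocessor,
    pool_datasets,
    transform,
)


@dataclass(frozen=True)
class OptimizerConfig:
    lr: float = 0.1
    batch_size: int = 64
    epochs: int = 20

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def sgd_epoch(
    params: dict[str, np.ndarray],
    design: DesignMatrices,
    model_config: ModelConfig,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
    mu: float = 0.0,
    w_ref: np.ndarray | None = None,
    correction: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], int]:
    """One pass over the data in shuffled mini-batches; returns (params, steps).

    ``mu``/``w_ref`` add the FedProx proximal gradient mu*(y - w_ref);
    ``correction`` adds a constant vector to every gradient (SCAFFOLD's
    c - c_i term).  Loss history is not tracked here; callers monitor
    validation metrics between epochs.
    """
    order = rng.permutation(design.n)
    steps = 0
    for start in range(0, design.n, batch_size):
        batch = design.take(order[start : start + batch_size])
        _, grads = loss_and_grad(params, batch, model_config)
        g = flatten_params({k: np.asarray(v) for k, v in grads.items()})
        if mu > 0.0 and w_ref is not None:
            g = g + mu * (flatten_params(params) - w_ref)
        if correction is not None:
            g = g + correction
        flat = flatten_params(params) - lr * g
        params = unflatten_params(flat, params)
        steps += 1
    return params, steps


@dataclass
class TrainResult:
    params: dict[str, np.ndarray]
    history: list[dict]                    # per-epoch validation metrics
    split: CohortSplit | None = None
    preprocessor: PreprocessorState | None = None
    best_epoch: int = -1
    trajectory: list = field(default_factory=list)  # per-epoch flat params (optional)


def train_on_designs(
    train: DesignMatrices,
    val: DesignMatrices | None,
    model_config: ModelConfig,
    opt: OptimizerConfig,
    seed: int,
    client_index: int = 0,
    epoch_offset: int = 0,
    init_params: dict[str, np.ndarray] | None = None,
    record_trajectory: bool = False,
) -> TrainResult:
    """SGD for ``opt.epochs`` epochs with best-validation-AUROC selection."""
    if train.n == 0:
        raise ValueError("training set is empty")
    if init_params is None:
        raise ValueError("init_params is required (use build_model with the schema)")
    params = init_params
    best = {k: v.copy() for k, v in params.items()}
    best_score, best_epoch = -np.inf, -1
    history = []
    trajectory: list[np.ndarray] = []
    for e in range(opt.epochs):
        rng = stage_rng(seed, "batches", epoch_offset + e, client_index)
        params, _ = sgd_epoch(params, train, model_config, opt.lr, opt.batch_size, rng)
        if record_trajectory:
            trajectory.append(flatten_params(params))
        score = np.nan
        if val is not None and val.n:
            score = mean_auroc(predict(params, val, model_config), val.y)
        history.append({"epoch": epoch_offset + e, "val_auroc": score})
        if val is None or (np.isfinite(score) and score > best_score):
            best_score = score if val is not None else 0.0
            best_epoch = e
            best = {k: v.copy() for k, v in params.items()}
    result = TrainResult(params=best, history=history, best_epoch=best_epoch)
    result.trajectory = trajectory
    return result


# ------------------------------------------------------- dataset pipelines


def prepare_site(
    dataset: SiteDataset,
    seed: int,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    state: PreprocessorState | None = None,
    with_intraop: bool = False,
) -> tuple[dict[str, DesignMatrices], CohortSplit, PreprocessorState]:
    """Split chronologically, fit preprocessing on train (unless a fitted
    state is supplied, e.g. pooled central preprocessing), transform all
    cohorts."""
    split = chronological_split(dataset, fractions)
    if state is None:
        state = fit_preprocessor(dataset.subset(split.train_ids))
    designs = {}
    for name, ids in (
        ("train", split.train_ids), ("val", split.val_ids), ("test", split.test_ids),
    ):
        rng = stage_rng(seed, "transform-" + name)
        designs[name] = transform(dataset, ids, state, rng, with_intraop=with_intraop)
    return designs, split, state


def train_local(
    dataset: SiteDataset,
    model_config: ModelConfig,
    opt: OptimizerConfig,
    seed: int,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    with_intraop: bool = False,
) -> tuple[TrainResult, dict[str, DesignMatrices]]:
    """Local learning: one site's data, site-fitted preprocessing."""
    designs, split, state = prepare_site(
        dataset, seed, fractions, with_intraop=with_intraop
    )
    init = build_model(model_config, dataset.schema, seed)
    result = train_on_designs(
        designs["train"], designs["val"], model_config, opt, seed, init_params=init
    )
    result.split = split
    result.preprocessor = state
    return result, designs


def train_central(
    datasets: list[SiteDataset],
    model_config: ModelConfig,
    opt: OptimizerConfig,
    seed: int,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    with_intraop: bool = False,
) -> tuple[TrainResult, dict[str, DesignMatrices]]:
    """Central learning: pooled data, pooled preprocessing — identical to
    :func:`train_local` on the concatenation."""
    if not datasets:
        raise ValueError("need at least one site")
    pooled = pool_datasets(datasets)
    return train_local(pooled, model_config, opt, seed, fractions, with_intraop)
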