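"""Federated training simulated in one process: FedAvg, FedProx, SCAFFOLD.

The privacy boundary is structural: clients expose only
``(delta_w, delta_c, n_k)`` flat vectors and counts to the server;
:func:`server_aggregate` never receives record-level data.

Update rules (eta_l = client step size, eta_g = server step size, full
participation):

* FedAvg: each client runs K = E * ceil(n_k / B) SGD steps from the global
  weights w; the server sets w <- w + eta_g * sum_k (n_k / n) * delta_w_k.
* FedProx: the local gradient gains a proximal term mu * (y - w) pulling the
  iterate toward the global weights; mu = 0 reduces exactly to FedAvg.
* SCAFFOLD: local steps use g - c_i + c (client/server control variates);
  after the K steps the client control variate updates by the "option II"
  rule delta_c_i = -c + (w - y) / (K * eta_l), and the server averages the
  client deltas into c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seeding import stage_rng
from .evaluation import mean_auroc
from .model import ModelConfig, build_model, flatten_params, predict, unflatten_params
from .preprocessing import DesignMatrices
from .training import OptimizerConfig, sgd_epoch

ALGORITHMS = ("fedavg", "fedprox", "scaffold")


@dataclass(frozen=True)
class FedConfig:
    algorithm: str = "fedavg"
    rounds: int = 30
    local_epochs: int = 1
    batch_size: int = 64
    client_lr: float = 0.1
    server_lr: float = 1.0
    proximal_mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.proximal_mu < 0:
            raise ValueError("proximal_mu must be nonnegative")
        if self.proximal_mu > 0 and self.algorithm != "fedprox":
            import warnings

            warnings.warn("proximal_mu is ignored unless algorithm='fedprox'")
        if self.client_lr <= 0 or self.server_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.rounds < 1 or self.local_epochs < 1:
            raise ValueError("rounds and local_epochs must be >= 1")


@dataclass
class ClientState:
    site_id: str
    n_k: int
    control: np.ndarray  # c_i, zero-initialized (scaffold)


@dataclass
class FederatedState:
    round: int
    weights: np.ndarray           # global flat parameter vector
    control: np.ndarray           # global control variate c
    clients: list[ClientState]
    history: list[dict] = field(default_factory=list)
    trajectory: list[np.ndarray] = field(default_factory=list)


def client_update(
    client: ClientState,
    w: np.ndarray,
    c: np.ndarray,
    train: DesignMatrices,
    template: dict[str, np.ndarray],
    model_config: ModelConfig,
    fed: FedConfig,
    round_index: int,
    client_index: int,
) -> tuple[np.ndarray, np.ndarray | None, int]:
    """Run E local epochs from w; return (delta_w, delta_c or None, n_k)."""
    if train.n == 0:
        raise ValueError(f"client {client.site_id} has no training data")
    if w.shape != client.control.shape:
        raise ValueError("parameter/control dimension mismatch")
    params = unflatten_params(w, template)
    mu = fed.proximal_mu if fed.algorithm == "fedprox" else 0.0
    correction = c - client.control if fed.algorithm == "scaffold" else None
    K = 0
    for e in range(fed.local_epochs):
        rng = stage_rng(fed.seed, "batches", round_index * fed.local_epochs + e, client_index)
        params, steps = sgd_epoch(
            params, train, model_config, fed.client_lr, fed.batch_size, rng,
            mu=mu, w_ref=w, correction=correction,
        )
        K += steps
    y = flatten_params(params)
    delta_w = y - w
    delta_c = None
    if fed.algorithm == "scaffold":
        delta_c = -c + (w - y) / (K * fed.client_lr)
    return delta_w, delta_c, train.n


def server_aggregate(
    state: FederatedState,
    deltas: list[np.ndarray],
    delta_controls: list[np.ndarray | None],
    counts: list[int],
    fed: FedConfig,
) -> FederatedState:
    """Sample-size-weighted aggregation: w += eta_g * sum n_k/n * delta_k.

    Scaling every n_k by a constant leaves the aggregate unchanged.  For
    SCAFFOLD the global control variate moves by the plain average of the
    client control deltas (full participation).
    """
    if any(d.shape != state.weights.shape for d in deltas):
        raise ValueError("client delta dimension mismatch")
    n_total = float(sum(counts))
    update = sum((n / n_total) * d for n, d in zip(counts, deltas))
    state.weights = state.weights + fed.server_lr * update
    if fed.algorithm == "scaffold":
        state.control = state.control + sum(delta_controls) / len(delta_controls)
        for client, dc in zip(state.clients, delta_controls):
            client.control = client.control + dc
    state.round += 1
    return state


def run_federated(
    client_designs: list[tuple[DesignMatrices, DesignMatrices | None]],
    model_config: ModelConfig,
    fed: FedConfig,
    schema,
    record_trajectory: bool = False,
) -> tuple[dict[str, np.ndarray], FederatedState]:
    """T rounds of client_update + server_aggregate over in-process clients.

    Preprocessing happens per site *before* this call (never pooled).  The
    returned parameters are those of the round with the best mean validation
    AUROC across clients; the full round history is kept in the state.
    """
    usable = [(i, tr, va) for i, (tr, va) in enumerate(client_designs) if tr.n > 0]
    if len(usable) < len(client_designs):
        import warnings

        warnings.warn("excluding clients with empty training cohorts")
    if not usable:
        raise ValueError("no clients with training data")
    template = build_model(model_config, schema, fed.seed)
    w = flatten_params(template)
    D = w.size
    state = FederatedState(
        round=0,
        weights=w,
        control=np.zeros(D),
        clients=[
            ClientState(site_id=f"client{i}", n_k=tr.n, control=np.zeros(D))
            for i, tr, _ in usable
        ],
    )
    best_w, best_score, best_round = state.weights.copy(), -np.inf, -1
    for t in range(fed.rounds):
        deltas, dcs, counts = [], [], []
        for slot, (i, tr, _) in enumerate(usable):
            dw, dc, nk = client_update(
                state.clients[slot], state.weights, state.control, tr,
                template, model_config, fed, t, i,
            )
            deltas.append(dw)
            dcs.append(dc)
            counts.append(nk)
        state = server_aggregate(state, deltas, dcs, counts, fed)
        if record_trajectory:
            state.trajectory.append(state.weights.copy())
        params = unflatten_params(state.weights, template)
        scores = []
        for _, _, va in usable:
            if va is not None and va.n:
                scores.append(mean_auroc(predict(params, va, model_config), va.y))
        score = float(np.mean(scores)) if scores else np.nan
        state.history.append({"round": t, "val_auroc": score})
        if not scores or (np.isfinite(score) and score > best_score):
            best_score = score if scores else 0.0
            best_round = t
            best_w = state.weights.copy()
    state.history.append({"round": "best", "val_auroc": best_score, "best_round": best_round})
    return unflatten_params(best_w, template), state
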