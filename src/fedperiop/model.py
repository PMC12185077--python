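"""Multi-branch, multi-task risk network in plain numpy.

Architecture (preoperative submodel):

* continuous branch: [values, presence flags] -> fully connected + ReLU;
* binary branch: fully connected + ReLU;
* high-cardinality branch: one embedding table per feature (vocabulary =
  observed levels + a "missing" slot), concatenated, fully connected + ReLU;
* the three branch outputs are fused by a fully connected layer.

Perioperative mode adds an intraoperative submodel: the [values, presence]
channel grid runs through a bidirectional GRU; additive attention scores each
bidirectional state, a masked softmax over time yields weights summing to 1,
and their weighted sum is the pooled context vector, concatenated with the
preoperative representation before the final fully connected layer.

Nine outcome-specific heads (fully connected layer -> sigmoid) emit one risk
probability per complication.  Gradients are computed by hand (reverse-mode,
including backpropagation through time for the GRU) and are verified against
central finite differences in the test suite.

All weights are addressable as one flat vector with a stable (sorted-name)
ordering — the unit of exchange for federated learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .datatypes import N_OUTCOMES, FeatureSchema
from .preprocessing import DesignMatrices

EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    mode: str = "preoperative"  # or "perioperative"
    cont_width: int = 32
    bin_width: int = 16
    embed_dim: int = 8
    hc_width: int = 16
    fusion_width: int = 32
    rnn_hidden: int = 16
    attn_dim: int = 16
    final_width: int = 32
    n_outcomes: int = N_OUTCOMES
    activation: str = "relu"
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("preoperative", "perioperative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_outcomes != N_OUTCOMES:
            raise ValueError("the network has exactly 9 outcome heads")
        widths = (
            self.cont_width, self.bin_width, self.embed_dim, self.hc_width,
            self.fusion_width, self.rnn_hidden, self.attn_dim, self.final_width,
        )
        if any(w < 1 for w in widths):
            raise ValueError("all widths must be >= 1")


# ------------------------------------------------------------ flat params


def flatten_params(params: dict[str, np.ndarray]) -> np.ndarray:
    """Concatenate all tensors into one vector, sorted by name."""
    return np.concatenate([params[k].ravel() for k in sorted(params)])


def unflatten_params(
    flat: np.ndarray, template: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    i = 0
    for k in sorted(template):
        shape = template[k].shape
        size = int(np.prod(shape)) if shape else 1
        out[k] = flat[i : i + size].reshape(shape).copy()
        i += size
    if i != flat.size:
        raise ValueError(f"flat vector of size {flat.size} does not match template ({i})")
    return out


def param_dimension(params: dict[str, np.ndarray]) -> int:
    return sum(p.size for p in params.values())


def _param_shapes(config: ModelConfig, schema: FeatureSchema) -> dict[str, tuple]:
    nc, nb = len(schema.continuous), len(schema.binary)
    shapes: dict[str, tuple] = {
        "cont_W": (2 * nc, config.cont_width),
        "cont_b": (config.cont_width,),
        "bin_W": (nb, config.bin_width),
        "bin_b": (config.bin_width,),
        "hc_W": (len(schema.highcard) * config.embed_dim, config.hc_width),
        "hc_b": (config.hc_width,),
    }
    for name, card in schema.highcard.items():
        shapes[f"emb_{name}"] = (card + 1, config.embed_dim)  # +1: "missing" slot
    branch_total = config.cont_width + config.bin_width + config.hc_width
    shapes["fuse_W"] = (branch_total, config.fusion_width)
    shapes["fuse_b"] = (config.fusion_width,)
    final_in = config.fusion_width
    if config.mode == "perioperative":
        C = len(schema.channels)
        H = config.rnn_hidden
        din = 2 * C
        for d in ("fwd", "bwd"):
            for gate in ("r", "z", "n"):
                shapes[f"gru_{d}_Wx{gate}"] = (din, H)
                shapes[f"gru_{d}_Wh{gate}"] = (H, H)
                shapes[f"gru_{d}_b{gate}"] = (H,)
        shapes["attn_W"] = (2 * H, config.attn_dim)
        shapes["attn_b"] = (config.attn_dim,)
        shapes["attn_v"] = (config.attn_dim,)
        final_in += 2 * H
    shapes["final_W"] = (final_in, config.final_width)
    shapes["final_b"] = (config.final_width,)
    for k in range(config.n_outcomes):
        shapes[f"head{k}_w"] = (config.final_width,)
        shapes[f"head{k}_b"] = ()
    return shapes


def build_model(
    config: ModelConfig, schema: FeatureSchema, seed: int
) -> dict[str, np.ndarray]:
    """Glorot-uniform initialization, deterministic in (config, schema, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x6D6F64]))
    params: dict[str, np.ndarray] = {}
    shapes = _param_shapes(config, schema)
    for name in sorted(shapes):
        shape = shapes[name]
        if name.endswith("_b") or shape == ():
            params[name] = np.zeros(shape)
        elif len(shape) == 1:
            limit = np.sqrt(6.0 / (shape[0] + 1))
            params[name] = rng.uniform(-limit, limit, size=shape)
        else:
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            params[name] = rng.uniform(-limit, limit, size=shape)
    return params


# ---------------------------------------------------------------- forward


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def forward(
    params: dict[str, np.ndarray],
    batch: DesignMatrices,
    config: ModelConfig,
    return_cache: bool = False,
):
    """Risk probabilities (B, 9); probabilities are strictly inside (0, 1)."""
    cache: dict = {}
    xc = np.concatenate([batch.x_cont, batch.f_cont], axis=1)
    hc_pre = xc @ params["cont_W"] + params["cont_b"]
    hc = _relu(hc_pre)
    hb_pre = batch.x_bin @ params["bin_W"] + params["bin_b"]
    hb = _relu(hb_pre)

    embs = []
    emb_names = [k for k in sorted(params) if k.startswith("emb_")]
    for j, name in enumerate(emb_names):
        idx = batch.x_high[:, j]
        if idx.max(initial=0) >= params[name].shape[0]:
            raise ValueError(f"category index out of range for {name}")
        embs.append(params[name][idx])
    he = np.concatenate(embs, axis=1)
    hh_pre = he @ params["hc_W"] + params["hc_b"]
    hh = _relu(hh_pre)

    branches = np.concatenate([hc, hb, hh], axis=1)
    fuse_pre = branches @ params["fuse_W"] + params["fuse_b"]
    h_pre = _relu(fuse_pre)

    if config.mode == "perioperative":
        if batch.series is None:
            raise ValueError("perioperative mode requires the time-series grid")
        if batch.series.shape[1] == 0:
            raise ValueError("sequence length 0 in perioperative mode")
        X = np.concatenate([batch.series, batch.series_presence], axis=2)  # (B,T,2C)
        mask = batch.series_mask  # (B,T)
        states, gru_caches = [], []
        for d, order in (("fwd", range(X.shape[1])), ("bwd", range(X.shape[1] - 1, -1, -1))):
            H = params[f"gru_{d}_Whr"].shape[0]
            h = np.zeros((X.shape[0], H))
            hs = np.zeros((X.shape[0], X.shape[1], H))
            steps = []
            for t in order:
                x_t, m = X[:, t], mask[:, t][:, None]
                r = expit(x_t @ params[f"gru_{d}_Wxr"] + h @ params[f"gru_{d}_Whr"]
                          + params[f"gru_{d}_br"])
                zg = expit(x_t @ params[f"gru_{d}_Wxz"] + h @ params[f"gru_{d}_Whz"]
                           + params[f"gru_{d}_bz"])
                bn = h @ params[f"gru_{d}_Whn"]
                n = np.tanh(x_t @ params[f"gru_{d}_Wxn"] + params[f"gru_{d}_bn"] + r * bn)
                h_new = (1.0 - zg) * n + zg * h
                h_next = m * h_new + (1.0 - m) * h
                steps.append((t, h.copy(), r, zg, bn, n, m))
                h = h_next
                hs[:, t] = h
            states.append(hs)
            gru_caches.append(steps)
        S = np.concatenate(states, axis=2)  # (B,T,2H)
        u = np.tanh(S @ params["attn_W"] + params["attn_b"])  # (B,T,A)
        e = u @ params["attn_v"]  # (B,T)
        e = np.where(mask > 0, e, -np.inf)
        e = e - e.max(axis=1, keepdims=True)
        a = np.exp(e)
        a = a / a.sum(axis=1, keepdims=True)
        ctx = np.einsum("bt,bth->bh", a, S)
        z_in = np.concatenate([h_pre, ctx], axis=1)
        cache.update(X=X, mask=mask, S=S, u=u, a=a, ctx=ctx, gru_caches=gru_caches)
    else:
        z_in = h_pre

    final_pre = z_in @ params["final_W"] + params["final_b"]
    h = _relu(final_pre)
    logits = np.stack(
        [h @ params[f"head{k}_w"] + params[f"head{k}_b"] for k in range(config.n_outcomes)],
        axis=1,
    )
    probs = expit(logits)
    probs = np.clip(probs, EPS, 1.0 - EPS)
    if not return_cache:
        return probs
    cache.update(
        xc=xc, hc_pre=hc_pre, hc=hc, hb_pre=hb_pre, hb=hb, he=he, hh_pre=hh_pre,
        hh=hh, branches=branches, fuse_pre=fuse_pre, h_pre=h_pre, z_in=z_in,
        final_pre=final_pre, h=h, logits=logits, probs=probs, emb_names=emb_names,
    )
    return probs, cache


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Unweighted sum over the 9 outcomes of mean binary cross-entropy."""
    p = np.clip(probs, EPS, 1.0 - EPS)
    per_outcome = -(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)).mean(axis=0)
    return float(per_outcome.sum())


def loss_and_grad(
    params: dict[str, np.ndarray],
    batch: DesignMatrices,
    config: ModelConfig,
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and its gradient w.r.t. every parameter (reverse mode, by hand)."""
    probs, cache = forward(params, batch, config, return_cache=True)
    y = batch.y
    B = probs.shape[0]
    loss = bce_loss(probs, y)
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    dlogits = (probs - y) / B  # (B, 9): BCE + sigmoid shortcut
    h = cache["h"]
    dh = np.zeros_like(h)
    for k in range(config.n_outcomes):
        grads[f"head{k}_w"] = h.T @ dlogits[:, k]
        grads[f"head{k}_b"] = np.array(dlogits[:, k].sum())
        dh += np.outer(dlogits[:, k], params[f"head{k}_w"])

    dfinal_pre = dh * (cache["final_pre"] > 0)
    grads["final_W"] = cache["z_in"].T @ dfinal_pre
    grads["final_b"] = dfinal_pre.sum(axis=0)
    dz_in = dfinal_pre @ params["final_W"].T

    fw = config.fusion_width
    dh_pre = dz_in[:, :fw]
    if config.mode == "perioperative":
        dctx = dz_in[:, fw:]
        S, a, u, mask = cache["S"], cache["a"], cache["u"], cache["mask"]
        da = np.einsum("bh,bth->bt", dctx, S)
        dS = a[:, :, None] * dctx[:, None, :]
        de = a * (da - (a * da).sum(axis=1, keepdims=True))
        de = de * (mask > 0)
        du = de[:, :, None] * params["attn_v"][None, None, :]
        grads["attn_v"] = np.einsum("bt,bta->a", de, u)
        dupre = du * (1.0 - u * u)
        grads["attn_W"] = np.einsum("bth,bta->ha", S, dupre)
        grads["attn_b"] = dupre.sum(axis=(0, 1))
        dS += dupre @ params["attn_W"].T

        X = cache["X"]
        H = params["gru_fwd_Whr"].shape[0]
        for d_i, d in enumerate(("fwd", "bwd")):
            steps = cache["gru_caches"][d_i]
            dSd = dS[:, :, d_i * H : (d_i + 1) * H]
            dh_next = np.zeros((X.shape[0], H))
            for t, h_prev, r, zg, bn, n, m in reversed(steps):
                dht = dh_next + dSd[:, t]
                dh_new = dht * m
                dh_prev = dht * (1.0 - m)
                dzg = dh_new * (h_prev - n)
                dn = dh_new * (1.0 - zg)
                dh_prev += dh_new * zg
                dn_pre = dn * (1.0 - n * n)
                dr = dn_pre * bn
                dbn = dn_pre * r
                dh_prev += dbn @ params[f"gru_{d}_Whn"].T
                grads[f"gru_{d}_Whn"] += h_prev.T @ dbn
                dzg_pre = dzg * zg * (1.0 - zg)
                dr_pre = dr * r * (1.0 - r)
                x_t = X[:, t]
                grads[f"gru_{d}_Wxn"] += x_t.T @ dn_pre
                grads[f"gru_{d}_bn"] += dn_pre.sum(axis=0)
                grads[f"gru_{d}_Wxz"] += x_t.T @ dzg_pre
                grads[f"gru_{d}_Whz"] += h_prev.T @ dzg_pre
                grads[f"gru_{d}_bz"] += dzg_pre.sum(axis=0)
                grads[f"gru_{d}_Wxr"] += x_t.T @ dr_pre
                grads[f"gru_{d}_Whr"] += h_prev.T @ dr_pre
                grads[f"gru_{d}_br"] += dr_pre.sum(axis=0)
                dh_prev += dzg_pre @ params[f"gru_{d}_Whz"].T
                dh_prev += dr_pre @ params[f"gru_{d}_Whr"].T
                dh_next = dh_prev

    dfuse_pre = dh_pre * (cache["fuse_pre"] > 0)
    grads["fuse_W"] = cache["branches"].T @ dfuse_pre
    grads["fuse_b"] = dfuse_pre.sum(axis=0)
    dbranches = dfuse_pre @ params["fuse_W"].T

    cw, bw = config.cont_width, config.bin_width
    dhc = dbranches[:, :cw]
    dhb = dbranches[:, cw : cw + bw]
    dhh = dbranches[:, cw + bw :]

    dhc_pre = dhc * (cache["hc_pre"] > 0)
    grads["cont_W"] = cache["xc"].T @ dhc_pre
    grads["cont_b"] = dhc_pre.sum(axis=0)

    dhb_pre = dhb * (cache["hb_pre"] > 0)
    grads["bin_W"] = batch.x_bin.T @ dhb_pre
    grads["bin_b"] = dhb_pre.sum(axis=0)

    dhh_pre = dhh * (cache["hh_pre"] > 0)
    grads["hc_W"] = cache["he"].T @ dhh_pre
    grads["hc_b"] = dhh_pre.sum(axis=0)
    dhe = dhh_pre @ params["hc_W"].T
    ed = config.embed_dim
    for j, name in enumerate(cache["emb_names"]):
        idx = batch.x_high[:, j]
        np.add.at(grads[name], idx, dhe[:, j * ed : (j + 1) * ed])

    return loss, grads


def predict(
    params: dict[str, np.ndarray],
    batch: DesignMatrices,
    config: ModelConfig,
    batch_size: int = 1024,
) -> np.ndarray:
    """Probabilities for a full cohort, evaluated in chunks."""
    out = []
    for i in range(0, batch.n, batch_size):
        out.append(forward(params, batch.take(np.arange(i, min(i + batch_size, batch.n))),
                           config))
    return np.concatenate(out, axis=0)
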