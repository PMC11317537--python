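"""Customized-gate-control (CGC) multitask regression core.

The model predicts log10 kcat and log10 Km simultaneously from a fused
feature vector x.  Each task k owns m_k specific expert networks and shares
m_s expert networks with the other task.  A per-task gating network

    w^k(x) = Softmax(W_g^k x),        W_g^k in R^{(m_k+m_s) x d}

produces fusion weights over the stacked expert outputs

    S^k(x) = [E_(k,1)(x), ..., E_(k,m_k)(x), E_(s,1)(x), ..., E_(s,m_s)(x)]
    g^k(x) = w^k(x) S^k(x)

and a per-task tower t^k maps g^k(x) to the scalar prediction y^k(x).
Towers use ReLU between hidden layers and an identity output so predictions
can be negative (log10 Km frequently is).  Setting ``n_cgc_layers > 1``
selects the stacked progressive-layered-extraction variant, where
intermediate layers additionally expose a gated shared output that feeds the
next layer's shared experts.

Training minimizes a masked mean-squared error over the observed labels:
entries carrying only one of the two labels contribute nothing to the other
task's loss.  Optimization is Adam; everything (initialization, shuffling,
dropout) is driven by a single seeded generator, so identical seeds give
identical training histories.

The whole network, including backpropagation, is implemented directly in
NumPy: parameters live in a flat name -> array dict and gradients are
accumulated by mirror-image backward passes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .featurize import AuxEncoderSpec, AuxParams, FeatureSet

__all__ = [
    "CGCConfig",
    "CGCModel",
    "TrainHistory",
    "gate_weights",
    "fuse",
    "tower_forward",
    "masked_l2_loss",
    "train",
    "predict_entries",
]

TASKS = ("kcat", "km")


@dataclass
class CGCConfig:
    """Hyperparameters of the multitask core.

    Defaults follow the tuned operating point of the method: 4 specific
    experts per task and 4 shared experts, one affine layer per expert with
    768-d output and dropout 0.2, towers of widths 128/128/1, Adam at 1e-4,
    batch size 1, 50 epochs.  Tests and examples shrink the dimensions; the
    architecture is unchanged.
    """

    input_dim: int
    n_shared_experts: int = 4
    n_specific_experts: int = 4
    expert_layers: int = 1
    expert_dim: int = 768
    expert_dropout: float = 0.2
    tower_dims: Tuple[int, ...] = (128, 128, 1)
    n_cgc_layers: int = 1
    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 50
    seed: int = 0
    tasks: Tuple[str, ...] = TASKS

    def __post_init__(self) -> None:
        if self.tower_dims[-1] != 1:
            raise ValueError("the last tower dimension must be 1 (scalar output)")
        if not 0 <= self.expert_dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        for name in ("input_dim", "expert_dim", "n_cgc_layers", "expert_layers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_shared_experts < 0 or self.n_specific_experts <= 0:
            raise ValueError("need >= 0 shared and >= 1 specific experts")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks: {unknown}")


# ----------------------------------------------------------------------
# standalone operations (also serve as oracles for the batched network)


def gate_weights(x: np.ndarray, W_g: np.ndarray) -> np.ndarray:
    """Softmax gate weights for one input vector; sums to 1."""
    W_g = np.asarray(W_g, dtype=float)
    x = np.asarray(x, dtype=float)
    if W_g.shape[1] != x.shape[0]:
        raise ValueError(
            f"gate matrix expects input dim {W_g.shape[1]}, got {x.shape[0]}"
        )
    logits = W_g @ x
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def fuse(weights: np.ndarray, expert_outputs: np.ndarray) -> np.ndarray:
    """Gate-weighted sum of expert output rows: g = w . S."""
    weights = np.asarray(weights, dtype=float)
    S = np.asarray(expert_outputs, dtype=float)
    if S.shape[0] != weights.shape[0]:
        raise ValueError("one weight per expert row is required")
    return weights @ S


def tower_forward(
    g: np.ndarray, weights: Sequence[np.ndarray], biases: Sequence[np.ndarray]
) -> float:
    """Affine stack with ReLU between hidden layers, identity at the output."""
    a = np.asarray(g, dtype=float)
    last = len(weights) - 1
    for j, (W, b) in enumerate(zip(weights, biases)):
        a = a @ W + b
        if j < last:
            a = np.maximum(a, 0.0)
    return float(a[0]) if a.shape == (1,) else a


def select_matrix(model: "CGCModel", x: np.ndarray, task: str) -> np.ndarray:
    """Stacked expert outputs S^k(x) for one input, eval mode.

    Rows are ordered [specific 1..m_k, shared 1..m_s], matching the ordering
    of the task's gate weights.  Single CGC layer only (layer 0).
    """
    cfg = model.config
    if task not in cfg.tasks:
        raise ValueError(f"unknown task {task!r}")
    x = np.asarray(x, dtype=float)[None, :]
    rows = []
    for g, n_exp in ((task, cfg.n_specific_experts), ("shared", cfg.n_shared_experts)):
        for i in range(n_exp):
            a, _ = _expert_forward(
                model.params, f"L0.exp.{g}.{i}", x, cfg.expert_layers,
                cfg.expert_dropout, train=False, rng=None,
            )
            rows.append(a[0])
    return np.stack(rows, axis=0)


def masked_l2_loss(
    preds: np.ndarray, labels: np.ndarray, label_mask: np.ndarray
) -> float:
    """Mean squared error over the observed labels only."""
    mask = np.asarray(label_mask, dtype=bool)
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise ValueError("masked loss undefined: no observed labels in batch")
    diff = (np.asarray(preds) - np.asarray(labels)) * mask
    return float((diff**2).sum() / n_obs)


# ----------------------------------------------------------------------
# parameter initialization


def _uniform(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _init_params(
    cfg: CGCConfig, aux_spec: AuxEncoderSpec, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    p: Dict[str, np.ndarray] = {}
    aux = AuxParams.init(aux_spec, rng)
    p["aux.w_ph"] = aux.w_ph
    p["aux.w_temp"] = aux.w_temp
    p["aux.org"] = aux.organism_table

    groups = list(cfg.tasks) + ["shared"]
    for l in range(cfg.n_cgc_layers):
        d_in = cfg.input_dim if l == 0 else cfg.expert_dim
        for g in groups:
            n_exp = cfg.n_shared_experts if g == "shared" else cfg.n_specific_experts
            for i in range(n_exp):
                for j in range(cfg.expert_layers):
                    dj = d_in if j == 0 else cfg.expert_dim
                    p[f"L{l}.exp.{g}.{i}.W{j}"] = _uniform(
                        rng, dj, (dj, cfg.expert_dim)
                    )
                    p[f"L{l}.exp.{g}.{i}.b{j}"] = np.zeros(cfg.expert_dim)
        n_task_gate = cfg.n_specific_experts + cfg.n_shared_experts
        for t in cfg.tasks:
            p[f"L{l}.gate.{t}"] = _uniform(rng, d_in, (n_task_gate, d_in))
        if l < cfg.n_cgc_layers - 1:
            n_all = (
                cfg.n_specific_experts * len(cfg.tasks) + cfg.n_shared_experts
            )
            p[f"L{l}.gate.shared"] = _uniform(rng, d_in, (n_all, d_in))

    for t in cfg.tasks:
        dims = (cfg.expert_dim,) + tuple(cfg.tower_dims)
        for j in range(len(dims) - 1):
            p[f"tower.{t}.W{j}"] = _uniform(rng, dims[j], (dims[j], dims[j + 1]))
            p[f"tower.{t}.b{j}"] = np.zeros(dims[j + 1])
    return p


# ----------------------------------------------------------------------
# forward / backward


def _assemble_x(
    p: Dict[str, np.ndarray], fs: FeatureSet, idx: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, dict]:
    """Fused input [enzyme || substrate || aux]; aux uses trainable params."""
    sl = slice(None) if idx is None else idx
    E, S = fs.enzyme[sl], fs.substrate[sl]
    Rp, Rt, org = fs.rbf_ph[sl], fs.rbf_temp[sl], fs.organism_idx[sl]
    aux = Rp @ p["aux.w_ph"] + Rt @ p["aux.w_temp"] + p["aux.org"][org]
    X = np.concatenate([E, S, aux], axis=1)
    cache = {"Rp": Rp, "Rt": Rt, "org": org, "d_e": E.shape[1], "d_s": S.shape[1]}
    return X, cache


def _expert_forward(
    p: Dict[str, np.ndarray],
    prefix: str,
    X: np.ndarray,
    n_layers: int,
    dropout: float,
    train: bool,
    rng: Optional[np.random.Generator],
) -> Tuple[np.ndarray, dict]:
    acts = [X]
    zs = []
    a = X
    for j in range(n_layers):
        z = a @ p[f"{prefix}.W{j}"] + p[f"{prefix}.b{j}"]
        a = np.maximum(z, 0.0)
        zs.append(z)
        acts.append(a)
    mask = None
    if train and dropout > 0:
        mask = rng.random(a.shape) >= dropout
        a = a * mask / (1.0 - dropout)
    return a, {"acts": acts, "zs": zs, "drop": mask, "prefix": prefix}


def _expert_backward(
    p: Dict[str, np.ndarray],
    grads: Dict[str, np.ndarray],
    cache: dict,
    dout: np.ndarray,
    dropout: float,
) -> np.ndarray:
    prefix = cache["prefix"]
    if cache["drop"] is not None:
        dout = dout * cache["drop"] / (1.0 - dropout)
    da = dout
    for j in reversed(range(len(cache["zs"]))):
        dz = da * (cache["zs"][j] > 0)
        grads[f"{prefix}.W{j}"] += cache["acts"][j].T @ dz
        grads[f"{prefix}.b{j}"] += dz.sum(axis=0)
        da = dz @ p[f"{prefix}.W{j}"].T
    return da


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(
    p: Dict[str, np.ndarray],
    cfg: CGCConfig,
    X: np.ndarray,
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, dict]:
    """Full network forward; returns (n, n_tasks) predictions and a cache."""
    groups = list(cfg.tasks) + ["shared"]
    layer_caches = []
    inputs = {g: X for g in groups}
    for l in range(cfg.n_cgc_layers):
        exp_out: Dict[str, List[np.ndarray]] = {}
        exp_cache: Dict[str, List[dict]] = {}
        for g in groups:
            n_exp = cfg.n_shared_experts if g == "shared" else cfg.n_specific_experts
            exp_out[g], exp_cache[g] = [], []
            for i in range(n_exp):
                a, c = _expert_forward(
                    p,
                    f"L{l}.exp.{g}.{i}",
                    inputs[g],
                    cfg.expert_layers,
                    cfg.expert_dropout,
                    train,
                    rng,
                )
                exp_out[g].append(a)
                exp_cache[g].append(c)
        gate_cache: Dict[str, dict] = {}
        outputs: Dict[str, np.ndarray] = {}
        gate_keys = list(cfg.tasks) + (
            ["shared"] if l < cfg.n_cgc_layers - 1 else []
        )
        for gk in gate_keys:
            if gk == "shared":
                rows = [e for t in cfg.tasks for e in exp_out[t]] + exp_out["shared"]
                sources = [
                    (t, i)
                    for t in cfg.tasks
                    for i in range(cfg.n_specific_experts)
                ] + [("shared", i) for i in range(cfg.n_shared_experts)]
            else:
                rows = exp_out[gk] + exp_out["shared"]
                sources = [(gk, i) for i in range(cfg.n_specific_experts)] + [
                    ("shared", i) for i in range(cfg.n_shared_experts)
                ]
            S = np.stack(rows, axis=1)  # (n, E, h)
            logits = inputs[gk] @ p[f"L{l}.gate.{gk}"].T
            w = _softmax_rows(logits)
            outputs[gk] = np.einsum("ne,neh->nh", w, S)
            gate_cache[gk] = {"S": S, "w": w, "sources": sources}
        layer_caches.append(
            {"inputs": inputs, "exp_cache": exp_cache, "gate_cache": gate_cache}
        )
        nxt = {t: outputs[t] for t in cfg.tasks}
        nxt["shared"] = outputs.get("shared", outputs[cfg.tasks[0]])
        inputs = nxt

    # towers
    tower_cache = {}
    preds = np.zeros((X.shape[0], len(cfg.tasks)))
    n_tower = len(cfg.tower_dims)
    for ti, t in enumerate(cfg.tasks):
        a = inputs[t]
        acts, zs = [a], []
        for j in range(n_tower):
            z = a @ p[f"tower.{t}.W{j}"] + p[f"tower.{t}.b{j}"]
            if j < n_tower - 1:
                a = np.maximum(z, 0.0)
            else:
                a = z
            zs.append(z)
            acts.append(a)
        preds[:, ti] = a[:, 0]
        tower_cache[t] = {"acts": acts, "zs": zs}
    cache = {"layers": layer_caches, "towers": tower_cache, "X": X}
    return preds, cache


def _backward(
    p: Dict[str, np.ndarray],
    cfg: CGCConfig,
    cache: dict,
    dpreds: np.ndarray,
) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Mirror of :func:`_forward`; returns (grads, dX)."""
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    groups = list(cfg.tasks) + ["shared"]
    n_tower = len(cfg.tower_dims)

    # towers
    d_fused: Dict[str, np.ndarray] = {}
    for ti, t in enumerate(cfg.tasks):
        tc = cache["towers"][t]
        da = dpreds[:, ti : ti + 1]
        for j in reversed(range(n_tower)):
            dz = da if j == n_tower - 1 else da * (tc["zs"][j] > 0)
            grads[f"tower.{t}.W{j}"] += tc["acts"][j].T @ dz
            grads[f"tower.{t}.b{j}"] += dz.sum(axis=0)
            da = dz @ p[f"tower.{t}.W{j}"].T
        d_fused[t] = da

    d_out = {t: d_fused[t] for t in cfg.tasks}
    d_out["shared"] = None  # final layer has no shared gate

    for l in reversed(range(cfg.n_cgc_layers)):
        lc = cache["layers"][l]
        d_inputs = {g: np.zeros_like(lc["inputs"][g]) for g in groups}
        d_experts: Dict[Tuple[str, int], np.ndarray] = {}
        for gk, gc in lc["gate_cache"].items():
            dout = d_out.get(gk)
            if dout is None:
                continue
            S, w, sources = gc["S"], gc["w"], gc["sources"]
            dw = np.einsum("nh,neh->ne", dout, S)
            dS = w[:, :, None] * dout[:, None, :]
            dlogits = w * (dw - (dw * w).sum(axis=1, keepdims=True))
            grads[f"L{l}.gate.{gk}"] += dlogits.T @ lc["inputs"][gk]
            d_inputs[gk] += dlogits @ p[f"L{l}.gate.{gk}"]
            for e_idx, src in enumerate(sources):
                d_experts[src] = d_experts.get(src, 0) + dS[:, e_idx, :]
        for g in groups:
            for i, ec in enumerate(lc["exp_cache"][g]):
                dE = d_experts.get((g, i))
                if dE is None:
                    continue
                d_inputs[g] += _expert_backward(
                    p, grads, ec, dE, cfg.expert_dropout
                )
        if l == 0:
            dX = sum(d_inputs[g] for g in groups)
        else:
            d_out = {t: d_inputs[t] for t in cfg.tasks}
            d_out["shared"] = d_inputs["shared"]
    return grads, dX


def _aux_backward(
    grads: Dict[str, np.ndarray], x_cache: dict, dX: np.ndarray
) -> None:
    d_e, d_s = x_cache["d_e"], x_cache["d_s"]
    daux = dX[:, d_e + d_s :]
    grads["aux.w_ph"] += x_cache["Rp"].T @ daux
    grads["aux.w_temp"] += x_cache["Rt"].T @ daux
    np.add.at(grads["aux.org"], x_cache["org"], daux)


# ----------------------------------------------------------------------
# model object, training, prediction


@dataclass
class TrainHistory:
    """Per-epoch losses and validation metrics; one row per completed epoch."""

    epochs: List[int] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_metrics: List[Dict[str, Dict[str, float]]] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ep in enumerate(self.epochs):
            row = {"epoch": ep, "train_loss": self.train_loss[i],
                   "val_loss": self.val_loss[i]}
            for task, ms in self.val_metrics[i].items():
                for name, v in ms.items():
                    row[f"val_{task}_{name}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CGCModel:
    """A trained (or freshly initialized) multitask core."""

    config: CGCConfig
    aux_spec: AuxEncoderSpec
    params: Dict[str, np.ndarray]

    @classmethod
    def init(cls, config: CGCConfig, aux_spec: AuxEncoderSpec) -> "CGCModel":
        rng = np.random.default_rng(config.seed)
        return cls(config, aux_spec, _init_params(config, aux_spec, rng))

    def forward(self, fs: FeatureSet) -> np.ndarray:
        """Eval-mode predictions, shape (n, n_tasks); deterministic."""
        if fs.input_dim != self.config.input_dim:
            raise ValueError(
                f"model expects input dim {self.config.input_dim}, "
                f"features have {fs.input_dim}"
            )
        X, _ = _assemble_x(self.params, fs)
        preds, _ = _forward(self.params, self.config, X, train=False)
        return preds

    def task_columns(self) -> List[int]:
        return [TASKS.index(t) for t in self.config.tasks]


def _eval_loss_metrics(
    model_p: Dict[str, np.ndarray], cfg: CGCConfig, fs: FeatureSet
) -> Tuple[float, Dict[str, Dict[str, float]]]:
    from .evalsplit import pcc, r2, rmse

    X, _ = _assemble_x(model_p, fs)
    preds, _ = _forward(model_p, cfg, X, train=False)
    cols = [TASKS.index(t) for t in cfg.tasks]
    loss = masked_l2_loss(preds, fs.labels[:, cols], fs.label_mask[:, cols])
    metrics: Dict[str, Dict[str, float]] = {}
    for ti, t in enumerate(cfg.tasks):
        m = fs.label_mask[:, cols[ti]]
        if m.sum() < 2:
            continue
        ye, yp = fs.labels[m, cols[ti]], preds[m, ti]
        entry = {"rmse": rmse(ye, yp)}
        if np.std(ye) > 0:
            entry["r2"] = r2(ye, yp)
            if np.std(yp) > 0:
                entry["pcc"] = pcc(ye, yp)
        metrics[t] = entry
    return loss, metrics


def train(
    train_fs: FeatureSet,
    val_fs: FeatureSet,
    config: CGCConfig,
) -> Tuple[CGCModel, TrainHistory]:
    """Adam training with masked L2 loss; returns best-validation parameters.

    The caller supplies the train/validation split.  Model selection keeps
    the epoch with the lowest validation loss (earliest on ties).
    """
    if len(train_fs) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    p = _init_params(config, train_fs.spec, rng)
    cols = [TASKS.index(t) for t in config.tasks]

    # Adam state
    m_state = {k: np.zeros_like(v) for k, v in p.items()}
    v_state = {k: np.zeros_like(v) for k, v in p.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = TrainHistory()
    best_loss = np.inf
    best_params = copy.deepcopy(p)
    n = len(train_fs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            y = train_fs.labels[idx][:, cols]
            mask = train_fs.label_mask[idx][:, cols]
            n_obs = mask.sum()
            if n_obs == 0:
                continue
            X, x_cache = _assemble_x(p, train_fs, idx)
            preds, cache = _forward(p, config, X, train=True, rng=rng)
            dpreds = 2.0 * (preds - y) * mask / n_obs
            grads, dX = _backward(p, config, cache, dpreds)
            _aux_backward(grads, x_cache, dX)
            step += 1
            lr_t = config.learning_rate * (
                np.sqrt(1 - beta2**step) / (1 - beta1**step)
            )
            for k in p:
                g = grads[k]
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                p[k] -= lr_t * m_state[k] / (np.sqrt(v_state[k]) + eps)

        train_loss, _ = _eval_loss_metrics(p, config, train_fs)
        val_loss, val_metrics = _eval_loss_metrics(p, config, val_fs)
        history.epochs.append(epoch)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.val_metrics.append(val_metrics)
        if val_loss < best_loss:
            best_loss = val_loss
            history.best_epoch = epoch
            best_params = copy.deepcopy(p)

    return CGCModel(config, train_fs.spec, best_params), history


def predict_entries(model: CGCModel, fs: FeatureSet) -> pd.DataFrame:
    """Predictions table: log10 and linear-scale values plus efficiency.

    Efficiency is log10(kcat/Km) = log10 kcat - log10 Km; the linear-scale
    columns are 10**log10 and therefore strictly positive.
    """
    preds = model.forward(fs)
    out = pd.DataFrame(
        {
            "canonical_smiles": [k[0] for k in fs.keys],
            "sequence": [k[1] for k in fs.keys],
            "ph": [k[2] for k in fs.keys],
            "temperature": [k[3] for k in fs.keys],
            "organism": [k[4] for k in fs.keys],
        }
    )
    for ti, t in enumerate(model.config.tasks):
        out[f"pred_log10_{t}"] = preds[:, ti]
        out[f"pred_{t}"] = 10.0 ** preds[:, ti]
    if {"kcat", "km"} <= set(model.config.tasks):
        out["pred_log10_efficiency"] = (
            out["pred_log10_kcat"] - out["pred_log10_km"]
        )
    return out


# ----------------------------------------------------------------------
# model persistence


def save_model(model: CGCModel, directory) -> None:
    """Model artifact: JSON metadata + a NumPy parameter archive."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": {
            **{k: v for k, v in model.config.__dict__.items()},
            "tower_dims": list(model.config.tower_dims),
            "tasks": list(model.config.tasks),
        },
        "aux_spec": model.aux_spec.to_dict(),
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    np.savez(directory / "params.npz", **model.params)


def load_model(directory) -> CGCModel:
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    cfg_d = meta["config"]
    cfg_d["tower_dims"] = tuple(cfg_d["tower_dims"])
    cfg_d["tasks"] = tuple(cfg_d["tasks"])
    config = CGCConfig(**cfg_d)
    aux_spec = AuxEncoderSpec.from_dict(meta["aux_spec"])
    with np.load(directory / "params.npz") as z:
        params = {k: z[k] for k in z.files}
    return CGCModel(config, aux_spec, params)
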