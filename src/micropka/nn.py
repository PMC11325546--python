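"""Graph neural network building blocks on the autodiff engine.

Three message-passing families are available, mirroring the usual taxonomy:

* ``gcn`` — symmetric-normalized graph convolution with a separate
  self-connection weight.
* ``gat`` — single-head additive attention over neighbors.
* ``transformer`` — scaled dot-product attention over neighbors with a
  residual self term.

Molecules are small (tens of atoms), so attention works on dense N x N
matrices masked by the bond structure; the adjacency used for aggregation
is weighted by the Wiberg bond order, which lets the models consume the
continuous bond-strength signal alongside the node features.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .graphs import DEFAULT_SCHEMA, MolGraph

GNN_FAMILIES = ("gcn", "gat", "transformer")


# ---------------------------------------------------------------------------
# graph preprocessing


def graph_inputs(g: MolGraph) -> dict:
    """Constant model inputs for one graph: X (N,61), norm adjacency, mask.

    Cached on the graph object — graphs are reused across epochs.
    """
    cached = getattr(g, "_nn_cache", None)
    if cached is not None:
        return cached
    n = g.n_atoms
    A = np.zeros((n, n))
    if g.edge_index.shape[1]:
        wiberg = g.edge_features[-1]  # last edge block is the Wiberg order
        A[g.edge_index[0], g.edge_index[1]] = wiberg
    A_loop = A + np.eye(n)
    d = A_loop.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    S = dinv[:, None] * A_loop * dinv[None, :]
    mask = (A_loop > 0).astype(float)
    out = {
        "X": g.node_features.T.copy(),       # (N, 61)
        "S": S,                              # normalized weighted adjacency
        "mask": mask,                        # neighbor mask incl. self loops
        "mol": g.mol_features.copy(),
    }
    g._nn_cache = out
    return out


# ---------------------------------------------------------------------------
# parameter containers


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-s, s, size=(n_in, n_out))


class ParamStore:
    """Flat name -> Tensor parameter dictionary."""

    def __init__(self):
        self.params: Dict[str, Tensor] = {}

    def add(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self.params[name] = t
        return t

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = np.array(state[k], dtype=np.float64)

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, store: ParamStore, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.store = store
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in store.params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in store.params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.store.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# encoders


class GraphEncoder:
    """Stack of message-passing layers from one of the three families."""

    def __init__(self, store: ParamStore, prefix: str, family: str,
                 in_dim: int, hidden: int, n_layers: int,
                 rng: np.random.Generator):
        if family not in GNN_FAMILIES:
            raise ValueError(f"unknown GNN family {family!r}")
        self.family = family
        self.n_layers = n_layers
        self.hidden = hidden
        self.p = {}
        dim = in_dim
        for layer in range(n_layers):
            pre = f"{prefix}.l{layer}"
            self.p[f"{pre}.W"] = store.add(f"{pre}.W", _glorot(rng, dim, hidden))
            self.p[f"{pre}.Wself"] = store.add(f"{pre}.Wself", _glorot(rng, dim, hidden))
            self.p[f"{pre}.b"] = store.add(f"{pre}.b", np.zeros((1, hidden)))
            if family == "gat":
                self.p[f"{pre}.a_src"] = store.add(f"{pre}.a_src",
                                                   _glorot(rng, hidden, 1))
                self.p[f"{pre}.a_dst"] = store.add(f"{pre}.a_dst",
                                                   _glorot(rng, hidden, 1))
            elif family == "transformer":
                self.p[f"{pre}.Wq"] = store.add(f"{pre}.Wq", _glorot(rng, dim, hidden))
                self.p[f"{pre}.Wk"] = store.add(f"{pre}.Wk", _glorot(rng, dim, hidden))
            dim = hidden
        self.prefix = prefix

    def forward(self, X: Tensor, S: np.ndarray, mask: np.ndarray) -> Tensor:
        S_t = Tensor(S)
        neg = Tensor((1.0 - mask) * -1e9)
        mask_t = Tensor(mask)
        H = X
        for layer in range(self.n_layers):
            pre = f"{self.prefix}.l{layer}"
            W, Wself, b = (self.p[f"{pre}.W"], self.p[f"{pre}.Wself"],
                           self.p[f"{pre}.b"])
            HW = H @ W
            if self.family == "gcn":
                agg = S_t @ HW
            elif self.family == "gat":
                s_src = HW @ self.p[f"{pre}.a_src"]      # (N,1)
                s_dst = HW @ self.p[f"{pre}.a_dst"]      # (N,1)
                scores = (s_src + s_dst.T).leaky_relu(0.2)
                att = (scores * mask_t + neg).softmax(axis=-1)
                agg = att @ HW
            else:  # transformer
                Q = H @ self.p[f"{pre}.Wq"]
                K = H @ self.p[f"{pre}.Wk"]
                scores = (Q @ K.T) * (1.0 / np.sqrt(self.hidden))
                att = (scores * mask_t + neg).softmax(axis=-1)
                agg = att @ HW
            H = (agg + H @ Wself + b).relu()
        return H


class MLP:
    """Dense head: hidden layers with ReLU, linear output."""

    def __init__(self, store: ParamStore, prefix: str, dims: Sequence[int],
                 rng: np.random.Generator):
        self.p = {}
        self.n = len(dims) - 1
        for k in range(self.n):
            self.p[f"{prefix}.W{k}"] = store.add(f"{prefix}.W{k}",
                                                 _glorot(rng, dims[k], dims[k + 1]))
            self.p[f"{prefix}.b{k}"] = store.add(f"{prefix}.b{k}",
                                                 np.zeros((1, dims[k + 1])))
        self.prefix = prefix

    def forward(self, x: Tensor) -> Tensor:
        for k in range(self.n):
            x = x @ self.p[f"{self.prefix}.W{k}"] + self.p[f"{self.prefix}.b{k}"]
            if k < self.n - 1:
                x = x.relu()
        return x


# ---------------------------------------------------------------------------
# losses


def bce_with_logits(z: Tensor, y: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Numerically stable binary cross-entropy on logits.

    ``loss_i = w_i * (max(z,0) - z*y + log(1 + exp(-|z|)))`` with
    ``w_i = pos_weight`` for positive atoms, 1 otherwise.
    """
    y_t = Tensor(y.reshape(z.shape))
    w = Tensor(np.where(y.reshape(z.shape) > 0.5, pos_weight, 1.0))
    abs_z = z.relu() + (-z).relu()
    loss = z.relu() - z * y_t + ((-abs_z).exp() + 1.0).log()
    return (loss * w).sum() / float(z.data.size)


# ---------------------------------------------------------------------------
# dataset splitting


def split_by_molecule(ids: Sequence[str], seed: int,
                      fractions: Tuple[float, ...] = (0.8, 0.1, 0.1)):
    """Partition unique molecule ids into seeded splits (default 80:10:10).

    Returns one set of ids per fraction.  Records sharing an id always land
    in the same partition, so splitting a per-site dataset by molecule needs
    no extra bookkeeping.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    uniq = sorted(set(ids))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    bounds = np.cumsum([int(round(f * len(uniq))) for f in fractions[:-1]])
    parts = np.split(order, bounds)
    return tuple({uniq[i] for i in part} for part in parts)


# ---------------------------------------------------------------------------
# training driver


@dataclass
class TrainResult:
    history: List[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")


def fit(store: ParamStore, loss_fn, train_items: list, val_items: list,
        *, epochs: int, lr: float, patience: int, seed: int,
        batch_size: int = 8) -> TrainResult:
    """Generic seeded training loop with early stopping on validation loss.

    ``loss_fn(item) -> Tensor`` evaluates one example's loss; gradients are
    accumulated over mini-batches.  The best-validation parameters are
    restored before returning.  ``epochs == 0`` leaves the parameters
    untouched (explicit no-op boundary used by fine-tuning tests).
    """
    result = TrainResult()
    if epochs == 0 or not train_items:
        if epochs > 0 and not train_items:
            raise ValueError("empty training partition")
        result.best_epoch = 0
        return result
    if not val_items:
        raise ValueError("empty validation partition")
    opt = Adam(store, lr=lr)
    rng = np.random.default_rng(seed)
    best_state = store.state_dict()

    def val_loss() -> float:
        with no_grad():
            return float(np.mean([loss_fn(it).data for it in val_items]))

    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(train_items))
        train_losses = []
        for start in range(0, len(order), batch_size):
            batch = order[start:start + batch_size]
            store.zero_grad()
            total = None
            for idx in batch:
                l = loss_fn(train_items[idx])
                total = l if total is None else total + l
            total = total / float(len(batch))
            total.backward()
            opt.step()
            train_losses.append(float(total.data))
        vl = val_loss()
        result.history.append({"epoch": epoch,
                               "train_loss": float(np.mean(train_losses)),
                               "val_loss": vl})
        if vl < result.best_val_loss - 1e-9:
            result.best_val_loss = vl
            result.best_epoch = epoch
            best_state = store.state_dict()
        elif epoch - result.best_epoch >= patience:
            break
    store.load_state_dict(best_state)
    return result


# ---------------------------------------------------------------------------
# serialization


def save_model(path, store: ParamStore, meta: dict) -> None:
    """Write parameters (.npz) and a JSON sidecar with config/provenance."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **store.state_dict())
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=str))


def load_model_arrays(path) -> Tuple[Dict[str, np.ndarray], dict]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        state = {k: z[k] for k in z.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    return state, meta
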