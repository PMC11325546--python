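"""Per-site micro-pKa regression on paired molecular graphs.

A pair couples the protonated and deprotonated forms of one reaction site.
Both graphs pass through a (weight-shared) GNN encoder and global mean
pooling; the pooled vectors and both molecular feature vectors — including
the protonation energy difference — are concatenated and regressed to a
single pKa by a dense head.

Training follows the two-stage recipe: pretrain on a large weakly labeled
pair set (80:10:10 split by molecule), then fine-tune the same weights on a
small experimental-style set (80:20 split).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .autodiff import Tensor, concat, no_grad
from .chem_io import MolRecord
from .graphs import DEFAULT_SCHEMA, FeatureSchema, MolGraph, featurize_pair
from .nn import (GraphEncoder, MLP, ParamStore, fit, graph_inputs,
                 split_by_molecule)
from .sites import SiteLabelSet

log = logging.getLogger("micropka")


@dataclass
class PairExample:
    """One reaction site as a (protonated, deprotonated) graph pair.

    ``reaction`` follows the acid/base convention: "acidic" is the removal
    of a proton from the neutral form; "basic" is the protonation of the
    neutral base.
    """

    mol_id: str
    atom_index: int
    reaction: str                   # "acidic" | "basic"
    graph_prot: MolGraph
    graph_deprot: MolGraph
    target_pka: Optional[float] = None

    def validate(self) -> None:
        if self.graph_prot.n_atoms != self.graph_deprot.n_atoms + 1:
            raise ValueError("protonated graph must have exactly one extra atom")
        if self.graph_prot.mol_features[-1] != self.graph_deprot.mol_features[-1]:
            raise ValueError("pair graphs disagree on the protonation energy")


@dataclass
class PkaModelConfig:
    gnn_family: str = "gcn"
    n_gnn_layers: int = 3
    hidden_width: int = 32
    n_linear_layers: int = 2
    share_encoder: bool = True
    lr: float = 5e-3
    batch_size: int = 16
    seed: int = 0


@dataclass
class TrainPlan:
    """Split fractions, rates and stopping rules for the two stages."""

    pretrain_fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    finetune_fractions: Tuple[float, float] = (0.8, 0.2)
    pretrain_epochs: int = 60
    finetune_epochs: int = 60
    patience: int = 8
    pretrain_lr: float = 5e-3
    finetune_lr: float = 1e-3
    split_seed: int = 0


class PkaModel:
    """Paired-graph regression model with global mean pooling."""

    def __init__(self, config: PkaModelConfig = PkaModelConfig(),
                 schema: FeatureSchema = DEFAULT_SCHEMA):
        self.config = config
        self.schema_hash = schema.hash()
        self.store = ParamStore()
        rng = np.random.default_rng(config.seed)
        c = config
        self.enc_prot = GraphEncoder(self.store, "enc_p", c.gnn_family, 61,
                                     c.hidden_width, c.n_gnn_layers, rng)
        if c.share_encoder:
            self.enc_deprot = self.enc_prot
        else:
            self.enc_deprot = GraphEncoder(self.store, "enc_d", c.gnn_family, 61,
                                           c.hidden_width, c.n_gnn_layers, rng)
        mol_dim = schema.mol_dim
        # n_gnn_layers == 0 leaves the encoder as the identity on the 61
        # node features (used by linear-probe attribution tests)
        enc_out = c.hidden_width if c.n_gnn_layers > 0 else 61
        head_in = 2 * enc_out + 2 * mol_dim
        dims = [head_in] + [c.hidden_width] * max(c.n_linear_layers - 1, 0) + [1]
        self.head = MLP(self.store, "head", dims, rng)
        self.provenance: List[dict] = []

    # -- forward ----------------------------------------------------------
    def _forward_tensors(self, Xp: Tensor, Sp, mp, molp: Tensor,
                         Xd: Tensor, Sd, md, mold: Tensor) -> Tensor:
        hp = self.enc_prot.forward(Xp, Sp, mp).mean(axis=0, keepdims=True)
        hd = self.enc_deprot.forward(Xd, Sd, md).mean(axis=0, keepdims=True)
        z = concat([hp, hd, molp, mold], axis=1)
        return self.head.forward(z)

    def forward(self, pair: PairExample) -> Tensor:
        for g in (pair.graph_prot, pair.graph_deprot):
            if g.schema_hash != self.schema_hash:
                raise ValueError("feature-schema hash mismatch")
        ip, id_ = graph_inputs(pair.graph_prot), graph_inputs(pair.graph_deprot)
        return self._forward_tensors(
            Tensor(ip["X"]), ip["S"], ip["mask"], Tensor(ip["mol"][None, :]),
            Tensor(id_["X"]), id_["S"], id_["mask"], Tensor(id_["mol"][None, :]))

    def predict(self, pair: PairExample) -> float:
        with no_grad():
            return float(self.forward(pair).data.item())

    def clone(self) -> "PkaModel":
        """Independent copy with identical weights and provenance."""
        other = PkaModel(PkaModelConfig(**self.config.__dict__))
        other.schema_hash = self.schema_hash
        other.store.load_state_dict(self.store.state_dict())
        other.provenance = [dict(p) for p in self.provenance]
        return other

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        from .nn import save_model

        save_model(path, self.store, {
            "kind": "pka", "schema_hash": self.schema_hash,
            "config": self.config.__dict__, "provenance": self.provenance,
        })

    @classmethod
    def load(cls, path) -> "PkaModel":
        from .nn import load_model_arrays

        state, meta = load_model_arrays(path)
        model = cls(PkaModelConfig(**meta["config"]))
        model.schema_hash = meta["schema_hash"]
        model.store.load_state_dict(state)
        model.provenance = meta.get("provenance", [])
        return model


# ---------------------------------------------------------------------------
# pair construction


def build_pairs(rec: MolRecord, site_labels: Tuple[SiteLabelSet, SiteLabelSet],
                backend="mock", schema: FeatureSchema = DEFAULT_SCHEMA,
                targets: Optional[Dict[Tuple[int, str], float]] = None
                ) -> List[PairExample]:
    """Expand site labels of the (neutral) selected tautomer into pairs.

    Deprotonation labels give *acidic* pairs (neutral molecule is the
    protonated form); protonation labels give *basic* pairs (neutral
    molecule is the deprotonated form).  Pairs whose edited product fails
    the structural-change filter are dropped with a warning.  ``targets``
    optionally maps (atom_index, reaction) to a label pKa.
    """
    from .qm import get_backend
    from .sites import SiteEditError, deprotonate_at, protonate_at, \
        structural_change_filter

    if isinstance(backend, str):
        backend = get_backend(backend)
    prot_labels, deprot_labels = site_labels
    pairs: List[PairExample] = []
    qm_cache: Dict[str, object] = {}

    def qm_of(r):
        if r.id not in qm_cache:
            qm_cache[r.id] = backend.compute(r)
        return qm_cache[r.id]

    for lbl, reaction in ((deprot_labels, "acidic"), (prot_labels, "basic")):
        for idx in np.flatnonzero(lbl.labels):
            idx = int(idx)
            try:
                if reaction == "acidic":
                    product = deprotonate_at(rec, idx)
                    rec_p, rec_d = rec, product
                else:
                    product = protonate_at(rec, idx)
                    rec_p, rec_d = product, rec
            except SiteEditError as exc:
                log.warning("pka: %s site %d dropped (%s)", rec.id, idx, exc)
                continue
            if not structural_change_filter(rec_d, rec_p, "protonation"):
                log.warning("pka: %s site %d dropped (structural change)",
                            rec.id, idx)
                continue
            g_p, g_d = featurize_pair((rec_p, qm_of(rec_p)), (rec_d, qm_of(rec_d)),
                                      schema)
            pairs.append(PairExample(
                mol_id=rec.id, atom_index=idx, reaction=reaction,
                graph_prot=g_p, graph_deprot=g_d,
                target_pka=None if targets is None
                else targets.get((idx, reaction)),
            ))
    return pairs


# ---------------------------------------------------------------------------
# training


def _mse_loss(model: PkaModel):
    def loss_fn(pair: PairExample):
        err = model.forward(pair) - Tensor(np.array([[pair.target_pka]]))
        return (err * err).sum()

    return loss_fn


def pretrain(model: PkaModel, weak_dataset: Sequence[PairExample],
             plan: TrainPlan = TrainPlan()) -> PkaModel:
    """Stage 1: train on the large weak-label pair set (80:10:10 split)."""
    ids = [p.mol_id for p in weak_dataset]
    tr, va, te = split_by_molecule(ids, plan.split_seed, plan.pretrain_fractions)
    train = [p for p in weak_dataset if p.mol_id in tr]
    val = [p for p in weak_dataset if p.mol_id in va]
    test = [p for p in weak_dataset if p.mol_id in te]
    if not train or not val:
        raise ValueError("a pretraining partition is empty")
    result = fit(model.store, _mse_loss(model), train, val,
                 epochs=plan.pretrain_epochs, lr=plan.pretrain_lr,
                 patience=plan.patience, seed=model.config.seed + 11,
                 batch_size=model.config.batch_size)
    metrics = {}
    if test:
        preds = [model.predict(p) for p in test]
        truths = [p.target_pka for p in test]
        rmse, mae, r2 = evaluate(preds, truths)
        metrics = {"test_rmse": rmse, "test_mae": mae, "test_r2": r2,
                   "n_test": len(test)}
    model.provenance.append({
        "stage": "pretrain", "n_train": len(train), "n_val": len(val),
        "best_epoch": result.best_epoch, "best_val_loss": result.best_val_loss,
        "history": result.history, **metrics,
    })
    return model


def finetune(model: PkaModel, experimental_dataset: Sequence[PairExample],
             plan: TrainPlan = TrainPlan()) -> PkaModel:
    """Stage 2: fine-tune pretrained weights on experimental pairs (80:20)."""
    if not any(p["stage"] == "pretrain" for p in model.provenance):
        raise ValueError("finetune requires a pretrained model")
    ids = [p.mol_id for p in experimental_dataset]
    tr, va = split_by_molecule(ids, plan.split_seed + 1, plan.finetune_fractions)
    train = [p for p in experimental_dataset if p.mol_id in tr]
    val = [p for p in experimental_dataset if p.mol_id in va]
    result = fit(model.store, _mse_loss(model), train, val,
                 epochs=plan.finetune_epochs, lr=plan.finetune_lr,
                 patience=plan.patience, seed=model.config.seed + 23,
                 batch_size=model.config.batch_size)
    model.provenance.append({
        "stage": "finetune", "n_train": len(train), "n_val": len(val),
        "best_epoch": result.best_epoch, "best_val_loss": result.best_val_loss,
        "history": result.history,
    })
    return model


def train_from_scratch(config: PkaModelConfig,
                       experimental_dataset: Sequence[PairExample],
                       plan: TrainPlan = TrainPlan()) -> PkaModel:
    """Ablation baseline: same architecture, experimental data only."""
    model = PkaModel(config)
    ids = [p.mol_id for p in experimental_dataset]
    tr, va = split_by_molecule(ids, plan.split_seed + 1, plan.finetune_fractions)
    train = [p for p in experimental_dataset if p.mol_id in tr]
    val = [p for p in experimental_dataset if p.mol_id in va]
    result = fit(model.store, _mse_loss(model), train, val,
                 epochs=plan.finetune_epochs, lr=plan.pretrain_lr,
                 patience=plan.patience, seed=config.seed + 23,
                 batch_size=config.batch_size)
    model.provenance.append({
        "stage": "scratch", "n_train": len(train), "n_val": len(val),
        "best_epoch": result.best_epoch, "best_val_loss": result.best_val_loss,
    })
    return model


# ---------------------------------------------------------------------------
# evaluation


def evaluate(predictions: Sequence[float], truths: Sequence[float]
             ) -> Tuple[float, float, float]:
    """(RMSE, MAE, R^2) with R^2 the coefficient of determination.

    Zero-variance truths make R^2 undefined; it is returned as NaN.
    """
    from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

    if len(predictions) != len(truths):
        raise ValueError("prediction/truth length mismatch")
    if len(predictions) == 0:
        raise ValueError("empty evaluation set")
    p, t = np.asarray(predictions, float), np.asarray(truths, float)
    rmse = float(np.sqrt(mean_squared_error(t, p)))
    mae = float(mean_absolute_error(t, p))
    r2 = float("nan") if np.var(t) == 0 else float(r2_score(t, p))
    return rmse, mae, r2


_FPGEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def max_tanimoto(query: MolRecord, reference: Sequence[MolRecord]) -> float:
    """Largest Tanimoto coefficient between query and any reference.

    Circular (Morgan) fingerprints, radius 2, 2048 bits.  Used for
    train/test overlap screening at the 0.8 threshold.
    """
    if not reference:
        raise ValueError("empty reference set")
    fq = _FPGEN.GetFingerprint(Chem.MolFromSmiles(query.smiles_canonical))
    best = 0.0
    for r in reference:
        fr = _FPGEN.GetFingerprint(Chem.MolFromSmiles(r.smiles_canonical))
        best = max(best, DataStructs.TanimotoSimilarity(fq, fr))
    return best


# ---------------------------------------------------------------------------
# attribution


def integrated_gradients(model: PkaModel, pair: PairExample,
                         baseline: Optional[PairExample] = None,
                         steps: int = 128) -> dict:
    """Integrated-gradients attribution of the predicted pKa.

    Integrates the input gradient along the straight path from a baseline
    pair (default: all-zero features on the same topology) using a
    midpoint Riemann sum, then multiplies by (input - baseline).  Satisfies
    completeness: attributions sum to f(input) - f(baseline) as steps grow
    (exactly, for linear models).

    Returns per-feature attribution arrays for both graphs' node features
    and molecular features, plus per-node-block aggregates.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    ip, id_ = graph_inputs(pair.graph_prot), graph_inputs(pair.graph_deprot)
    inputs = {"Xp": ip["X"], "molp": ip["mol"][None, :],
              "Xd": id_["X"], "mold": id_["mol"][None, :]}
    if baseline is None:
        base = {k: np.zeros_like(v) for k, v in inputs.items()}
    else:
        bp, bd = graph_inputs(baseline.graph_prot), graph_inputs(baseline.graph_deprot)
        base = {"Xp": bp["X"], "molp": bp["mol"][None, :],
                "Xd": bd["X"], "mold": bd["mol"][None, :]}
        if any(base[k].shape != inputs[k].shape for k in inputs):
            raise ValueError("baseline shapes do not match input shapes")

    grads = {k: np.zeros_like(v) for k, v in inputs.items()}
    for k_step in range(steps):
        alpha = (k_step + 0.5) / steps
        ts = {k: Tensor(base[k] + alpha * (inputs[k] - base[k]),
                        requires_grad=True) for k in inputs}
        out = model._forward_tensors(ts["Xp"], ip["S"], ip["mask"], ts["molp"],
                                     ts["Xd"], id_["S"], id_["mask"], ts["mold"])
        out.backward()
        for k in grads:
            grads[k] += ts[k].grad
    attr = {k: (inputs[k] - base[k]) * grads[k] / steps for k in inputs}

    rows = DEFAULT_SCHEMA.node_block_rows()
    by_block = {
        name: float(attr["Xp"][:, sl].sum() + attr["Xd"][:, sl].sum())
        for name, sl in rows.items()
    }
    for i, (name, _) in enumerate(DEFAULT_SCHEMA.mol_blocks):
        by_block[f"mol:{name}"] = float(attr["molp"][0, i] + attr["mold"][0, i])
    attr["by_block"] = by_block
    attr["total"] = float(sum(a.sum() for k, a in attr.items()
                              if k in ("Xp", "Xd", "molp", "mold")))
    return attr
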