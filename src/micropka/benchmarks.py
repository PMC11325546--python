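"""Reproducible evaluation protocols on the synthetic benchmark.

These drive both the regression tests and the standalone evaluation script.
Problem sizes are the package's reference study conditions: 500 molecules
for the site classifiers, 2,000 noiseless weak-label pairs for pKa
pretraining, and 200 experimental-style pairs (noise 0.3 pKa units, +0.75
systematic offset) for the transfer-learning comparison over five seeds.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .chem_io import invert_stereocenters
from .graphs import featurize
from .pka import (PkaModel, PkaModelConfig, TrainPlan, build_pairs, evaluate,
                  finetune, integrated_gradients, pretrain,
                  train_from_scratch)
from .qm import get_backend
from .sites import SiteModelConfig, oracle_label, train_site_model
from .synthetic import (SyntheticSpec, assign_labels, gen_chiral_library,
                        gen_library, make_benchmark)

log = logging.getLogger("micropka")

SITE_N_MOLECULES = 500
WEAK_N_PAIRS = 2000
EXP_N_PAIRS = 200
TRANSFER_N_SEEDS = 5


def site_model_benchmark(seed: int = 0, n_molecules: int = SITE_N_MOLECULES,
                         epochs: int = 40) -> Dict[str, float]:
    """Train both site classifiers on an oracle-labeled synthetic library.

    Returns held-out per-atom accuracies (fractions in [0, 1]).
    """
    backend = get_backend("mock")
    spec = SyntheticSpec(n_molecules=n_molecules, seed=seed, noise_sd=0.0)
    lib = gen_library(spec)
    data = {"protonation": [], "deprotonation": []}
    for rec in lib:
        prot, deprot, _ = assign_labels(rec, spec, backend)
        g = featurize(rec, backend.compute(rec))
        data["protonation"].append((g, prot))
        data["deprotonation"].append((g, deprot))
    out = {}
    for reaction, dataset in data.items():
        cfg = SiteModelConfig(epochs=epochs, seed=seed)
        model = train_site_model(dataset, cfg)
        out[f"{reaction}_accuracy"] = model.test_accuracy
        out[f"{reaction}_model"] = model
    return out


def build_pka_benchmark(seed: int = 0,
                        n_weak_pairs: int = WEAK_N_PAIRS,
                        n_exp_pairs: int = EXP_N_PAIRS):
    """Weak (noiseless) and experimental-style (noisy, offset) pair sets."""
    spec_weak = SyntheticSpec(n_molecules=2400, seed=seed, noise_sd=0.0)
    spec_exp = SyntheticSpec(n_molecules=400, seed=seed + 9000, noise_sd=0.3,
                             label_offset=0.75)
    return make_benchmark(spec_weak, spec_exp, n_weak_pairs=n_weak_pairs,
                          n_exp_pairs=n_exp_pairs)


def pretrain_benchmark(weak_pairs, seed: int = 0,
                       epochs: int = 40) -> Tuple[PkaModel, Dict[str, float]]:
    """Pretrain on the weak pairs; report held-out (10% split) metrics."""
    model = PkaModel(PkaModelConfig(seed=seed))
    plan = TrainPlan(pretrain_epochs=epochs, patience=8, split_seed=seed)
    pretrain(model, weak_pairs, plan)
    stage = model.provenance[-1]
    return model, {"rmse": stage["test_rmse"], "mae": stage["test_mae"],
                   "r2": stage["test_r2"], "n_test": stage["n_test"]}


def transfer_benchmark(pretrained: PkaModel, exp_pairs,
                       seeds: Sequence[int] = range(TRANSFER_N_SEEDS),
                       epochs: int = 40) -> Dict[str, float]:
    """Fine-tuned versus trained-from-scratch on the experimental pairs.

    For each seed the 80:20 split is shared by both arms; the reported
    numbers are the mean validation RMSEs across seeds.
    """
    from .nn import split_by_molecule

    ft_rmses, sc_rmses = [], []
    for s in seeds:
        plan = TrainPlan(finetune_epochs=epochs, patience=8, split_seed=int(s))
        ft = finetune(pretrained.clone(), exp_pairs, plan)
        cfg = PkaModelConfig(**{**pretrained.config.__dict__, "seed": int(s)})
        sc = train_from_scratch(cfg, exp_pairs, plan)
        _, va = split_by_molecule([p.mol_id for p in exp_pairs],
                                 plan.split_seed + 1, plan.finetune_fractions)
        val = [p for p in exp_pairs if p.mol_id in va]
        truths = [p.target_pka for p in val]
        ft_rmses.append(evaluate([ft.predict(p) for p in val], truths)[0])
        sc_rmses.append(evaluate([sc.predict(p) for p in val], truths)[0])
    return {"finetuned_rmse_mean": float(np.mean(ft_rmses)),
            "scratch_rmse_mean": float(np.mean(sc_rmses)),
            "finetuned_rmse_per_seed": ft_rmses,
            "scratch_rmse_per_seed": sc_rmses}


def enantiomer_invariance_benchmark(model: PkaModel, seed: int = 0,
                                    n_molecules: int = 50) -> Dict[str, float]:
    """Max |pKa(molecule) - pKa(mirror image)| over matched sites."""
    backend = get_backend("mock")
    lib = gen_chiral_library(n_molecules, seed)
    worst = 0.0
    n_sites = 0
    for rec in lib:
        ent = invert_stereocenters(rec)
        if ent is None:
            continue
        preds = {}
        for r in (rec, ent):
            labels = oracle_label(r, backend=backend)
            for pair in build_pairs(r, labels, backend):
                preds.setdefault((pair.atom_index, pair.reaction), []).append(
                    model.predict(pair))
        for key, vals in preds.items():
            if len(vals) == 2:
                worst = max(worst, abs(vals[0] - vals[1]))
                n_sites += 1
    return {"max_abs_delta_pka": worst, "n_matched_sites": n_sites}


def ig_completeness_benchmark(model: PkaModel, pair,
                              steps: int = 128) -> Dict[str, float]:
    """Relative completeness gap of integrated gradients on one pair."""
    from .autodiff import Tensor, no_grad
    from .nn import graph_inputs

    attr = integrated_gradients(model, pair, steps=steps)
    f_x = model.predict(pair)
    ip, id_ = graph_inputs(pair.graph_prot), graph_inputs(pair.graph_deprot)
    with no_grad():
        f_0 = float(model._forward_tensors(
            Tensor(np.zeros_like(ip["X"])), ip["S"], ip["mask"],
            Tensor(np.zeros((1, ip["mol"].size))),
            Tensor(np.zeros_like(id_["X"])), id_["S"], id_["mask"],
            Tensor(np.zeros((1, id_["mol"].size)))).data.item())
    gap = abs(attr["total"] - (f_x - f_0))
    denom = max(abs(f_x - f_0), 1e-12)
    return {"relative_error": gap / denom, "attr_total": attr["total"],
            "output_delta": f_x - f_0}
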