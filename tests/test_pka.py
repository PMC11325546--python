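"""Pair construction, the paired-graph regressor, metrics and attribution."""

import numpy as np
import pytest

from micropka.pka import (PairExample, PkaModel, PkaModelConfig, TrainPlan,
                          build_pairs, evaluate, finetune,
                          integrated_gradients, max_tanimoto, pretrain)
from micropka.sites import SiteLabelSet, oracle_label


@pytest.fixture(scope="module")
def acetic_pairs(make_record, backend):
    rec = make_record("CC(=O)O", "hac_pairs")
    return build_pairs(rec, oracle_label(rec, backend=backend), backend)


@pytest.fixture(scope="module")
def tiny_weak(small_library, backend):
    """~40 noiseless training pairs built from the session library."""
    from micropka.synthetic import _pairs_for_record
    pairs = []
    for entry in small_library[:40]:
        pairs.extend(_pairs_for_record(entry["record"], entry["spec"], backend))
    return pairs


class TestBuildPairs:
    def test_acetic_acid_gives_one_acidic_pair(self, acetic_pairs):
        acidic = [p for p in acetic_pairs if p.reaction == "acidic"]
        assert len(acidic) == 1
        p = acidic[0]
        assert p.graph_prot.n_atoms == p.graph_deprot.n_atoms + 1
        p.validate()

    def test_pyridine_gives_basic_pair(self, make_record, backend):
        rec = make_record("c1ccncc1", "pyr_pairs")
        pairs = build_pairs(rec, oracle_label(rec, backend=backend), backend)
        assert [p.reaction for p in pairs] == ["basic"]
        assert pairs[0].graph_prot.n_atoms == rec.n_atoms + 1

    def test_no_labels_empty_list(self, make_record, backend):
        rec = make_record("CC", "ethane_pairs")
        empty = (SiteLabelSet(rec.id, np.zeros(rec.n_atoms), "protonation"),
                 SiteLabelSet(rec.id, np.zeros(rec.n_atoms), "deprotonation"))
        assert build_pairs(rec, empty, backend) == []


class TestForward:
    def test_deterministic_in_eval_mode(self, acetic_pairs):
        model = PkaModel(PkaModelConfig(seed=5))
        p = acetic_pairs[0]
        assert model.predict(p) == model.predict(p)

    @pytest.mark.parametrize("family", ["gcn", "gat", "transformer"])
    def test_all_families_run(self, acetic_pairs, family):
        model = PkaModel(PkaModelConfig(gnn_family=family, seed=2))
        assert np.isfinite(model.predict(acetic_pairs[0]))

    def test_schema_mismatch_rejected(self, acetic_pairs):
        model = PkaModel(PkaModelConfig(seed=1))
        model.schema_hash = "stale"
        with pytest.raises(ValueError):
            model.forward(acetic_pairs[0])

    def test_save_load_round_trip(self, acetic_pairs, tmp_path):
        model = PkaModel(PkaModelConfig(seed=7))
        model.save(tmp_path / "pka")
        loaded = PkaModel.load(tmp_path / "pka")
        assert loaded.predict(acetic_pairs[0]) == model.predict(acetic_pairs[0])


class TestTraining:
    def test_pretrain_deterministic(self, tiny_weak):
        plan = TrainPlan(pretrain_epochs=4, patience=4)
        losses = []
        for _ in range(2):
            model = PkaModel(PkaModelConfig(seed=3))
            pretrain(model, tiny_weak, plan)
            losses.append(model.provenance[-1]["best_val_loss"])
        assert losses[0] == losses[1]

    def test_finetune_requires_pretrained(self, tiny_weak):
        model = PkaModel(PkaModelConfig(seed=3))
        with pytest.raises(ValueError):
            finetune(model, tiny_weak, TrainPlan())

    def test_finetune_zero_epochs_is_noop(self, tiny_weak):
        plan = TrainPlan(pretrain_epochs=3, patience=3)
        model = PkaModel(PkaModelConfig(seed=3))
        pretrain(model, tiny_weak, plan)
        before = model.store.state_dict()
        finetune(model, tiny_weak, TrainPlan(finetune_epochs=0))
        after = model.store.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            pretrain(PkaModel(PkaModelConfig(seed=0)), [], TrainPlan())


class TestEvaluate:
    def test_perfect_predictions(self):
        rmse, mae, r2 = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (rmse, mae, r2) == (0.0, 0.0, 1.0)

    def test_unit_shift(self):
        rmse, mae, _ = evaluate([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert rmse == pytest.approx(1.0) and mae == pytest.approx(1.0)

    def test_constant_mean_prediction_r2_zero(self):
        rmse, mae, r2 = evaluate([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert r2 == pytest.approx(0.0)

    def test_zero_variance_truths_flagged(self):
        _, _, r2 = evaluate([1.0, 2.0], [5.0, 5.0])
        assert np.isnan(r2)

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            evaluate([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            evaluate([], [])


class TestTanimoto:
    def test_self_similarity_is_one(self, make_record):
        rec = make_record("CC(=O)O", "hac_fp")
        assert max_tanimoto(rec, [rec]) == 1.0

    def test_dissimilar_molecules_low(self, make_record):
        q = make_record("C", "methane_fp")
        ref = [make_record("Ic1c(I)c(I)c(I)c(I)c1I", "hexaiodo")]
        assert max_tanimoto(q, ref) < 0.2

    def test_matches_manual_bitset_ratio(self, make_record):
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        a, b = make_record("CCO", "eth_fp"), make_record("CCCO", "prop_fp")
        fa = set(gen.GetFingerprint(Chem.MolFromSmiles(a.smiles_canonical)).GetOnBits())
        fb = set(gen.GetFingerprint(Chem.MolFromSmiles(b.smiles_canonical)).GetOnBits())
        manual = len(fa & fb) / len(fa | fb)
        assert max_tanimoto(a, [b]) == pytest.approx(manual)

    def test_empty_reference_rejected(self, make_record):
        with pytest.raises(ValueError):
            max_tanimoto(make_record("C", "m_fp"), [])


class TestInvariances:
    def test_atom_permutation_leaves_prediction_unchanged(self, acetic_pairs):
        """Mean pooling makes the regressor invariant to node order."""
        import copy

        model = PkaModel(PkaModelConfig(seed=8))
        p = acetic_pairs[0]
        base = model.predict(p)
        rng = np.random.default_rng(0)
        perm = rng.permutation(p.graph_prot.n_atoms)
        inv = np.argsort(perm)
        g = copy.deepcopy(p.graph_prot)
        g.node_features = g.node_features[:, perm]
        g.edge_index = inv[g.edge_index]
        if hasattr(g, "_nn_cache"):
            del g._nn_cache
        shuffled = PairExample(p.mol_id, p.atom_index, p.reaction,
                               g, p.graph_deprot, p.target_pka)
        assert model.predict(shuffled) == pytest.approx(base, abs=1e-6)

    def test_mock_features_independent_of_smiles_spelling(self, backend):
        from rdkit import Chem

        from micropka.chem_io import record_from_mol, standardize
        a = standardize(record_from_mol(Chem.MolFromSmiles("OCC"), "a",
                                        embed=False))
        b = standardize(record_from_mol(Chem.MolFromSmiles("CCO"), "b",
                                        embed=False))
        qa, qb = backend.compute(a), backend.compute(b)
        assert np.array_equal(qa.partial_charge, qb.partial_charge)
        assert np.array_equal(qa.wiberg_order, qb.wiberg_order)

    def test_labeled_site_edit_cycle_restores_parent(self, small_library,
                                                     backend):
        from micropka.sites import deprotonate_at, protonate_at

        for entry in small_library[:10]:
            rec = entry["record"]
            for idx in np.flatnonzero(entry["deprot"].labels):
                product = deprotonate_at(rec, int(idx))
                site = next(i for i, a in enumerate(product.atoms)
                            if a[1] == -1)
                assert protonate_at(product, site).smiles_canonical == \
                    rec.smiles_canonical
            for idx in np.flatnonzero(entry["prot"].labels):
                product = protonate_at(rec, int(idx))
                site = next(i for i, a in enumerate(product.atoms)
                            if a[1] == +1)
                assert deprotonate_at(product, site).smiles_canonical == \
                    rec.smiles_canonical


class TestIntegratedGradients:
    def test_baseline_equals_input_gives_zero(self, acetic_pairs):
        model = PkaModel(PkaModelConfig(seed=9))
        p = acetic_pairs[0]
        attr = integrated_gradients(model, p, baseline=p, steps=4)
        assert attr["total"] == pytest.approx(0.0, abs=1e-12)

    def test_linear_model_closed_form(self, acetic_pairs):
        """For a purely linear map, IG equals weight * (input - baseline)."""
        model = PkaModel(PkaModelConfig(seed=4, n_gnn_layers=0,
                                        n_linear_layers=1))
        p = acetic_pairs[0]
        for steps in (1, 7):
            attr = integrated_gradients(model, p, steps=steps)
            pred = model.predict(p)
            zero_pred = float(model.head.p["head.b0"].data.item())
            assert attr["total"] == pytest.approx(pred - zero_pred, rel=1e-9)

    def test_completeness_on_nonlinear_model(self, acetic_pairs):
        model = PkaModel(PkaModelConfig(seed=6))
        p = acetic_pairs[0]
        attr = integrated_gradients(model, p, steps=128)
        f_x = model.predict(p)
        zeros = {k: np.zeros_like(v) for k, v in
                 {"Xp": None, "Xd": None}.items()}
        # f(baseline): evaluate with all-zero inputs on the same topology
        from micropka.autodiff import Tensor, no_grad
        from micropka.nn import graph_inputs
        ip, id_ = graph_inputs(p.graph_prot), graph_inputs(p.graph_deprot)
        with no_grad():
            f_0 = float(model._forward_tensors(
                Tensor(np.zeros_like(ip["X"])), ip["S"], ip["mask"],
                Tensor(np.zeros((1, ip["mol"].size))),
                Tensor(np.zeros_like(id_["X"])), id_["S"], id_["mask"],
                Tensor(np.zeros((1, id_["mol"].size)))).data.item())
        assert attr["total"] == pytest.approx(f_x - f_0, rel=0.01)

    def test_block_aggregation_keys(self, acetic_pairs):
        model = PkaModel(PkaModelConfig(seed=2))
        attr = integrated_gradients(model, acetic_pairs[0], steps=2)
        assert "xTB Partial Charge" in attr["by_block"]
        assert "mol:xTB-Energy" in attr["by_block"]

    def test_invalid_steps_rejected(self, acetic_pairs):
        model = PkaModel(PkaModelConfig(seed=2))
        with pytest.raises(ValueError):
            integrated_gradients(model, acetic_pairs[0], steps=0)
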