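"""Structure edits, physical filters, SMARTS oracle and the site models."""

import numpy as np
import pytest

from micropka.chem_io import canonical_smiles
from micropka.sites import (DEFAULT_PATTERNS, PatternSet, SiteCandidate,
                            SiteEditError, SiteModelConfig, deprotonate_at,
                            energy_window_filter, oracle_label, predict_sites,
                            protonate_at, structural_change_filter,
                            train_site_model)


def _atom_idx(rec, symbol, with_h=None):
    for i, (s, _, h, _) in enumerate(rec.atoms):
        if s == symbol and (with_h is None or (h >= 1) == with_h):
            return i
    raise AssertionError(f"no {symbol} atom found")


class TestEdits:
    def test_protonate_pyridine_nitrogen(self, make_record):
        rec = make_record("c1ccncc1", "pyr")
        cat = protonate_at(rec, _atom_idx(rec, "N"))
        assert cat.net_charge == 1
        assert sum(1 for a in cat.atoms if a[0] != "H") == \
            sum(1 for a in rec.atoms if a[0] != "H")

    def test_protonate_water_oxygen(self, make_record):
        rec = make_record("O.C", "water")  # keeps methane? largest frag is C
        rec = make_record("OCC", "ethanol_w")
        cat = protonate_at(rec, _atom_idx(rec, "O"))
        o = next(i for i, a in enumerate(cat.atoms) if a[0] == "O")
        assert cat.atoms[o][1] == 1

    def test_protonate_saturated_carbon_fails(self, make_record):
        rec = make_record("CC", "ethane")
        with pytest.raises(SiteEditError):
            protonate_at(rec, 0)

    def test_deprotonate_carboxyl(self, make_record):
        rec = make_record("CC(=O)O", "hac")
        anion = deprotonate_at(rec, _atom_idx(rec, "O", with_h=True))
        assert anion.net_charge == -1
        assert anion.smiles_canonical == canonical_smiles("CC(=O)[O-]")

    def test_deprotonate_aromatic_carbon_allowed(self, make_record):
        rec = make_record("c1ccccc1", "bz")
        anion = deprotonate_at(rec, 0)
        assert anion.net_charge == -1

    def test_deprotonate_without_hydrogen_fails(self, make_record):
        rec = make_record("CC(=O)O", "hac2")
        carbonyl_o = next(i for i, a in enumerate(rec.atoms)
                          if a[0] == "O" and a[2] == 0)
        with pytest.raises(SiteEditError):
            deprotonate_at(rec, carbonyl_o)

    def test_edit_back_restores_parent(self, make_record):
        rec = make_record("c1ccncc1", "pyr2")
        n = _atom_idx(rec, "N")
        cat = protonate_at(rec, n)
        n_cat = next(i for i, a in enumerate(cat.atoms) if a[0] == "N")
        back = deprotonate_at(cat, n_cat)
        assert back.smiles_canonical == rec.smiles_canonical


class TestStructuralChangeFilter:
    def test_true_protomer_passes(self, make_record):
        rec = make_record("c1ccncc1", "pyr3")
        cat = protonate_at(rec, _atom_idx(rec, "N"))
        assert structural_change_filter(rec, cat, "protonation")

    def test_ring_opened_product_fails(self, make_record):
        ring = make_record("C1CCNC1", "pyrrolidine")
        open_chain = make_record("CCC[NH3+]", "openamine")  # not a protomer
        assert not structural_change_filter(ring, open_chain, "protonation")

    def test_heavy_atom_change_fails(self, make_record):
        a = make_record("CCO", "eth")
        b = make_record("CCCO", "prop")
        assert not structural_change_filter(a, b, "protonation")


class TestEnergyWindow:
    def _cand(self, e):
        return SiteCandidate(0, "protonation", None, rel_energy_ev=e)

    def test_all_within_window_kept(self):
        cands = [self._cand(e) for e in (0.0, 5.0, 9.9)]
        assert len(energy_window_filter(cands)) == 3

    def test_boundary_inclusive_default_10ev(self):
        cands = [self._cand(e) for e in (0.0, 10.0, 10.01)]
        kept = energy_window_filter(cands)
        assert [c.rel_energy_ev for c in kept] == [0.0, 10.0]

    def test_empty_and_singleton(self):
        assert energy_window_filter([]) == []
        assert len(energy_window_filter([self._cand(0.0)])) == 1


class TestOracle:
    def test_pyridine_basic_site_only(self, make_record, backend):
        rec = make_record("c1ccncc1", "pyr4")
        prot, deprot = oracle_label(rec, backend=backend)
        assert prot.labels.sum() == 1
        assert prot.labels[_atom_idx(rec, "N")] == 1
        assert deprot.labels.sum() == 0

    def test_phenol_acidic_site_on_hydroxyl(self, make_record, backend):
        rec = make_record("Oc1ccccc1", "phenol")
        prot, deprot = oracle_label(rec, backend=backend)
        assert deprot.labels[_atom_idx(rec, "O")] == 1

    def test_ethane_no_sites(self, make_record, backend):
        rec = make_record("CC", "ethane2")
        prot, deprot = oracle_label(rec, backend=backend)
        assert prot.labels.sum() == 0 and deprot.labels.sum() == 0

    def test_labels_respect_hydrogen_and_valence(self, small_library):
        for entry in small_library[:25]:
            rec = entry["record"]
            for idx in np.flatnonzero(entry["deprot"].labels):
                assert rec.atoms[idx][2] >= 1  # H-bearing
            for idx in np.flatnonzero(entry["prot"].labels):
                assert rec.atoms[idx][0] in ("N", "O", "S")

    def test_pattern_file_round_trip(self, tmp_path):
        p = tmp_path / "patterns.txt"
        lines = ["# test patterns"]
        lines += [f"{s}\tacidic" for s in DEFAULT_PATTERNS.acidic[:3]]
        lines += [f"{s}\tbasic" for s in DEFAULT_PATTERNS.basic[:3]]
        p.write_text("\n".join(lines))
        ps = PatternSet.from_file(p)
        assert len(ps.acidic) == 3 and len(ps.basic) == 3


@pytest.fixture(scope="module")
def trained(small_library):
    data = [(e["graph"], e["deprot"]) for e in small_library]
    cfg = SiteModelConfig(epochs=25, seed=0)
    return train_site_model(data, cfg), data


class TestSiteModel:
    def test_training_deterministic(self, small_library):
        data = [(e["graph"], e["prot"]) for e in small_library]
        cfg = SiteModelConfig(epochs=6, seed=1)
        h1 = train_site_model(data, cfg).result.history
        h2 = train_site_model(data, cfg).result.history
        assert [e["val_loss"] for e in h1] == [e["val_loss"] for e in h2]

    def test_early_stopping_semantics(self, small_library):
        data = [(e["prot"], e["prot"]) for e in small_library]  # placeholder
        from micropka.nn import ParamStore, fit
        from micropka.autodiff import Tensor

        store = ParamStore()
        w = store.add("w", np.array([[0.0]]))

        # validation loss can never improve: stops at best_epoch + patience
        def loss_fn(item):
            return (w * 0.0 + 1.0).sum()

        res = fit(store, loss_fn, [1, 2, 3], [1], epochs=50, lr=1e-3,
                  patience=5, seed=0)
        assert len(res.history) == 6 and res.best_epoch == 1

    def test_prediction_shape_and_threshold(self, trained):
        model, data = trained
        g = data[0][0]
        labels = predict_sites(model, g, threshold=0.5)
        assert labels.labels.shape == (g.n_atoms,)
        everything = predict_sites(model, g, threshold=0.0)
        assert everything.labels.sum() == g.n_atoms  # sigmoid > 0 everywhere

    def test_schema_mismatch_rejected(self, trained):
        model, data = trained
        g = data[0][0]
        model2 = type(model)(model.config, model.reaction)
        model2.schema_hash = "stale"
        with pytest.raises(ValueError):
            predict_sites(model2, g)

    def test_learns_oracle_on_small_set(self, trained):
        model, _ = trained
        assert model.test_accuracy >= 0.9

    def test_save_load_round_trip(self, trained, tmp_path):
        from micropka.sites import SiteModel
        model, data = trained
        model.save(tmp_path / "m")
        loaded = SiteModel.load(tmp_path / "m")
        g = data[0][0]
        assert np.allclose(loaded.probabilities(g), model.probabilities(g))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_site_model([])
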