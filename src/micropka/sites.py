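"""Ionization-site enumeration: edits, filters, oracle labels, GNN models.

The training-label generator couples a curated SMARTS pattern set for
acidic/basic groups with backend energy ranking of the edited structures,
then applies two physical filters: a structural-change filter (the product
must differ from the parent by exactly one proton — rearranged or
fragmented products are rejected) and a 10 eV energy window above the most
stable product of each reaction.  Two node-classification GNNs — one for
protonation, one for deprotonation — learn these labels and replace the
oracle at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from rdkit import Chem

from .autodiff import Tensor, no_grad
from .chem_io import MolRecord, record_from_mol
from .graphs import DEFAULT_SCHEMA, FeatureSchema, MolGraph
from .nn import (GraphEncoder, MLP, ParamStore, bce_with_logits, fit,
                 graph_inputs, split_by_molecule)
from .qm import relative_energy_ev

log = logging.getLogger("micropka")

DEFAULT_ENERGY_WINDOW_EV = 10.0

_VALENCE_ELECTRONS = {"H": 1, "C": 4, "N": 5, "O": 6, "S": 6, "P": 5,
                      "F": 7, "Cl": 7, "Br": 7, "I": 7}


class SiteEditError(ValueError):
    """A protonation/deprotonation edit violates valence rules."""


@dataclass
class SiteCandidate:
    """One putative reaction site with its edited product."""

    atom_index: int                  # 0-based, parent atom order
    reaction: str                    # "protonation" | "deprotonation"
    product: MolRecord
    rel_energy_ev: float = 0.0      # relative to the best product, same reaction


@dataclass
class SiteLabelSet:
    """Per-atom binary site labels for one molecule and one reaction."""

    mol_id: str
    labels: np.ndarray               # (N,) values in {0,1}
    reaction: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")


# ---------------------------------------------------------------------------
# structure edits


def _lone_pairs(atom: Chem.Atom) -> float:
    ve = _VALENCE_ELECTRONS.get(atom.GetSymbol(), 4)
    return (ve - atom.GetFormalCharge() - atom.GetTotalValence()) / 2.0


def protonate_at(rec: MolRecord, atom_index: int) -> MolRecord:
    """Add a proton at ``atom_index`` (+1 formal charge, net charge +1).

    The atom must hold a lone pair; protonating a saturated carbon raises
    :class:`SiteEditError`.  The new hydrogen is placed 1.0 A from the site
    atom opposite the mean of its bond vectors — deterministic and
    reflection-equivariant, so editing a mirrored molecule yields the exact
    mirror of the edited original.
    """
    mol = Chem.RWMol(rec.mol)
    atom = mol.GetAtomWithIdx(atom_index)
    if _lone_pairs(atom) < 1:
        raise SiteEditError(
            f"{rec.id}: atom {atom_index} ({atom.GetSymbol()}) has no lone pair")
    h = mol.AddAtom(Chem.Atom(1))
    mol.AddBond(atom_index, h, Chem.BondType.SINGLE)
    atom.SetFormalCharge(atom.GetFormalCharge() + 1)
    atom.SetNoImplicit(True)
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
    except Exception as exc:
        raise SiteEditError(f"{rec.id}: protonation at {atom_index} invalid: {exc}")
    coords = None
    if rec.conformer is not None:
        pos = rec.conformer[atom_index]
        nbrs = [j for i, j, _ in rec.bonds if i == atom_index] + \
               [i for i, j, _ in rec.bonds if j == atom_index]
        d = -np.sum([rec.conformer[n] - pos for n in nbrs], axis=0) if nbrs \
            else np.array([1.0, 0.0, 0.0])
        norm = np.linalg.norm(d)
        d = d / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
        coords = np.vstack([rec.conformer, pos + d])
    return record_from_mol(m, f"{rec.id}_p{atom_index}", embed=False,
                           coords=coords)


def deprotonate_at(rec: MolRecord, atom_index: int) -> MolRecord:
    """Remove a proton from ``atom_index`` (-1 formal charge, net -1).

    The product conformer is the parent's with the removed hydrogen's row
    deleted (no re-embedding).
    """
    mol = Chem.RWMol(rec.mol)
    atom = mol.GetAtomWithIdx(atom_index)
    h_idx = next((nb.GetIdx() for nb in atom.GetNeighbors()
                  if nb.GetAtomicNum() == 1), None)
    if h_idx is None:
        raise SiteEditError(f"{rec.id}: atom {atom_index} bears no hydrogen")
    mol.RemoveAtom(h_idx)
    atom = mol.GetAtomWithIdx(atom_index if atom_index < h_idx else atom_index - 1)
    atom.SetFormalCharge(atom.GetFormalCharge() - 1)
    atom.SetNoImplicit(True)
    atom.SetNumExplicitHs(0)
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
    except Exception as exc:
        raise SiteEditError(f"{rec.id}: deprotonation at {atom_index} invalid: {exc}")
    coords = np.delete(rec.conformer, h_idx, axis=0) \
        if rec.conformer is not None else None
    return record_from_mol(m, f"{rec.id}_d{atom_index}", embed=False,
                           coords=coords)


# ---------------------------------------------------------------------------
# filters


def _heavy_graph(rec: MolRecord) -> nx.Graph:
    """Heavy-atom graph labeled by element and bond order, H counts on nodes."""
    g = nx.Graph()
    heavy = [i for i, a in enumerate(rec.atoms) if a[0] != "H"]
    idx_map = {i: k for k, i in enumerate(heavy)}
    h_count = {i: 0 for i in heavy}
    for i, j, order in rec.bonds:
        si, sj = rec.atoms[i][0], rec.atoms[j][0]
        if si != "H" and sj != "H":
            g.add_edge(idx_map[i], idx_map[j], order=order)
        elif si == "H" and sj != "H":
            h_count[j] += 1
        elif sj == "H" and si != "H":
            h_count[i] += 1
    for i in heavy:
        g.add_node(idx_map[i], element=rec.atoms[i][0], h=h_count[i])
    return g


def structural_change_filter(parent: MolRecord, child: MolRecord,
                             reaction: str) -> bool:
    """True iff parent and child differ by exactly one proton.

    The protonated form (child for protonation, parent for deprotonation)
    must map onto the other form by a heavy-atom isomorphism preserving
    elements and bond orders, with the hydrogen counts of exactly one
    mapped atom differing by one.  Ring closures, ring openings and any
    heavy-atom change fail the test.
    """
    prot, deprot = (child, parent) if reaction == "protonation" else (parent, child)
    gp, gd = _heavy_graph(prot), _heavy_graph(deprot)
    if gp.number_of_nodes() != gd.number_of_nodes():
        return False
    nm = nx.algorithms.isomorphism.categorical_node_match("element", "")
    em = nx.algorithms.isomorphism.numerical_edge_match("order", 1.0)
    matcher = nx.algorithms.isomorphism.GraphMatcher(gp, gd, node_match=nm,
                                                     edge_match=em)
    for n_checked, mapping in enumerate(matcher.isomorphisms_iter()):
        diff = sum(abs(gp.nodes[a]["h"] - gd.nodes[b]["h"])
                   for a, b in mapping.items())
        if diff == 1:
            return True
        if n_checked > 200:  # combinatorial guard for highly symmetric molecules
            break
    return False


def energy_window_filter(candidates: Sequence[SiteCandidate],
                         window_ev: float = DEFAULT_ENERGY_WINDOW_EV
                         ) -> List[SiteCandidate]:
    """Keep candidates within ``window_ev`` (inclusive) of the best product."""
    return [c for c in candidates if c.rel_energy_ev <= window_ev]


# ---------------------------------------------------------------------------
# SMARTS oracle

# Curated acidic patterns: the starred atom in comments is the labeled site
# (the first atom of each SMARTS match is the ionizable heavy atom).
ACIDIC_SMARTS: List[str] = [
    "[OX2H1][CX3]=[OX1]",              # carboxylic acid O-H
    "[OX2H1][c]",                      # phenol / aromatic alcohol
    "[OX2H1][SX4](=O)(=O)",            # sulfonic acid
    "[OX2H1][P](=O)",                  # phosphonic / phosphoric acid
    "[OX2H1][NX3]",                    # hydroxylamine O-H
    "[OX2H1][CX3]=[CX3]",              # enol
    "[SX2H1][#6]",                     # thiol
    "[SX2H1][c]",                      # thiophenol
    "[NX3H1]([CX3]=[OX1])[CX3]=[OX1]", # imide N-H
    "[NX3H1]([SX4](=O)(=O))",          # sulfonamide N-H
    "[NX3H1][C](=O)[c]",               # aryl amide N-H (weakly acidic)
    "[nX3H1]1nnnc1",                   # tetrazole N-H
    "[nX3H1]1ccnc1",                   # imidazole / pyrrole-type ring N-H
    "[NX3H1]([CX3]=[OX1])[OX2H0]",     # hydroxamic-type N-H
    "[OX2H1][CX4][CX3]=[OX1]",         # alpha-hydroxy carbonyl
    "[NX3H2][CX3]=[OX1]",              # primary amide N-H2 (edge of range)
    "[OX2H1][NX2]=[CX3]",              # oxime O-H
    "[SX2H1]",                         # generic S-H
    "[OX2H1][SX4]",                    # sulfinic/sulfenic O-H
    "[NX3H1]([c])[SX4](=O)(=O)",       # aryl sulfonamide
    "[nX3H1]1ncnc1",                   # triazole-type N-H
    "[OX2H1][CX3](=[SX1])",            # thioacid O-H
    "[NX3H1]1[CX3](=[OX1])[#6][#6][CX3]1=[OX1]",  # cyclic imide
    "[OX2H1][B]",                      # boronic-like O-H (rare, kept general)
    "[NX3H1]([CX3]=[OX1])[NX3]",       # hydrazide N-H
]

BASIC_SMARTS: List[str] = [
    "[NX3H2;!$(NC=O);!$(N[SX4]);!$(Na)][CX4]",   # primary aliphatic amine
    "[NX3H1;!$(NC=O);!$(N[SX4])]([CX4])[CX4]",   # secondary aliphatic amine
    "[NX3H0;!$(NC=O);!$(N[SX4]);!$(N=*)]([CX4])([CX4])[CX4]",  # tertiary amine
    "[nX2H0]1ccccc1",                  # pyridine-type ring N
    "[nX2H0]1ccncc1",                  # pyrimidine/pyrazine-type ring N
    "[nX2H0]1cc[nX3H1]c1",             # imidazole basic N
    "[nX2H0]1ccon1",                   # isoxazole-type ring N
    "[nX2H0]1ncnc1",                   # triazine/triazole ring N
    "[NX3H2][c]",                      # aniline N
    "[NX3H1]([c])[CX4]",               # N-alkyl aniline
    "[NX2H0]=[CX3][NX3]",              # amidine sp2 N
    "[NX2H0]=[CX3]([NX3])[NX3]",       # guanidine sp2 N
    "[NX3H2][NX3]",                    # hydrazine N
    "[NX2H0]=[NX2]",                   # azo N (weak)
    "[NX3H2][CX4][c]",                 # benzylamine N
    "[NX3H1]1[CX4][CX4][CX4][CX4][CX4]1",  # piperidine N-H
    "[NX3H0]1([CX4])[CX4][CX4][CX4][CX4][CX4]1",  # N-alkyl piperidine
    "[NX3H1]1[CX4][CX4][OX2][CX4][CX4]1",  # morpholine N
    "[NX3H1]1[CX4][CX4][CX4][CX4]1",   # pyrrolidine N
    "[NX2H0]=[CX3][c]",                # aryl imine N
    "[NX3H2][CX4][CX4][OX2]",          # aminoether N
    "[nX2H0]1cccc1",                   # generic aromatic sp2 N (5-ring)
    "[NX3H1]([CX4])[CX4][c]",          # secondary benzylic amine
    "[NX2H0]([CX4])=[CX3]",            # alkyl imine N
    "[NX3H2][CX4][CX4][NX3H2]",        # diamine terminal N
]


@dataclass
class PatternSet:
    """Compiled SMARTS oracle patterns; the labeled atom is match atom 0."""

    acidic: List[str] = field(default_factory=lambda: list(ACIDIC_SMARTS))
    basic: List[str] = field(default_factory=lambda: list(BASIC_SMARTS))

    def __post_init__(self):
        self._acidic = [Chem.MolFromSmarts(s) for s in self.acidic]
        self._basic = [Chem.MolFromSmarts(s) for s in self.basic]
        if any(p is None for p in self._acidic + self._basic):
            raise ValueError("invalid SMARTS in pattern set")

    def match_atoms(self, mol: Chem.Mol, reaction: str) -> List[int]:
        patterns = self._basic if reaction == "protonation" else self._acidic
        hits: List[int] = []
        for p in patterns:
            for match in mol.GetSubstructMatches(p):
                if match[0] not in hits:
                    hits.append(match[0])
        return sorted(hits)

    @classmethod
    def from_file(cls, path) -> "PatternSet":
        """Read 'SMARTS<tab>acidic|basic' lines."""
        acidic, basic = [], []
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smarts, tag = line.split()
            (acidic if tag == "acidic" else basic).append(smarts)
        return cls(acidic=acidic, basic=basic)


DEFAULT_PATTERNS = PatternSet()


def enumerate_candidates(rec: MolRecord, reaction: str, backend,
                         patterns: PatternSet = DEFAULT_PATTERNS,
                         window_ev: float = DEFAULT_ENERGY_WINDOW_EV
                         ) -> List[SiteCandidate]:
    """Pattern-matched sites -> edited products -> filters -> candidates.

    Products failing the edit, the structural-change filter, or the energy
    window are dropped.  Surviving candidates carry energies relative to
    the most stable product of the same reaction (the minimum is 0 eV).
    """
    edit = protonate_at if reaction == "protonation" else deprotonate_at
    raw: List[SiteCandidate] = []
    for idx in patterns.match_atoms(rec.mol, reaction):
        try:
            product = edit(rec, idx)
        except SiteEditError:
            continue
        if not structural_change_filter(rec, product, reaction):
            log.warning("sites: %s atom %d (%s) failed structural filter",
                        rec.id, idx, reaction)
            continue
        raw.append(SiteCandidate(idx, reaction, product))
    if not raw:
        return []
    energies = [backend.energy(c.product) for c in raw]
    e_min = min(energies)
    for c, e in zip(raw, energies):
        c.rel_energy_ev = relative_energy_ev(e_min + 0.0, e)
    return energy_window_filter(raw, window_ev)


def oracle_label(rec: MolRecord, patterns: PatternSet = DEFAULT_PATTERNS,
                 backend=None) -> Tuple[SiteLabelSet, SiteLabelSet]:
    """Label protonation and deprotonation sites with the SMARTS oracle.

    Returns (protonation labels, deprotonation labels), each a binary
    vector over all atoms (explicit hydrogens included, always 0 for H of
    protonation).  No matches gives all-zero labels.
    """
    from .qm import get_backend

    backend = get_backend("mock") if backend is None else backend
    out = []
    for reaction in ("protonation", "deprotonation"):
        labels = np.zeros(rec.n_atoms, dtype=np.int8)
        for cand in enumerate_candidates(rec, reaction, backend, patterns):
            labels[cand.atom_index] = 1
        out.append(SiteLabelSet(rec.id, labels, reaction))
    return tuple(out)


# ---------------------------------------------------------------------------
# site model


@dataclass
class SiteModelConfig:
    gnn_family: str = "gcn"
    n_layers: int = 3
    hidden: int = 32
    lr: float = 5e-3
    epochs: int = 60
    patience: int = 8
    batch_size: int = 8
    pos_weight: float = 4.0   # most atoms are non-sites
    threshold: float = 0.5
    seed: int = 0


class SiteModel:
    """Node-classification GNN scoring each atom as a reaction site."""

    def __init__(self, config: SiteModelConfig, reaction: str,
                 schema: FeatureSchema = DEFAULT_SCHEMA):
        self.config = config
        self.reaction = reaction
        self.schema_hash = schema.hash()
        self.store = ParamStore()
        rng = np.random.default_rng(config.seed)
        self.encoder = GraphEncoder(self.store, "enc", config.gnn_family,
                                    61, config.hidden, config.n_layers, rng)
        self.head = MLP(self.store, "head", [config.hidden, config.hidden, 1], rng)
        self.result = None

    def logits(self, g: MolGraph) -> Tensor:
        if g.schema_hash != self.schema_hash:
            raise ValueError("feature-schema hash mismatch between graph and model")
        inp = graph_inputs(g)
        H = self.encoder.forward(Tensor(inp["X"]), inp["S"], inp["mask"])
        return self.head.forward(H)  # (N, 1)

    def probabilities(self, g: MolGraph) -> np.ndarray:
        with no_grad():
            z = self.logits(g).data.ravel()
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, path) -> None:
        from .nn import save_model

        save_model(path, self.store, {
            "kind": "site", "reaction": self.reaction,
            "schema_hash": self.schema_hash, "config": self.config.__dict__,
            "history": self.result.history if self.result else [],
        })

    @classmethod
    def load(cls, path) -> "SiteModel":
        from .nn import load_model_arrays

        state, meta = load_model_arrays(path)
        model = cls(SiteModelConfig(**meta["config"]), meta["reaction"])
        model.schema_hash = meta["schema_hash"]
        model.store.load_state_dict(state)
        return model


def train_site_model(dataset: Sequence[Tuple[MolGraph, SiteLabelSet]],
                     config: SiteModelConfig = SiteModelConfig()
                     ) -> SiteModel:
    """Train one node classifier on (graph, label) pairs.

    The dataset is split 80:10:10 by molecule with the config seed; early
    stopping watches the validation loss.  Training history, seed and the
    held-out test accuracy are recorded on the model.
    """
    if not dataset:
        raise ValueError("empty dataset")
    reaction = dataset[0][1].reaction
    ids = [lbl.mol_id for _, lbl in dataset]
    train_ids, val_ids, test_ids = split_by_molecule(ids, config.seed)
    parts = {
        "train": [d for d in dataset if d[1].mol_id in train_ids],
        "val": [d for d in dataset if d[1].mol_id in val_ids],
        "test": [d for d in dataset if d[1].mol_id in test_ids],
    }
    if not parts["train"] or not parts["val"]:
        raise ValueError("a split partition is empty")
    model = SiteModel(config, reaction)

    def loss_fn(item):
        g, lbl = item
        return bce_with_logits(model.logits(g), lbl.labels.astype(float),
                               config.pos_weight)

    model.result = fit(model.store, loss_fn, parts["train"], parts["val"],
                       epochs=config.epochs, lr=config.lr,
                       patience=config.patience, seed=config.seed + 1,
                       batch_size=config.batch_size)
    correct = total = 0
    for g, lbl in parts["test"] or parts["val"]:
        pred = predict_sites(model, g, config.threshold).labels
        correct += int((pred == lbl.labels).sum())
        total += lbl.labels.size
    model.test_accuracy = correct / total if total else float("nan")
    return model


def predict_sites(model: SiteModel, g: MolGraph,
                  threshold: float = 0.5) -> SiteLabelSet:
    """Threshold per-atom probabilities into a binary site vector."""
    p = model.probabilities(g)
    return SiteLabelSet(g.mol_id, (p > threshold).astype(np.int8), model.reaction)
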