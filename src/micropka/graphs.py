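"""Model-facing molecular graphs with a locked 61-dim node-feature schema.

Nodes are *all* atoms including explicit hydrogens — deprotonation sites are
hydrogen-bearing atoms, so hydrogen nodes carry real signal.  Each
undirected bond is stored as two directed arcs with identical features.

The node schema totals exactly 61 features; the block layout below is the
contract between featurization and every trained model, hashed into each
model artifact so a stale model cannot silently consume mismatched inputs.
Every feature is invariant under reflection of the conformer, which makes
graph features of enantiomer pairs identical by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from rdkit.Chem import rdMolDescriptors

from .chem_io import MolRecord
from .qm import ELECTRONEGATIVITY, MolQM

_ATOM_TYPES = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H", "other"]
_CHARGES = [-2, -1, 0, 1, 2]
_HYBRIDIZATIONS = ["S", "SP", "SP2", "SP3", "SP3D", "SP3D2", "other"]

#: node blocks: (name, width) — widths sum to exactly 61.
NODE_BLOCKS: List[Tuple[str, int]] = [
    ("Atom Type", 11),          # one-hot over _ATOM_TYPES
    ("Formal Charge", 5),       # one-hot over -2..+2
    ("Degree", 7),              # one-hot over 0..6
    ("Total H Count", 5),       # one-hot over 0..4
    ("Hybridization", 7),       # one-hot over _HYBRIDIZATIONS
    ("Total Valence", 7),       # one-hot over 0..6
    ("Is Aromatic", 1),
    ("Is In Ring", 1),
    ("Ring Size", 6),           # one-hot over {3,4,5,6,7,>=8}
    ("Is HBD", 1),
    ("Is HBA", 1),
    ("Is Stereocenter", 1),
    ("Mass", 1),                # atomic mass / 100
    ("Electronegativity", 1),   # Pauling / 4
    ("xTB Partial Charge", 1),
    ("xTB Fukui(+)", 1),
    ("xTB Fukui(0)", 1),
    ("xTB Fukui(-)", 1),
    ("xTB Coord Number", 1),
    ("xTB Alpha", 1),           # atomic polarizability / 10
]

EDGE_BLOCKS: List[Tuple[str, int]] = [
    ("Bond Type", 4),           # one-hot SINGLE / AROMATIC / DOUBLE / TRIPLE
    ("Is Conjugated", 1),
    ("Is In Ring", 1),
    ("Wiberg Bond Order", 1),
]

MOL_BLOCKS: List[Tuple[str, int]] = [
    ("RadiusOfGyration", 1),
    ("Eccentricity", 1),
    ("Spherocity", 1),
    ("FractionCSP3", 1),
    ("Asphericity", 1),
    ("xTB-Energy", 1),          # E(protonated) - E(deprotonated), Hartree; pairs only
]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature-block layout for nodes, edges and the molecule."""

    node_blocks: Tuple[Tuple[str, int], ...] = tuple(NODE_BLOCKS)
    edge_blocks: Tuple[Tuple[str, int], ...] = tuple(EDGE_BLOCKS)
    mol_blocks: Tuple[Tuple[str, int], ...] = tuple(MOL_BLOCKS)

    @property
    def node_dim(self) -> int:
        return sum(w for _, w in self.node_blocks)

    @property
    def edge_dim(self) -> int:
        return sum(w for _, w in self.edge_blocks)

    @property
    def mol_dim(self) -> int:
        return sum(w for _, w in self.mol_blocks)

    def validate(self) -> None:
        if self.node_dim != 61:
            raise ValueError(f"node feature widths sum to {self.node_dim}, not 61")

    def hash(self) -> str:
        payload = json.dumps(
            [list(map(list, self.node_blocks)), list(map(list, self.edge_blocks)),
             list(map(list, self.mol_blocks))])
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def node_block_rows(self) -> Dict[str, slice]:
        """Map block name -> row slice into the (61, N) node matrix."""
        out, r = {}, 0
        for name, w in self.node_blocks:
            out[name] = slice(r, r + w)
            r += w
        return out

    def to_json(self) -> str:
        return json.dumps({
            "node_blocks": [list(b) for b in self.node_blocks],
            "edge_blocks": [list(b) for b in self.edge_blocks],
            "mol_blocks": [list(b) for b in self.mol_blocks],
            "hash": self.hash(),
        }, indent=1)


DEFAULT_SCHEMA = FeatureSchema()
DEFAULT_SCHEMA.validate()


@dataclass
class MolGraph:
    """A featurized molecule: (61, N) nodes, directed arcs, mol vector."""

    node_features: np.ndarray   # (61, N)
    edge_index: np.ndarray      # (2, 2*n_bonds) directed arcs
    edge_features: np.ndarray   # (edge_dim, 2*n_bonds)
    mol_features: np.ndarray    # (mol_dim,)
    n_atoms: int
    schema_hash: str = field(default=DEFAULT_SCHEMA.hash())
    mol_id: str = ""

    def validate(self) -> None:
        if self.node_features.shape != (61, self.n_atoms):
            raise ValueError("node_features must be (61, N)")
        arcs = {(int(i), int(j)) for i, j in self.edge_index.T}
        if any((j, i) not in arcs for i, j in arcs):
            raise ValueError("edge_index is not symmetric")
        for name, arr in (("node", self.node_features),
                          ("edge", self.edge_features),
                          ("mol", self.mol_features)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite {name} features")


def _one_hot(value, choices) -> np.ndarray:
    v = np.zeros(len(choices))
    try:
        v[choices.index(value)] = 1.0
    except ValueError:
        v[-1] = 1.0
    return v


def _clipped_one_hot(value: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[min(max(int(value), 0), n - 1)] = 1.0
    return v


def molecular_descriptors(rec: MolRecord) -> np.ndarray:
    """Five shape/composition descriptors from the conformer and graph.

    From the mass-weighted gyration tensor
    ``S = sum_i m_i (r_i - rbar)(r_i - rbar)^T / sum_i m_i``
    with eigenvalues ``l1 >= l2 >= l3``:

    * RadiusOfGyration = sqrt(l1 + l2 + l3)
    * Asphericity      = ((l1-l2)^2 + (l2-l3)^2 + (l1-l3)^2) / (2 (l1+l2+l3)^2)
      — 0 for a sphere, 1 for a perfect rod.
    * Eccentricity     = sqrt(l1^2 - l3^2) / l1 — 1 when the smallest
      eigenvalue vanishes (planar or linear arrangements).
    * Spherocity       = 3 l3 / (l1 + l2 + l3) — 0 for planar molecules.

    FractionCSP3 is the sp3 fraction of the carbons.  Degenerate inputs
    (< 3 atoms, or all eigenvalues 0) get all shape descriptors 0 rather
    than NaN.  All four shape values are reflection-invariant.
    """
    pt = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
          "P": 30.974, "F": 18.998, "Cl": 35.45, "Br": 79.904, "I": 126.904}
    fcsp3 = rdMolDescriptors.CalcFractionCSP3(rec.mol)
    if rec.conformer is None or rec.n_atoms < 3:
        return np.array([0.0, 0.0, 0.0, fcsp3, 0.0])
    m = np.array([pt.get(a[0], 12.0) for a in rec.atoms])
    r = rec.conformer - np.average(rec.conformer, axis=0, weights=m)
    S = (m[:, None, None] * r[:, :, None] * r[:, None, :]).sum(axis=0) / m.sum()
    lam = np.sort(np.linalg.eigvalsh(S))[::-1]
    lam = np.clip(lam, 0.0, None)
    tot = lam.sum()
    if tot <= 1e-12:
        return np.array([0.0, 0.0, 0.0, fcsp3, 0.0])
    rog = float(np.sqrt(tot))
    asph = float(((lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2
                  + (lam[0] - lam[2]) ** 2) / (2.0 * tot**2))
    ecc = float(np.sqrt(max(lam[0] ** 2 - lam[2] ** 2, 0.0)) / lam[0])
    sph = float(3.0 * lam[2] / tot)
    return np.array([rog, ecc, sph, fcsp3, asph])


def featurize(rec: MolRecord, qm: MolQM,
              schema: FeatureSchema = DEFAULT_SCHEMA) -> MolGraph:
    """Build the (61, N) graph for one molecule from record + QM features."""
    schema.validate()
    qm.validate(rec)
    n = rec.n_atoms
    mol = rec.mol

    cols = []
    for idx, atom in enumerate(mol.GetAtoms()):
        sym, charge, _, _ = rec.atoms[idx]
        n_h = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1) \
            + atom.GetTotalNumHs()
        hbd = 1.0 if sym in ("N", "O", "S") and n_h >= 1 else 0.0
        hba = 1.0 if sym in ("N", "O") and charge <= 0 else 0.0
        ring_size = 0
        for size in (3, 4, 5, 6, 7, 8):
            if atom.IsInRingSize(size):
                ring_size = size
                break
        ring_onehot = np.zeros(6)
        if ring_size:
            ring_onehot[[3, 4, 5, 6, 7, 8].index(ring_size)] = 1.0
        stereo = 1.0 if str(atom.GetChiralTag()) != "CHI_UNSPECIFIED" else 0.0
        col = np.concatenate([
            _one_hot(sym, _ATOM_TYPES),
            _one_hot(charge, _CHARGES),
            _clipped_one_hot(atom.GetDegree(), 7),
            _clipped_one_hot(n_h, 5),
            _one_hot(str(atom.GetHybridization()), _HYBRIDIZATIONS),
            _clipped_one_hot(atom.GetTotalValence(), 7),
            [1.0 if atom.GetIsAromatic() else 0.0],
            [1.0 if atom.IsInRing() else 0.0],
            ring_onehot,
            [hbd],
            [hba],
            [stereo],
            [atom.GetMass() / 100.0],
            [ELECTRONEGATIVITY.get(sym, 2.5) / 4.0],
            [qm.partial_charge[idx]],
            [qm.fukui_plus[idx]],
            [qm.fukui_zero[idx]],
            [qm.fukui_minus[idx]],
            [qm.coord_number[idx]],
            [qm.polarizability[idx] / 10.0],
        ])
        cols.append(col)
    node_features = np.array(cols).T  # (61, N)

    arcs, feats = [], []
    bond_types = [1.0, 1.5, 2.0, 3.0]
    for b_idx, (i, j, order) in enumerate(rec.bonds):
        bond = mol.GetBondBetweenAtoms(i, j)
        f = np.concatenate([
            _one_hot(order, bond_types),
            [1.0 if bond.GetIsConjugated() else 0.0],
            [1.0 if bond.IsInRing() else 0.0],
            [qm.wiberg_order[b_idx]],
        ])
        arcs.extend([(i, j), (j, i)])
        feats.extend([f, f])
    edge_index = (np.array(arcs, dtype=np.int64).T if arcs
                  else np.zeros((2, 0), dtype=np.int64))
    edge_features = (np.array(feats).T if feats
                     else np.zeros((schema.edge_dim, 0)))

    desc = molecular_descriptors(rec)
    mol_features = np.concatenate([desc, [0.0]])  # xTB-Energy filled for pairs

    g = MolGraph(
        node_features=node_features,
        edge_index=edge_index,
        edge_features=edge_features,
        mol_features=mol_features,
        n_atoms=n,
        schema_hash=schema.hash(),
        mol_id=rec.id,
    )
    g.validate()
    if np.isnan(node_features).any():
        rows = schema.node_block_rows()
        bad = [name for name, sl in rows.items()
               if np.isnan(node_features[sl]).any()]
        raise ValueError(f"NaN in node feature block(s): {bad}")
    return g


def featurize_pair(protonated, deprotonated,
                   schema: FeatureSchema = DEFAULT_SCHEMA):
    """Featurize a (protonated, deprotonated) record pair.

    Each argument is a ``(MolRecord, MolQM)`` tuple.  The two records must
    differ by exactly one hydrogen (checked with the structural-change
    filter); both graphs get the shared protonation energy
    ``E(protonated) - E(deprotonated)`` in their xTB-Energy slot.
    """
    from .sites import structural_change_filter

    (rec_p, qm_p), (rec_d, qm_d) = protonated, deprotonated
    if not structural_change_filter(rec_d, rec_p, "protonation"):
        raise ValueError(
            f"{rec_p.id}/{rec_d.id}: records do not differ by exactly one proton")
    g_p = featurize(rec_p, qm_p, schema)
    g_d = featurize(rec_d, qm_d, schema)
    de = qm_p.total_energy - qm_d.total_energy
    g_p.mol_features[-1] = de
    g_d.mol_features[-1] = de
    return g_p, g_d
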