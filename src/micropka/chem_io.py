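"""Reading, standardizing, filtering, augmenting and writing molecules.

The central container is :class:`MolRecord`: a standardized molecule with
explicit hydrogens, a single deterministically embedded 3D conformer and a
canonical SMILES.  Every downstream stage (QM features, graphs, site edits)
consumes MolRecords, so the conventions fixed here — 0-based atom indices,
explicit hydrogens, seed-from-SMILES conformers — hold across the package.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger("micropka")

#: Elements allowed in the training library (organic subset).
ALLOWED_ELEMENTS = frozenset({"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"})


@dataclass
class MolRecord:
    """A standardized molecule with explicit hydrogens and one conformer.

    Atom indices are 0-based and refer to the explicit-hydrogen atom order
    of ``mol`` (and of ``atoms`` / ``conformer`` rows).
    """

    id: str
    smiles_canonical: str
    atoms: List[tuple]  # (symbol, formal charge, total H count, chiral tag)
    bonds: List[tuple]  # (i, j, order) with order in {1, 1.5, 2, 3}
    conformer: Optional[np.ndarray]  # (n_atoms, 3) in Angstrom, or None
    net_charge: int
    mol: Chem.Mol = field(repr=False, compare=False, default=None)
    flagged: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def validate(self) -> None:
        if self.net_charge != sum(a[1] for a in self.atoms):
            raise ValueError("net_charge does not match sum of formal charges")
        if self.conformer is not None and self.conformer.shape != (self.n_atoms, 3):
            raise ValueError("conformer shape does not match atom count")
        if canonical_smiles(self.smiles_canonical) != self.smiles_canonical:
            raise ValueError("smiles_canonical is not canonical")


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.AROMATIC: 1.5,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
}


def canonical_smiles(smiles: str) -> str:
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(m)


def smiles_seed(smiles: str) -> int:
    """Stable conformer seed derived from a canonical SMILES (below 2^31)."""
    h = hashlib.sha256(smiles.encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1) + 1


def embed_conformer(mol: Chem.Mol, seed: int) -> np.ndarray:
    """Deterministic single-conformer 3D embedding (distance geometry).

    Falls back to flat 2D coordinates for species the distance-geometry
    embedder rejects, so every record carries *some* deterministic geometry.
    """
    mol = Chem.Mol(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.useRandomCoords = False
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            AllChem.Compute2DCoords(mol)
    conf = mol.GetConformer()
    return np.array(conf.GetPositions(), dtype=np.float64)


def record_from_mol(mol: Chem.Mol, mol_id: str, embed: bool = True,
                    flagged: bool = False,
                    coords: Optional[np.ndarray] = None) -> MolRecord:
    """Build a MolRecord from an RDKit mol (adds explicit Hs).

    The conformer is embedded deterministically unless ``coords`` provides
    geometry directly (used by structure edits that derive the product
    conformer from the parent's instead of re-embedding).
    """
    heavy = Chem.RemoveHs(Chem.Mol(mol))
    smiles = Chem.MolToSmiles(heavy)
    molh = Chem.AddHs(Chem.Mol(mol))
    Chem.SanitizeMol(molh)
    Chem.AssignStereochemistry(molh, cleanIt=True, force=True)
    atoms = [
        (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs() + sum(
            1 for nb in a.GetNeighbors() if nb.GetAtomicNum() == 1),
         str(a.GetChiralTag()))
        for a in molh.GetAtoms()
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER[b.GetBondType()])
        for b in molh.GetBonds()
    ]
    if coords is not None:
        conformer = np.asarray(coords, dtype=np.float64)
    else:
        conformer = embed_conformer(molh, smiles_seed(smiles)) if embed else None
    if conformer is not None:
        conf = Chem.Conformer(molh.GetNumAtoms())
        for i, xyz in enumerate(conformer):
            conf.SetAtomPosition(i, [float(x) for x in xyz])
        molh.RemoveAllConformers()
        molh.AddConformer(conf, assignId=True)
    return MolRecord(
        id=mol_id,
        smiles_canonical=smiles,
        atoms=atoms,
        bonds=bonds,
        conformer=conformer,
        net_charge=Chem.GetFormalCharge(molh),
        mol=molh,
        flagged=flagged,
    )


def read_molecules(path, fmt: str = "smiles") -> List[MolRecord]:
    """Read molecules from a .smi ("SMILES[ws]name") or SDF file.

    Invalid entries are skipped with a logged warning; the skip count is
    attached to the returned list as ``.n_skipped``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    records: List[MolRecord] = []
    skipped = 0
    if fmt == "smiles":
        for ln, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"mol{ln}"
            m = Chem.MolFromSmiles(smi)
            if m is None:
                skipped += 1
                log.warning("chem_io: skipping unparseable SMILES %r (line %d)", smi, ln + 1)
                continue
            records.append(record_from_mol(m, name, embed=False))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, m in enumerate(supplier):
            if m is None:
                skipped += 1
                log.warning("chem_io: skipping unreadable SDF entry %d", i)
                continue
            name = m.GetProp("_Name") if m.HasProp("_Name") and m.GetProp("_Name") else f"mol{i}"
            records.append(record_from_mol(m, name, embed=False))
    else:
        raise ValueError(f"unsupported format: {fmt}")

    class _RecList(list):
        pass

    out = _RecList(records)
    out.n_skipped = skipped
    return out


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Move protons to cancel +-1 charges on O/N/S until neutral or stuck.

    Rules: an O/N/S carrying -1 gains a hydrogen; an N carrying +1 with at
    least one hydrogen loses one.  This covers carboxylates, phenolates,
    thiolates, alkoxides and ammonium/anilinium species.
    """
    mol = Chem.RWMol(mol)
    changed = True
    while Chem.GetFormalCharge(mol) != 0 and changed:
        changed = False
        for atom in mol.GetAtoms():
            q = atom.GetFormalCharge()
            sym = atom.GetSymbol()
            if q == -1 and sym in ("O", "N", "S"):
                atom.SetFormalCharge(0)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
                changed = True
                break
            if q == +1 and sym == "N" and atom.GetTotalNumHs() >= 1:
                atom.SetFormalCharge(0)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
                atom.SetNoImplicit(True)
                changed = True
                break
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return m


def standardize(rec: MolRecord) -> MolRecord:
    """Largest-fragment selection, neutralization, explicit Hs, conformer.

    Records whose residual charge cannot be neutralized by the proton rules
    are passed through flagged, with a warning.
    """
    mol = Chem.MolFromSmiles(rec.smiles_canonical)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        # keep the largest covalent fragment (heavy-atom count, ties by SMILES)
        mol = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    mol = _neutralize(mol)
    flagged = Chem.GetFormalCharge(mol) != 0
    if flagged:
        log.warning("chem_io: %s not neutralizable (charge %+d), passing through",
                    rec.id, Chem.GetFormalCharge(mol))
    return record_from_mol(mol, rec.id, embed=True, flagged=flagged)


def element_filter(rec: MolRecord) -> bool:
    """True iff the molecule is organic over {H,C,N,O,S,P,F,Cl,Br,I}."""
    symbols = [a[0] for a in rec.atoms]
    return all(s in ALLOWED_ELEMENTS for s in symbols) and "C" in symbols


def pka_range_filter(pka: float) -> bool:
    """True iff 0 <= pKa <= 14 (training-library window, bounds inclusive)."""
    if np.isnan(pka):
        raise ValueError("pKa is NaN")
    return 0.0 <= pka <= 14.0


def invert_stereocenters(rec: MolRecord) -> Optional[MolRecord]:
    """Return the enantiomer record, or None if the molecule is achiral.

    Every tetrahedral chirality tag is flipped and the conformer is mirrored
    (x-axis negated) rather than re-embedded, so the enantiomer's 3D
    descriptors match the parent's bit for bit.  If flipping leaves the
    canonical SMILES unchanged (meso compounds), None is returned: no
    augmentation is emitted.
    """
    mol = Chem.Mol(rec.mol)
    n_flipped = 0
    for atom in mol.GetAtoms():
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
            n_flipped += 1
        elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
            n_flipped += 1
    if n_flipped == 0:
        return None
    smiles = Chem.MolToSmiles(Chem.RemoveHs(mol))
    if smiles == rec.smiles_canonical:
        return None
    mirrored = rec.conformer.copy() if rec.conformer is not None else None
    if mirrored is not None:
        mirrored[:, 0] *= -1.0
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(mirrored):
            conf.SetAtomPosition(i, [float(x) for x in xyz])
        mol.RemoveAllConformers()
        mol.AddConformer(conf, assignId=True)
    atoms = [(s, q, h, str(a.GetChiralTag()))
             for (s, q, h, _), a in zip(rec.atoms, mol.GetAtoms())]
    return MolRecord(
        id=rec.id + "_ent",
        smiles_canonical=smiles,
        atoms=atoms,
        bonds=list(rec.bonds),
        conformer=mirrored,
        net_charge=rec.net_charge,
        mol=mol,
        flagged=rec.flagged,
    )


PREDICTION_COLUMNS = ["id", "tautomer_smiles", "atom_index", "reaction", "pka"]


def write_predictions(records: Sequence[dict], path, fmt: str = "csv") -> None:
    """Write per-site predictions (atom indices 0-based).

    CSV columns, in order: id, tautomer_smiles, atom_index, reaction, pka.
    SDF output stores one entry per molecule with site predictions as
    properties ``site_<atom_index>_<reaction>``.
    """
    path = Path(path)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(PREDICTION_COLUMNS)
            for r in records:
                w.writerow([r["id"], r["tautomer_smiles"], r["atom_index"],
                            r["reaction"], f"{r['pka']:.4f}"])
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        by_mol: dict = {}
        for r in records:
            by_mol.setdefault((r["id"], r["tautomer_smiles"]), []).append(r)
        for (mid, smi), rows in by_mol.items():
            m = Chem.MolFromSmiles(smi)
            m.SetProp("_Name", mid)
            for r in rows:
                m.SetProp(f"site_{r['atom_index']}_{r['reaction']}", f"{r['pka']:.4f}")
            writer.write(m)
        writer.close()
    else:
        raise ValueError(f"unsupported format: {fmt}")


def read_predictions(path) -> List[dict]:
    """Read back a predictions CSV written by :func:`write_predictions`."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            row["atom_index"] = int(row["atom_index"])
            row["pka"] = float(row["pka"])
            out.append(row)
    return out
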