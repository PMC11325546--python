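"""Reproducible synthetic molecule libraries with known micro-pKa ground truth.

Molecules are assembled from a fragment grammar: templates carrying one or
two ionizable groups (carboxylic acids, phenols, thiols, amines, anilines,
pyridines, imidazoles) with two substituent slots drawn from inert alkyl /
aryl / halogenated / ether fragments.  Every generated molecule is neutral,
organic over the allowed element set, and ionizable by construction.

Ground-truth pKa values come from a *documented linear label function*:

    pka(site) = base[class] + w_hal * n_halogens(mol)
              + w_arom * arom_2bond(site) + w_ether * n_ether(mol)
              + Gaussian(0, noise_sd),  clipped to [0, 14]

with class the ionizable-group class of the site.  Linearity means a least
squares probe on the documented features recovers the coefficients exactly
on noiseless data — a guard that the generator leaks no hidden signal.

The weak/experimental benchmark mirrors a weak-label pretraining corpus
versus a small experimental fine-tuning set: the experimental label
function is the weak one shifted by a documented systematic offset, and
the two sets are disjoint by molecule.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .chem_io import MolRecord, element_filter, record_from_mol, standardize
from .graphs import DEFAULT_SCHEMA
from .pka import PairExample, build_pairs
from .qm import get_backend
from .sites import SiteLabelSet, oracle_label

log = logging.getLogger("micropka")

# template -> (smiles with {R1}/{R2} slots); slots are always parenthesized
TEMPLATES: List[str] = [
    "OC(=O)C({R1})({R2})",          # carboxylic acid
    "OC(=O)c1cc({R1})cc({R2})c1",   # benzoic acid
    "Oc1cc({R1})cc({R2})c1",        # phenol
    "SC({R1})({R2})",               # thiol
    "NC({R1})({R2})",               # primary amine
    "CNC({R1})({R2})",              # secondary amine
    "Nc1cc({R1})cc({R2})c1",        # aniline
    "c1cc({R1})cc({R2})n1",         # pyridine
    "C({R1})({R2})c1ncc[nH]1",      # imidazole (basic n + acidic NH)
    "OC(=O)C({R1})Cc1cc({R2})ccn1", # acid + pyridine (bifunctional)
]

# inert substituents: no N, no O-H/S-H, allowed elements only; ring labels
# use digit 8 so they can never collide with template ring closures
SUBSTITUENTS: List[str] = [
    "", "C", "CC", "CCC", "C(C)C", "CCCC", "C(C)(C)C",
    "c8ccccc8", "Cc8ccccc8", "C8CCCCC8",
    "CF", "CCF", "CCl", "CCCl", "CCBr", "CCI", "C(F)(F)F", "CC(F)F",
    "COC", "CCOC", "CSC", "CCSC",
    "CCCCC", "CC(C)CC", "CCc8ccccc8", "CCCF", "CCCBr", "CCC(F)(F)F",
    "COCC", "CSCC", "CC8CCCC8", "Cc8ccc(F)cc8", "Cc8ccc(Cl)cc8", "CCCI",
]

#: site classes, their base pKa values and the shared correction weights
CLASS_ORDER: List[str] = [
    "carboxylic_acid", "phenol", "thiol", "ring_nh",
    "primary_amine", "secondary_amine", "tertiary_amine",
    "aniline", "pyridine_n", "imidazole_n",
]
BASE_PKA: Dict[str, float] = {
    "carboxylic_acid": 4.2, "phenol": 9.9, "thiol": 8.6, "ring_nh": 12.5,
    "primary_amine": 10.6, "secondary_amine": 10.8, "tertiary_amine": 10.1,
    "aniline": 4.6, "pyridine_n": 5.2, "imidazole_n": 7.0,
}
W_HALOGEN = -0.55   # per halogen atom in the molecule
W_AROM = -0.40      # site within two bonds of an aromatic atom
W_ETHER = -0.20     # per ether/thioether heteroatom in the molecule

_HALOGENS = {"F", "Cl", "Br", "I"}


@dataclass
class SyntheticSpec:
    """Generation conditions: size, seed, noise and label parameters."""

    n_molecules: int = 500
    seed: int = 0
    noise_sd: float = 0.3            # pKa units; 0 for oracle-equivalence tests
    label_offset: float = 0.0        # systematic shift (experimental sets)
    templates: Tuple[str, ...] = tuple(TEMPLATES)
    substituents: Tuple[str, ...] = tuple(SUBSTITUENTS)

    def to_dict(self) -> dict:
        return {"n_molecules": self.n_molecules, "seed": self.seed,
                "noise_sd": self.noise_sd, "label_offset": self.label_offset,
                "templates": list(self.templates),
                "substituents": list(self.substituents)}

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["templates"] = tuple(d["templates"])
        d["substituents"] = tuple(d["substituents"])
        return cls(**d)


def _fill(template: str, r1: str, r2: str) -> str:
    s = template.replace("({R1})", f"({r1})" if r1 else "")
    return s.replace("({R2})", f"({r2})" if r2 else "")


def gen_library(spec: SyntheticSpec) -> List[MolRecord]:
    """Assemble ``n_molecules`` unique standardized records from the grammar.

    Combinations are enumerated, shuffled with the spec seed, deduplicated
    by canonical SMILES and truncated; running the same spec twice yields
    byte-identical SMILES lists.
    """
    combos = [(t, r1, r2) for t in spec.templates
              for r1 in spec.substituents for r2 in spec.substituents]
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(combos))
    records: List[MolRecord] = []
    seen = set()
    for k in order:
        if len(records) >= spec.n_molecules:
            break
        t, r1, r2 = combos[k]
        smi = _fill(t, r1, r2)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        rec = standardize(record_from_mol(mol, f"syn{spec.seed}_{len(records)}",
                                          embed=False))
        if not element_filter(rec):
            continue
        records.append(rec)
    if len(records) < spec.n_molecules:
        raise ValueError(
            f"grammar exhausted: {len(records)} unique molecules available, "
            f"{spec.n_molecules} requested")
    return records


# ---------------------------------------------------------------------------
# label function


def classify_site(rec: MolRecord, atom_index: int) -> Optional[str]:
    """Map a labeled site atom to its ionizable-group class (or None)."""
    atom = rec.mol.GetAtomWithIdx(atom_index)
    sym = atom.GetSymbol()
    heavy_nbrs = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1]
    n_h = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1) \
        + atom.GetTotalNumHs()
    if sym == "O" and n_h >= 1:
        for nb in heavy_nbrs:
            if nb.GetIsAromatic():
                return "phenol"
            if nb.GetSymbol() == "C" and any(
                    b.GetBondType() == Chem.BondType.DOUBLE
                    and b.GetOtherAtom(nb).GetSymbol() == "O"
                    for b in nb.GetBonds()):
                return "carboxylic_acid"
        return None  # aliphatic alcohols fall outside the pKa window
    if sym == "S" and n_h >= 1:
        return "thiol"
    if sym == "N":
        if atom.GetIsAromatic():
            if n_h >= 1:
                return "ring_nh"
            return "imidazole_n" if atom.IsInRingSize(5) else "pyridine_n"
        if any(nb.GetIsAromatic() for nb in heavy_nbrs) and n_h >= 1:
            return "aniline"
        if n_h >= 2:
            return "primary_amine"
        if n_h == 1:
            return "secondary_amine"
        return "tertiary_amine"
    return None


def label_features(rec: MolRecord, atom_index: int) -> Optional[np.ndarray]:
    """Documented feature vector phi(site): class one-hot + corrections."""
    cls = classify_site(rec, atom_index)
    if cls is None:
        return None
    n_hal = sum(1 for s, *_ in rec.atoms if s in _HALOGENS)
    n_ether = 0
    for atom in rec.mol.GetAtoms():
        if atom.GetSymbol() in ("O", "S") and not atom.GetIsAromatic():
            nbrs = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1]
            h = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1)
            if len(nbrs) == 2 and h == 0:
                n_ether += 1
    site = rec.mol.GetAtomWithIdx(atom_index)
    arom = 0.0
    for nb in site.GetNeighbors():
        if nb.GetIsAromatic():
            arom = 1.0
        for nb2 in nb.GetNeighbors():
            if nb2.GetIsAromatic():
                arom = 1.0
    phi = np.zeros(len(CLASS_ORDER) + 3)
    phi[CLASS_ORDER.index(cls)] = 1.0
    phi[-3:] = (n_hal, arom, n_ether)
    return phi


def label_weights() -> np.ndarray:
    """The true coefficient vector of the linear label function."""
    return np.array([BASE_PKA[c] for c in CLASS_ORDER]
                    + [W_HALOGEN, W_AROM, W_ETHER])


def _site_noise(spec: SyntheticSpec, mol_id: str, atom_index: int,
                reaction: str) -> float:
    if spec.noise_sd == 0:
        return 0.0
    key = f"{spec.seed}|{mol_id}|{atom_index}|{reaction}".encode()
    sub = int.from_bytes(hashlib.sha256(key).digest()[:4], "big")
    return float(np.random.default_rng(sub).normal(0.0, spec.noise_sd))


def assign_labels(rec: MolRecord, spec: SyntheticSpec,
                  backend=None) -> Tuple[SiteLabelSet, SiteLabelSet,
                                         Dict[Tuple[int, str], float]]:
    """Oracle site labels plus ground-truth pKa for every classifiable site.

    Returns (protonation labels, deprotonation labels, pKa map keyed by
    (atom_index, reaction)).  Sites the class table cannot name are
    unlabeled.  Noise is hashed from (seed, molecule, site), so labels are
    reproducible molecule by molecule.
    """
    backend = get_backend("mock") if backend is None else backend
    prot, deprot = oracle_label(rec, backend=backend)
    w = label_weights()
    pka_map: Dict[Tuple[int, str], float] = {}
    for lbl, reaction in ((prot, "protonation"), (deprot, "deprotonation")):
        keep = np.zeros_like(lbl.labels)
        for idx in np.flatnonzero(lbl.labels):
            phi = label_features(rec, int(idx))
            if phi is None:
                continue
            keep[idx] = 1
            pka = float(phi @ w) + spec.label_offset \
                + _site_noise(spec, rec.id, int(idx), reaction)
            pka_map[(int(idx), reaction)] = float(np.clip(pka, 0.0, 14.0))
        lbl.labels = keep
    return prot, deprot, pka_map


# ---------------------------------------------------------------------------
# benchmark datasets


def _pairs_for_record(rec: MolRecord, spec: SyntheticSpec, backend
                      ) -> List[PairExample]:
    """Weak-label policy: one acidic + one basic pair per molecule, each at
    the lowest-energy labeled site of its reaction."""
    prot, deprot, pka_map = assign_labels(rec, spec, backend)
    pairs: List[PairExample] = []
    from .sites import deprotonate_at, protonate_at

    for lbl, reaction, edit in ((deprot, "deprotonation", deprotonate_at),
                                (prot, "protonation", protonate_at)):
        sites = [int(i) for i in np.flatnonzero(lbl.labels)]
        if not sites:
            continue
        best = min(sites, key=lambda i: backend.energy(edit(rec, i)))
        keep = np.zeros_like(lbl.labels)
        keep[best] = 1
        one = SiteLabelSet(rec.id, keep, reaction)
        labels = (one, SiteLabelSet(rec.id, np.zeros_like(keep), "deprotonation")) \
            if reaction == "protonation" else \
            (SiteLabelSet(rec.id, np.zeros_like(keep), "protonation"), one)
        reaction_out = "basic" if reaction == "protonation" else "acidic"
        targets = {(best, reaction_out): pka_map[(best, reaction)]}
        pairs.extend(build_pairs(rec, labels, backend, DEFAULT_SCHEMA,
                                 targets=targets))
    return pairs


def make_benchmark(spec_weak: SyntheticSpec, spec_exp: SyntheticSpec,
                   n_weak_pairs: Optional[int] = None,
                   n_exp_pairs: Optional[int] = None,
                   backend=None):
    """Build disjoint weak-label and experimental-style pair datasets.

    Molecules appearing (by canonical SMILES) in the weak set are removed
    from the experimental set.  Returns (weak_pairs, exp_pairs, manifest);
    regenerating from the manifest reproduces both datasets exactly.
    """
    backend = get_backend("mock") if backend is None else backend
    weak_lib = gen_library(spec_weak)
    exp_lib = gen_library(spec_exp)
    weak_smiles = {r.smiles_canonical for r in weak_lib}
    kept_exp = [r for r in exp_lib if r.smiles_canonical not in weak_smiles]
    n_dropped = len(exp_lib) - len(kept_exp)
    if n_dropped:
        log.info("synthetic: dropped %d overlapping experimental molecules",
                 n_dropped)

    def collect(lib, cap):
        pairs = []
        for rec in lib:
            pairs.extend(_pairs_for_record(rec, spec_weak if lib is weak_lib
                                           else spec_exp, backend))
            if cap is not None and len(pairs) >= cap:
                break
        return pairs[:cap] if cap is not None else pairs

    weak_pairs = collect(weak_lib, n_weak_pairs)
    exp_pairs = collect(kept_exp, n_exp_pairs)
    manifest = {
        "spec_weak": spec_weak.to_dict(), "spec_exp": spec_exp.to_dict(),
        "n_weak_pairs": len(weak_pairs), "n_exp_pairs": len(exp_pairs),
        "caps": [n_weak_pairs, n_exp_pairs],
        "n_exp_overlap_dropped": n_dropped,
    }
    return weak_pairs, exp_pairs, manifest


def regenerate(manifest: dict, backend=None):
    """Rebuild the benchmark datasets recorded in a manifest."""
    return make_benchmark(SyntheticSpec.from_dict(manifest["spec_weak"]),
                          SyntheticSpec.from_dict(manifest["spec_exp"]),
                          n_weak_pairs=manifest["caps"][0],
                          n_exp_pairs=manifest["caps"][1],
                          backend=backend)


def gen_chiral_library(n_molecules: int, seed: int) -> List[MolRecord]:
    """Chiral variants of grammar molecules with assigned stereocenters.

    Molecules with unassigned tetrahedral centers get one deterministic
    stereo assignment, so each record has a genuine enantiomer (the
    mirror-augmentation tests need molecules where inversion changes the
    canonical SMILES).
    """
    from rdkit.Chem.EnumerateStereoisomers import (
        EnumerateStereoisomers, StereoEnumerationOptions)

    pool = gen_library(SyntheticSpec(n_molecules=max(4 * n_molecules, 40),
                                     seed=seed, noise_sd=0.0))
    out: List[MolRecord] = []
    opts = StereoEnumerationOptions(maxIsomers=1, onlyUnassigned=True)
    for rec in pool:
        if len(out) >= n_molecules:
            break
        mol = Chem.MolFromSmiles(rec.smiles_canonical)
        isomer = next(iter(EnumerateStereoisomers(mol, options=opts)), None)
        if isomer is None:
            continue
        smi = Chem.MolToSmiles(isomer)
        if "@" not in smi:
            continue
        out.append(standardize(record_from_mol(isomer, rec.id + "_chiral",
                                               embed=False)))
    if len(out) < n_molecules:
        raise ValueError(
            f"only {len(out)} chiral molecules available from this grammar")
    return out


def write_library(records: Sequence[MolRecord], spec: SyntheticSpec,
                  smi_path, labels_path, manifest_path,
                  backend=None) -> None:
    """Emit .smi + per-site label CSV + manifest JSON for a library."""
    import csv

    backend = get_backend("mock") if backend is None else backend
    with open(smi_path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles_canonical} {r.id}\n")
    with open(labels_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "atom_index", "reaction", "pka"])
        for r in records:
            _, _, pka_map = assign_labels(r, spec, backend)
            for (idx, reaction), pka in sorted(pka_map.items()):
                w.writerow([r.id, idx, reaction, f"{pka:.4f}"])
    with open(manifest_path, "w") as fh:
        json.dump(spec.to_dict(), fh, indent=1)
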