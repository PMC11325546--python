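"""Neutral-tautomer enumeration and lowest-energy selection.

The first pipeline stage: enumerate the neutral tautomers of a standardized
molecule with the stock transform-rule collection (keto-enol, amide-imidic
acid, lactam-lactim, ...) and keep the one with the lowest total electronic
energy in implicit water.  The search deliberately covers only neutral
species; tautomers of ions and zwitterions are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem_io import MolRecord, record_from_mol
from .qm import get_backend

log = logging.getLogger("micropka")

DEFAULT_MAX_TAUTOMERS = 64


@dataclass
class TautomerSet:
    """All enumerated tautomers of one parent, with energies and the pick."""

    parent_id: str
    tautomers: List[MolRecord]
    energies: List[float]  # Hartree, parallel to tautomers
    selected_index: int

    @property
    def selected(self) -> MolRecord:
        return self.tautomers[self.selected_index]


def enumerate_tautomers(rec: MolRecord,
                        max_tautomers: int = DEFAULT_MAX_TAUTOMERS) -> List[MolRecord]:
    """Enumerate neutral tautomers, deduplicated by canonical SMILES.

    The input form is always present in the output.  The list is truncated
    at ``max_tautomers`` (input form kept) with a warning.
    """
    if rec.net_charge != 0:
        raise ValueError(
            f"{rec.id}: tautomer enumeration requires a neutral molecule "
            "(standardize first)")
    enumerator = rdMolStandardize.TautomerEnumerator()
    enumerator.SetMaxTautomers(max(max_tautomers, 1))
    mol = Chem.MolFromSmiles(rec.smiles_canonical)
    seen = {rec.smiles_canonical}
    out = [rec]
    for taut in enumerator.Enumerate(mol):
        smi = Chem.MolToSmiles(taut)
        if smi in seen:
            continue
        seen.add(smi)
        out.append(record_from_mol(taut, f"{rec.id}_t{len(out)}", embed=True))
    if len(out) > max_tautomers:
        log.warning("tautomer: %s truncated to %d tautomers", rec.id, max_tautomers)
        out = out[:max_tautomers]
    return out


def select_stable_tautomer(tautomers: List[MolRecord], backend="mock") -> TautomerSet:
    """Rank tautomers by total electronic energy; keep the most stable.

    Ties are broken by the lexicographically smallest canonical SMILES.
    Backend failures on non-input forms drop those forms with a warning; a
    failure on the input form (index 0) aborts.
    """
    if not tautomers:
        raise ValueError("empty tautomer list")
    if isinstance(backend, str):
        backend = get_backend(backend)
    kept: List[MolRecord] = []
    energies: List[float] = []
    for k, t in enumerate(tautomers):
        try:
            energies.append(backend.energy(t))
            kept.append(t)
        except Exception as exc:
            if k == 0:
                raise
            log.warning("tautomer: dropping %s (backend failure: %s)", t.id, exc)
    if not kept:
        raise RuntimeError("all tautomer energy evaluations failed")
    selected = min(range(len(kept)),
                   key=lambda i: (energies[i], kept[i].smiles_canonical))
    return TautomerSet(
        parent_id=tautomers[0].id,
        tautomers=kept,
        energies=energies,
        selected_index=selected,
    )


def most_stable_tautomer(rec: MolRecord, backend="mock",
                         max_tautomers: int = DEFAULT_MAX_TAUTOMERS) -> TautomerSet:
    """Convenience wrapper: enumerate then select."""
    return select_stable_tautomer(enumerate_tautomers(rec, max_tautomers), backend)
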