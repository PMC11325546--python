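"""Pluggable quantum-chemistry feature backends.

The package consumes semiempirical tight-binding descriptors — per-atom
partial charges, Fukui indices, coordination numbers, polarizabilities,
per-bond Wiberg orders and a total electronic energy in implicit water.
Two backends provide them behind one contract:

* ``MockBackend`` — a fully deterministic, dependency-free surrogate whose
  formulas are written out below.  It preserves the *structure* of the real
  descriptors (charge conservation, positive bond orders, charge-sensitive
  energies) so models and filters exercise the same code paths.
* ``XTBBackend`` — an adapter that shells out to an external GFN2-xTB
  executable in single-point mode with ALPB water solvation.

Energies are in Hartree throughout; the eV conversion used by the
site-energy window lives in :func:`relative_energy_ev`.
"""

from __future__ import annotations

import hashlib
import shutil
import subprocess
from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .chem_io import MolRecord

HARTREE_TO_EV = 27.211386

# Pauling electronegativities and free-atom dipole polarizabilities (a.u.)
ELECTRONEGATIVITY: Dict[str, float] = {
    "H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44, "S": 2.58, "P": 2.19,
    "F": 3.98, "Cl": 3.16, "Br": 2.96, "I": 2.66,
}
POLARIZABILITY: Dict[str, float] = {
    "H": 4.51, "C": 11.3, "N": 7.4, "O": 5.3, "S": 19.4, "P": 25.0,
    "F": 3.74, "Cl": 14.6, "Br": 21.0, "I": 32.9,
}
# crude per-element electronic energy terms (Hartree) for the mock energy
_ELEMENT_ENERGY: Dict[str, float] = {
    "H": -0.5, "C": -5.0, "N": -7.2, "O": -9.8, "S": -10.5, "P": -9.0,
    "F": -12.4, "Cl": -12.0, "Br": -11.5, "I": -11.0,
}
_VALENCE_ELECTRONS: Dict[str, int] = {
    "H": 1, "C": 4, "N": 5, "O": 6, "S": 6, "P": 5,
    "F": 7, "Cl": 7, "Br": 7, "I": 7,
}


class BackendUnavailable(RuntimeError):
    """The requested backend cannot run (e.g. no executable on PATH)."""


class BackendFailure(RuntimeError):
    """The backend ran but failed; carries captured diagnostics."""


@dataclass
class MolQM:
    """Per-atom / per-bond / whole-molecule QM-derived features."""

    partial_charge: np.ndarray   # (N,) in e; sums to the net formal charge
    fukui_plus: np.ndarray       # (N,) nucleophilic-attack susceptibility
    fukui_zero: np.ndarray       # (N,) radical-attack susceptibility
    fukui_minus: np.ndarray      # (N,) electrophilic-attack susceptibility
    coord_number: np.ndarray     # (N,) covalent coordination number
    polarizability: np.ndarray   # (N,) atomic polarizability, a.u.
    wiberg_order: np.ndarray     # (n_bonds,) parallel to MolRecord.bonds
    total_energy: float          # Hartree
    solvated: bool = True

    def validate(self, rec: MolRecord) -> None:
        n = rec.n_atoms
        for name in ("partial_charge", "fukui_plus", "fukui_zero",
                     "fukui_minus", "coord_number", "polarizability"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} misaligned with molecule")
        if self.wiberg_order.shape != (len(rec.bonds),):
            raise ValueError("wiberg_order misaligned with bonds")
        if not np.all(self.wiberg_order > 0):
            raise ValueError("non-positive Wiberg order")


def relative_energy_ev(e_a: float, e_b: float) -> float:
    """(e_b - e_a) converted from Hartree to eV."""
    return (e_b - e_a) * HARTREE_TO_EV


def _smiles_jitter(smiles: str, scale: float) -> float:
    """Deterministic pseudo-random term in [0, scale) from a SMILES hash."""
    h = hashlib.sha256(smiles.encode()).digest()
    return int.from_bytes(h[4:8], "big") / 2**32 * scale


class MockBackend:
    """Deterministic surrogate QM backend.

    Formulas (all documented so tests can assert them):

    * partial charge: one electronegativity-equalization sweep over the
      bond graph — ``q_i = f_i - k * sum_j w_ij (chi_i - chi_j) / (chi_i + chi_j)``
      with ``k = 0.16`` and ``w_ij`` the integer/aromatic bond order; the
      pairwise terms are antisymmetric, so the sum equals the net formal
      charge; any floating-point residual is shifted onto the
      highest-degree atom so conservation is exact.
    * coordination number: heavy-atom degree + 0.5 x bonded hydrogens.
    * Fukui indices: degree/valence heuristics (electron-rich atoms score
      high on f-, electron-poor on f+, low-coordination on f0), each
      normalized to sum to 1 over the atoms.
    * polarizability: free-atom element lookup.
    * Wiberg order: bond order damped by electronegativity mismatch,
      ``w = order * (1 - 0.05 |chi_i - chi_j|)`` — always positive.
    * total energy: element terms + ``-0.04 x`` bond orders + quadratic net
      charge penalty (0.15 q^2 Hartree) + a small jitter (< 0.05 Hartree)
      hashed from the canonical SMILES so distinct isomers rank distinctly.
    """

    name = "mock"

    def compute(self, rec: MolRecord) -> MolQM:
        if rec.conformer is not None:
            d = np.linalg.norm(
                rec.conformer[:, None, :] - rec.conformer[None, :, :], axis=-1)
            np.fill_diagonal(d, 1.0)
            if rec.n_atoms > 1 and d.min() < 1e-3:
                raise BackendFailure(f"{rec.id}: overlapping atoms in geometry")
        symbols = [a[0] for a in rec.atoms]
        formal = np.array([a[1] for a in rec.atoms], dtype=float)
        chi = np.array([ELECTRONEGATIVITY.get(s, 2.5) for s in symbols])
        n = rec.n_atoms

        heavy_deg = np.zeros(n)
        h_deg = np.zeros(n)
        bond_order_sum = np.zeros(n)
        # charges live on a dyadic grid (multiples of 2^-30): integer
        # transfer terms cancel pairwise exactly, and dyadic floats of this
        # magnitude add without rounding, so the float sum of the partial
        # charges equals the net formal charge bit for bit
        grid = 2**30
        q_int = np.array([int(f) * grid for f in formal], dtype=np.int64)
        for i, j, order in rec.bonds:
            t = int(round(0.16 * order * (chi[i] - chi[j]) / (chi[i] + chi[j])
                          * grid))
            q_int[i] -= t
            q_int[j] += t
            for a, b in ((i, j), (j, i)):
                if symbols[b] == "H":
                    h_deg[a] += 1
                else:
                    heavy_deg[a] += 1
                bond_order_sum[a] += order
        residual = rec.net_charge * grid - int(q_int.sum())
        q_int[int(np.argmax(heavy_deg + h_deg))] += residual
        q = q_int.astype(np.float64) / grid

        cn = heavy_deg + 0.5 * h_deg
        valence = np.array([_VALENCE_ELECTRONS.get(s, 4) for s in symbols], dtype=float)
        lone = np.maximum(valence - formal - bond_order_sum, 0.0)

        def _norm(v):
            s = v.sum()
            return v / s if s > 0 else np.full(n, 1.0 / n)

        fukui_minus = _norm(lone * chi)            # electron-rich centers
        fukui_plus = _norm(np.maximum(q, 0) + 0.1) # electron-poor centers
        fukui_zero = _norm(1.0 / (1.0 + heavy_deg + h_deg))

        alpha = np.array([POLARIZABILITY.get(s, 10.0) for s in symbols])
        wiberg = np.array(
            [o * (1.0 - 0.05 * abs(chi[i] - chi[j])) for i, j, o in rec.bonds])

        qm = MolQM(
            partial_charge=q,
            fukui_plus=fukui_plus,
            fukui_zero=fukui_zero,
            fukui_minus=fukui_minus,
            coord_number=cn,
            polarizability=alpha,
            wiberg_order=wiberg,
            total_energy=self.energy(rec),
            solvated=True,
        )
        qm.validate(rec)
        return qm

    def energy(self, rec: MolRecord) -> float:
        """Mock total electronic energy in Hartree (see class docstring).

        The jitter hashes the *stereo-agnostic* canonical SMILES, so
        enantiomers — identical bond graphs — get bit-identical energies.
        """
        from rdkit import Chem

        e = sum(_ELEMENT_ENERGY.get(a[0], -6.0) for a in rec.atoms)
        e += -0.04 * sum(o for _, _, o in rec.bonds)
        e += 0.15 * rec.net_charge**2
        flat = Chem.MolToSmiles(Chem.MolFromSmiles(rec.smiles_canonical),
                                isomericSmiles=False)
        e += _smiles_jitter(flat, 0.05)
        return e


class XTBBackend:
    """Adapter to an external GFN2-xTB executable (single point, ALPB water).

    Only the subprocess contract is implemented here; when the executable is
    absent the constructor raises :class:`BackendUnavailable` so pipelines
    can fall back or abort per molecule without crashing the batch.
    """

    name = "gfn2xtb"

    def __init__(self, executable: str = "xtb"):
        self.executable = shutil.which(executable)
        if self.executable is None:
            raise BackendUnavailable(
                f"external backend executable {executable!r} not found on PATH")

    def compute(self, rec: MolRecord) -> MolQM:  # pragma: no cover - needs binary
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as tmp:
            xyz = Path(tmp) / "mol.xyz"
            lines = [str(rec.n_atoms), rec.id]
            for (sym, *_), pos in zip(rec.atoms, rec.conformer):
                lines.append(f"{sym} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f}")
            xyz.write_text("\n".join(lines) + "\n")
            cmd = [self.executable, str(xyz), "--gfn", "2", "--alpb", "water",
                   "--chrg", str(rec.net_charge), "--sp", "--vfukui"]
            proc = subprocess.run(cmd, cwd=tmp, capture_output=True, text=True)
            if proc.returncode != 0:
                raise BackendFailure(
                    f"{rec.id}: xtb exited {proc.returncode}\n{proc.stderr[-2000:]}")
            raise BackendFailure(
                f"{rec.id}: parsing of external xtb output not configured")

    def energy(self, rec: MolRecord) -> float:  # pragma: no cover - needs binary
        return self.compute(rec).total_energy


_BACKENDS = {"mock": MockBackend, "gfn2xtb": XTBBackend}


def get_backend(name: str = "mock", **kwargs):
    """Instantiate a backend by name (``mock`` or ``gfn2xtb``)."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ValueError(f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}")
    return cls(**kwargs)


def compute_qm(rec: MolRecord, backend="mock") -> MolQM:
    """Compute QM features for a standardized record.

    ``backend`` may be a backend name or an instantiated backend object.
    """
    if isinstance(backend, str):
        backend = get_backend(backend)
    return backend.compute(rec)


def mock_energy(rec: MolRecord) -> float:
    """Deterministic surrogate total energy (Hartree) — see MockBackend."""
    return MockBackend().energy(rec)
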