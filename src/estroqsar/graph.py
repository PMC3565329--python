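"""Lightweight molecular-graph container used by the descriptor routines.

A :class:`MolecularGraph` carries exactly what the topological and geometric
descriptors need: heavy-atom connectivity, optional 3D coordinates and
per-atom van der Waals radii.  It can be built by hand (for tests and toy
systems) or converted from an RDKit molecule / SMILES string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

try:  # rdkit is a hard dependency, but keep the import point explicit
    from rdkit import Chem
    from rdkit.Chem import AllChem
except ImportError as _exc:  # pragma: no cover
    raise ImportError("estroqsar requires rdkit for structure handling") from _exc


#: Bondi (1964) van der Waals radii in Å for the elements that occur in
#: steroidal phenols and common organic molecules.  Overridable per call.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

DEFAULT_RADIUS = 1.70  # fallback for elements missing from the table


class StructureError(ValueError):
    """Raised when a molecular graph violates a descriptor's preconditions."""


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    aromatic: bool = False


@dataclass
class MolecularGraph:
    """Hydrogen-handling mode is recorded: ``explicit_hydrogens`` tells
    geometric descriptors whether H atoms are present in the atom list."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]  # (i, j, bond order)
    coords: Optional[np.ndarray] = None  # (n_atoms, 3) in Å
    radii: Optional[np.ndarray] = None  # per-atom vdW radii in Å
    explicit_hydrogens: bool = False
    rdkit_mol: Optional["Chem.Mol"] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise StructureError(f"bond ({i},{j}) references missing atoms")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise StructureError(
                    f"coordinates shape {self.coords.shape} does not cover all {n} atoms"
                )
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if self.radii.shape != (n,):
                raise StructureError("radii must give one value per atom")

    # ---------------------------------------------------------------- counts
    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    @property
    def n_heavy_bonds(self) -> int:
        """Bonds between two heavy atoms (paths of length 1 in the
        hydrogen-suppressed graph)."""
        return sum(
            1
            for i, j, _ in self.bonds
            if self.atoms[i].element != "H" and self.atoms[j].element != "H"
        )

    def is_connected(self) -> bool:
        """Connectivity of the hydrogen-suppressed graph."""
        heavy = [k for k, a in enumerate(self.atoms) if a.element != "H"]
        if not heavy:
            return False
        adj: dict[int, list[int]] = {k: [] for k in heavy}
        heavy_set = set(heavy)
        for i, j, _ in self.bonds:
            if i in heavy_set and j in heavy_set:
                adj[i].append(j)
                adj[j].append(i)
        seen = {heavy[0]}
        stack = [heavy[0]]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(heavy)

    def default_radii(self) -> np.ndarray:
        return np.array(
            [BONDI_RADII.get(a.element, DEFAULT_RADIUS) for a in self.atoms]
        )

    # ------------------------------------------------------------- builders
    @classmethod
    def from_rdkit(
        cls, mol: "Chem.Mol", conformer_id: int = -1
    ) -> "MolecularGraph":
        atoms = [
            Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
            for a in mol.GetAtoms()
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        ]
        coords = None
        if mol.GetNumConformers():
            coords = np.array(mol.GetConformer(conformer_id).GetPositions())
        g = cls(
            atoms=atoms,
            bonds=bonds,
            coords=coords,
            explicit_hydrogens=any(a.element == "H" for a in atoms),
            rdkit_mol=mol,
        )
        g.radii = g.default_radii()
        return g

    @classmethod
    def from_smiles(
        cls,
        smiles: str,
        embed3d: bool = False,
        add_hydrogens: bool = False,
        seed: int = 2013,
    ) -> "MolecularGraph":
        """Parse a SMILES string; optionally add explicit hydrogens and a
        deterministic ETKDG 3D embedding (MMFF-minimised) for SASA."""
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise StructureError(f"unparseable SMILES: {smiles!r}")
        if add_hydrogens or embed3d:
            mol = Chem.AddHs(mol)
        if embed3d:
            params = AllChem.ETKDGv3()
            params.randomSeed = seed
            if AllChem.EmbedMolecule(mol, params) != 0:
                raise StructureError(f"3D embedding failed for {smiles!r}")
            AllChem.MMFFOptimizeMolecule(mol)
        return cls.from_rdkit(mol)


def as_graph(mol: "MolecularGraph | Chem.Mol | str", **kwargs) -> MolecularGraph:
    """Normalise the accepted structure inputs to a :class:`MolecularGraph`."""
    if isinstance(mol, MolecularGraph):
        return mol
    if isinstance(mol, str):
        return MolecularGraph.from_smiles(mol, **kwargs)
    return MolecularGraph.from_rdkit(mol)
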