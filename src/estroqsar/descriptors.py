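"""The five molecular descriptors that enter the potency models.

===========  ========  =============================================
descriptor   units     meaning
===========  ========  =============================================
BDE          kcal/mol  phenolic O–H bond dissociation enthalpy, from
                       an enthalpy cycle over quantum-chemical heats
                       of formation (supplied, not computed here)
SI_k1        —         Kier first-order kappa shape index (plain,
                       non-alpha variant, hydrogen-suppressed graph)
SA           Å²        solvent-accessible surface area, Shrake–Rupley
logP         —         octanol/water partition coefficient, Wildman–
                       Crippen atom-contribution estimate
HOMO         eV        highest-occupied-molecular-orbital energy
                       (supplied, not computed here)
===========  ========  =============================================

BDE and HOMO come from semi-empirical quantum chemistry, which is outside
this package's scope: they are consumed as inputs (the BDE from a pair of
enthalpies of formation via :func:`bond_dissociation_enthalpy`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import rdMolDescriptors

from .graph import MolecularGraph, StructureError, as_graph

#: Experimental gas-phase enthalpy of formation of the hydrogen atom,
#: kcal/mol, used to close the O–H homolysis cycle.
H_ATOM_ENTHALPY = 52.08

#: Version tag for the atom-contribution logP parameter table in use.
LOGP_TABLE_VERSION = "Wildman-Crippen (RDKit implementation)"

DESCRIPTOR_NAMES = ("BDE", "SI_k1", "SA", "logP", "HOMO")


class DescriptorError(ValueError):
    """Invalid input to a descriptor computation."""


@dataclass(frozen=True)
class EnthalpyPair:
    """Heats of formation (kcal/mol) of a parent phenol and its phenoxyl
    radical, as produced by an external quantum-chemistry calculation."""

    H_p: float
    H_r: float


@dataclass
class DescriptorVector:
    """Values for the five model descriptors; missing entries are ``None``
    (never silently zero)."""

    BDE: Optional[float] = None
    SI_k1: Optional[float] = None
    SA: Optional[float] = None
    logP: Optional[float] = None
    HOMO: Optional[float] = None

    def get(self, name: str) -> Optional[float]:
        if name not in DESCRIPTOR_NAMES:
            raise KeyError(f"unknown descriptor {name!r}")
        return getattr(self, name)

    def as_dict(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}

    def missing(self) -> list[str]:
        return [name for name in DESCRIPTOR_NAMES if getattr(self, name) is None]


def bond_dissociation_enthalpy(
    pair: EnthalpyPair, H_H: float = H_ATOM_ENTHALPY
) -> float:
    """O–H bond dissociation enthalpy from the homolysis cycle
    ArOH → ArO• + H•:  BDE = H_r + H_H − H_p  (all kcal/mol).

    When parent and radical have equal heats of formation the BDE reduces
    to the hydrogen-atom term itself.
    """
    for value, label in ((pair.H_p, "H_p"), (pair.H_r, "H_r"), (H_H, "H_H")):
        if not math.isfinite(value):
            raise DescriptorError(f"{label} must be finite, got {value!r}")
    return pair.H_r + H_H - pair.H_p


def kier_kappa1(mol) -> float:
    """Plain first-order Kier kappa shape index on the hydrogen-suppressed
    graph:  κ1 = A·(A−1)² / P₁²  with A heavy atoms and P₁ heavy-atom bonds.

    For an acyclic chain κ1 equals A exactly; each ring closure increases
    P₁ at fixed A and lowers the index, which is what makes it sensitive to
    the ring count of polycyclic phenols.
    """
    g = as_graph(mol)
    A = g.n_heavy_atoms
    if A < 2:
        raise DescriptorError("kappa-1 requires at least two heavy atoms")
    if not g.is_connected():
        raise DescriptorError("kappa-1 is undefined for disconnected graphs")
    P1 = g.n_heavy_bonds
    return A * (A - 1) ** 2 / P1**2


def logp(mol) -> float:
    """Octanol/water logP as the sum of Wildman–Crippen atom contributions.

    Deterministic for a fixed parameter table; the table version is recorded
    in :data:`LOGP_TABLE_VERSION`.  Elements outside the scheme's
    parameterised set fall back to its wildcard/metal contribution; a
    warning flags the molecule when that happens.
    """
    _CRIPPEN_ELEMENTS = {
        "H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I",
    }
    g = as_graph(mol)
    if g.rdkit_mol is None:
        raise DescriptorError(
            "logP needs an RDKit-backed structure (build the graph from "
            "SMILES or an RDKit Mol)"
        )
    from rdkit import Chem

    molh = Chem.AddHs(g.rdkit_mol)
    odd = sorted(
        {a.GetSymbol() for a in molh.GetAtoms()} - _CRIPPEN_ELEMENTS
    )
    if odd:
        warnings.warn(
            f"elements {odd} have no specific logP atom type; wildcard "
            "contributions used",
            stacklevel=2,
        )
    contribs = rdMolDescriptors._CalcCrippenContribs(molh)
    return float(sum(c for c, _mr in contribs))


def _golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral);
    no RNG so SASA values are bit-reproducible."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def sasa(
    mol,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: Optional[Sequence[float]] = None,
) -> float:
    """Solvent-accessible surface area (Å²) by the Shrake–Rupley method.

    Each atom's van der Waals sphere is expanded by the probe radius and
    covered with a deterministic lattice of ``n_sphere_points`` test points;
    the accessible area is the fraction of points not buried inside any
    neighbouring expanded sphere, times the full sphere area, summed over
    atoms.  Uses explicit hydrogens when the supplied geometry contains
    them, heavy atoms only otherwise.
    """
    g = as_graph(mol)
    if g.coords is None:
        raise DescriptorError(
            "SASA needs 3D coordinates: supply a conformer (e.g. "
            "MolecularGraph.from_smiles(..., embed3d=True)) or an SDF record"
        )
    r = np.asarray(radii, dtype=float) if radii is not None else (
        g.radii if g.radii is not None else g.default_radii()
    )
    if r.shape != (len(g.atoms),):
        raise DescriptorError("need one radius per atom")
    expanded = r + probe_radius
    points = _golden_spiral_points(n_sphere_points)
    coords = g.coords
    n_atoms = len(g.atoms)
    total = 0.0
    for i in range(n_atoms):
        test = coords[i] + expanded[i] * points  # (n_points, 3)
        accessible = np.ones(len(test), dtype=bool)
        for j in range(n_atoms):
            if j == i:
                continue
            # neighbour can only bury points if the expanded spheres overlap
            d_centres = np.linalg.norm(coords[j] - coords[i])
            if d_centres >= expanded[i] + expanded[j]:
                continue
            d2 = np.sum((test - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        frac = accessible.mean()
        total += frac * 4.0 * math.pi * expanded[i] ** 2
    return float(total)


# --------------------------------------------------------------------------
# descriptor-table assembly


@dataclass
class Compound:
    """One molecule: identity, optional structure, optional precomputed
    descriptor values and enthalpy pair."""

    id: str
    smiles: Optional[str] = None
    values: dict[str, float] = field(default_factory=dict)
    enthalpies: Optional[EnthalpyPair] = None


def build_descriptor_table(
    compounds: Iterable[Compound],
    homo_provider: Optional[Mapping[str, float]] = None,
    enthalpy_provider: Optional[Mapping[str, EnthalpyPair]] = None,
    embed_seed: int = 2013,
) -> pd.DataFrame:
    """Assemble the descriptor matrix for a compound collection.

    SI_k1, SA and logP are computed from structure when not supplied; BDE
    comes from an :class:`EnthalpyPair` (on the compound or via
    ``enthalpy_provider``); HOMO is passed through from the compound values
    or ``homo_provider``.  Every cell records provenance (``supplied`` /
    ``computed`` / missing), and a compound lacking both structure and
    values yields an error row rather than aborting the table.
    """
    rows = []
    for c in compounds:
        row: dict[str, object] = {"id": c.id, "error": None}
        graph = None
        if c.smiles is not None:
            try:
                graph = MolecularGraph.from_smiles(
                    c.smiles, embed3d=True, seed=embed_seed
                )
            except StructureError as exc:
                row["error"] = str(exc)
        elif not c.values:
            row["error"] = "no structure and no precomputed values"

        pair = c.enthalpies
        if pair is None and enthalpy_provider is not None:
            pair = enthalpy_provider.get(c.id)
        homo = c.values.get("HOMO")
        if homo is None and homo_provider is not None:
            homo = homo_provider.get(c.id)

        for name in DESCRIPTOR_NAMES:
            value, source = None, "missing"
            if name in c.values:
                value, source = c.values[name], "supplied"
            elif name == "BDE" and pair is not None:
                value, source = bond_dissociation_enthalpy(pair), "computed"
            elif name == "HOMO" and homo is not None:
                value, source = homo, "supplied"
            elif graph is not None and name in ("SI_k1", "SA", "logP"):
                func = {"SI_k1": kier_kappa1, "SA": sasa, "logP": logp}[name]
                try:
                    value, source = func(graph), "computed"
                except DescriptorError as exc:
                    row["error"] = str(exc)
            row[name] = value
            row[f"{name}_source"] = source
        rows.append(row)
    table = pd.DataFrame(rows).set_index("id")
    table.attrs["logP_table_version"] = LOGP_TABLE_VERSION
    return table
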