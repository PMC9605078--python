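"""All-atom molecular graphs for peptides and reference compounds.

A peptide graph is assembled by condensing bundled residue templates
(side-chain SMILES branches on a standard backbone) into a single linear
SMILES string with a free amine N-terminus and free acid C-terminus;
proline contributes its pyrrolidine ring closed through the backbone
nitrogen, and the arginine guanidine group is drawn neutral (one =NH).
RDKit parses the SMILES; the resulting molecule is converted into the
package's own :class:`MolecularGraph`, on which all drug-likeness
descriptors are computed.  Atom ordering follows the SMILES writing order
and is deterministic for a given sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources as _ilres

from rdkit import Chem

from .peptide import Peptide

AROMATIC_BOND = 1.5


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    formal_charge: int
    n_hydrogens: int
    aromatic: bool
    in_ring: bool
    hybridization: str  # "sp", "sp2", "sp3", ...


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float  # 1.0, 2.0, 3.0 or AROMATIC_BOND
    in_ring: bool = False


@dataclass(frozen=True)
class MolecularGraph:
    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    provenance: str
    smiles: str

    def neighbors(self, idx: int) -> list[tuple[Atom, Bond]]:
        out = []
        for bond in self.bonds:
            if bond.i == idx:
                out.append((self.atoms[bond.j], bond))
            elif bond.j == idx:
                out.append((self.atoms[bond.i], bond))
        return out

    def heavy_degree(self, idx: int) -> int:
        return len(self.neighbors(idx))

    def formula_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        n_h = 0
        for atom in self.atoms:
            counts[atom.element] = counts.get(atom.element, 0) + 1
            n_h += atom.n_hydrogens
        if n_h:
            counts["H"] = counts.get("H", 0) + n_h
        return counts

    def average_mass(self) -> float:
        weights = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}
        return sum(weights[el] * n for el, n in self.formula_counts().items())


@lru_cache(maxsize=1)
def _templates() -> dict:
    return json.loads(
        _ilres.files("pepsilico.resources").joinpath("chem_templates.json").read_text()
    )


def peptide_smiles(p: Peptide) -> str:
    """Linear SMILES with free termini; proline rings use fresh closure digits."""
    side = _templates()["side_chains"]
    parts = []
    ring = 1
    for aa in p:
        if aa == "P":
            parts.append(f"N{ring}CCCC{ring}C(=O)")
            ring += 1
        elif aa == "G":
            parts.append("NCC(=O)")
        else:
            parts.append(f"NC({side[aa]})C(=O)")
    return "".join(parts) + "O"


_HYBRID = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}

_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: AROMATIC_BOND,
}


def graph_from_smiles(smiles: str, provenance: str) -> MolecularGraph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {provenance!r}: {smiles}")
    atoms = tuple(
        Atom(
            index=a.GetIdx(),
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            n_hydrogens=a.GetTotalNumHs(),
            aromatic=a.GetIsAromatic(),
            in_ring=a.IsInRing(),
            hybridization=_HYBRID.get(a.GetHybridization(), "other"),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        Bond(
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            _ORDER[b.GetBondType()],
            b.IsInRing(),
        )
        for b in mol.GetBonds()
    )
    return MolecularGraph(atoms=atoms, bonds=bonds, provenance=provenance, smiles=smiles)


def build_peptide_graph(p: Peptide) -> MolecularGraph:
    """All-atom graph of the peptide with free termini (neutral form)."""
    return graph_from_smiles(peptide_smiles(p), provenance=str(p))


def load_reference(name: str) -> MolecularGraph:
    """Load a bundled named reference compound (e.g. ``"captopril"``)."""
    refs = _templates()["references"]
    if name not in refs:
        raise ValueError(f"unknown reference compound {name!r}; bundled: {sorted(refs)}")
    return graph_from_smiles(refs[name]["smiles"], provenance=name)
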