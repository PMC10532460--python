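"""Molecular templates for the 20 standard amino acids.

Templates are built once, at first use, by parsing neutral-form SMILES with
RDKit, adding explicit hydrogens and kekulizing aromatic rings so every bond
has an integer order.  Atom-map numbers tag the backbone anchors needed for
peptide condensation: 1 = backbone amine N, 2 = Calpha, 3 = carbonyl C,
4 = carboxyl hydroxyl O.

Conventions: everything neutral (NH2 / COOH termini, neutral Asp/Glu/Lys/Arg
side chains, His as the Neps2-H tautomer, Cys free thiol).  No stereochemistry
is kept anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem

# Backbone written identically everywhere; proline's ring forces its own form.
_SIDE = "[NH2:1][CH:2]({side})[C:3](=O)[OH:4]"

AMINO_ACID_SMILES: dict[str, str] = {
    "G": "[NH2:1][CH2:2][C:3](=O)[OH:4]",
    "A": _SIDE.format(side="C"),
    "V": _SIDE.format(side="C(C)C"),
    "L": _SIDE.format(side="CC(C)C"),
    "I": _SIDE.format(side="C(C)CC"),
    "P": "[OH:4][C:3](=O)[CH:2]1CCC[NH:1]1",
    "F": _SIDE.format(side="Cc1ccccc1"),
    "W": _SIDE.format(side="Cc1c[nH]c2ccccc12"),
    "M": _SIDE.format(side="CCSC"),
    "C": _SIDE.format(side="CS"),
    "S": _SIDE.format(side="CO"),
    "T": _SIDE.format(side="C(C)O"),
    "Y": _SIDE.format(side="Cc1ccc(O)cc1"),
    "N": _SIDE.format(side="CC(N)=O"),
    "Q": _SIDE.format(side="CCC(N)=O"),
    "D": _SIDE.format(side="CC(O)=O"),
    "E": _SIDE.format(side="CCC(O)=O"),
    "K": _SIDE.format(side="CCCCN"),
    "R": _SIDE.format(side="CCCNC(=N)N"),
    # tele (Neps2-H) tautomer: H on the ring N adjacent to Ceps1 and Cdel2
    "H": _SIDE.format(side="Cc1nc[nH]c1"),
}


@dataclass(frozen=True)
class ResidueTemplate:
    """One amino acid as an explicit-hydrogen molecular graph.

    ``atoms`` is a list of (element, formal_charge); ``bonds`` of
    (i, j, order).  Anchor indices locate the atoms involved in peptide-bond
    condensation: the carboxyl hydroxyl O (plus its H) leaves from the
    N-terminal partner, one amine H leaves from the C-terminal partner.
    """

    code: str
    atoms: tuple[tuple[str, int], ...]
    bonds: tuple[tuple[int, int, int], ...]
    backbone_n: int
    carbonyl_c: int
    hydroxyl_o: int
    hydroxyl_h: int
    amine_h: tuple[int, ...]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def _build_template(code: str) -> ResidueTemplate:
    mol = Chem.MolFromSmiles(AMINO_ACID_SMILES[code])
    if mol is None:  # pragma: no cover - template table is fixed
        raise RuntimeError(f"bad template SMILES for {code}")
    mol = Chem.AddHs(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)

    anchors: dict[int, int] = {}
    atoms = []
    for atom in mol.GetAtoms():
        if atom.GetAtomMapNum():
            anchors[atom.GetAtomMapNum()] = atom.GetIdx()
        atoms.append((atom.GetSymbol(), atom.GetFormalCharge()))
    bonds = []
    for bond in mol.GetBonds():
        order = int(bond.GetBondTypeAsDouble())
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))

    n_idx, c_idx, o_idx = anchors[1], anchors[3], anchors[4]
    o_atom = mol.GetAtomWithIdx(o_idx)
    hydroxyl_h = [a.GetIdx() for a in o_atom.GetNeighbors()
                  if a.GetSymbol() == "H"]
    n_atom = mol.GetAtomWithIdx(n_idx)
    amine_h = tuple(sorted(a.GetIdx() for a in n_atom.GetNeighbors()
                           if a.GetSymbol() == "H"))
    assert len(hydroxyl_h) == 1 and len(amine_h) >= 1
    return ResidueTemplate(
        code=code,
        atoms=tuple(atoms),
        bonds=tuple(bonds),
        backbone_n=n_idx,
        carbonyl_c=c_idx,
        hydroxyl_o=o_idx,
        hydroxyl_h=hydroxyl_h[0],
        amine_h=amine_h,
    )


@lru_cache(maxsize=None)
def get_template(code: str) -> ResidueTemplate:
    if code not in AMINO_ACID_SMILES:
        raise KeyError(f"no residue template for {code!r}")
    return _build_template(code)


def residue_formula(code: str) -> dict[str, int]:
    """Element counts of the free amino acid (explicit H)."""
    counts: dict[str, int] = {}
    for el, _ in get_template(code).atoms:
        counts[el] = counts.get(el, 0) + 1
    return counts
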