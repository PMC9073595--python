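"""Molecular graphs and the topological information-content descriptor.

The mean information content of order k is the Shannon entropy (in bits) of
the partition of atoms into equivalence classes: at order 0 the classes are
chemical elements; each further order refines a class by the multiset of
neighbour classes (a Morgan-style sphere of radius k).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem


@dataclass(frozen=True)
class MolecularGraph:
    """Element-labelled graph with explicit bonds.

    atoms: (symbol, formal charge, attached-H count) per atom; when hydrogens
    are explicit the attached-H count of a hydrogen is 0 and heavy atoms list
    only *implicit* hydrogens (normally 0 in that representation).
    bonds: ((i, j), order) with i < j.
    """

    atoms: tuple[tuple[str, int, int], ...]
    bonds: tuple[tuple[tuple[int, int], float], ...] = field(default_factory=tuple)

    def __post_init__(self):
        n = len(self.atoms)
        for (i, j), _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, add_hs: bool = True) -> "MolecularGraph":
        if add_hs:
            mol = Chem.AddHs(mol)
        atoms = tuple(
            (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in mol.GetAtoms()
        )
        bonds = tuple(
            ((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
              max(b.GetBeginAtomIdx(), b.GetEndAtomIdx())),
             b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        )
        return cls(atoms, bonds)

    @classmethod
    def from_smiles(cls, smiles: str, add_hs: bool = True) -> "MolecularGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES {smiles!r}")
        return cls.from_rdkit(mol, add_hs=add_hs)

    def __len__(self):
        return len(self.atoms)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(sym for sym, _, _ in self.atoms)

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for (i, j), _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def hydrogen_attachment(self) -> dict[int, int]:
        """Explicit H atom index -> index of the heavy atom it is bonded to."""
        out: dict[int, int] = {}
        adj = self.neighbors()
        for idx, (sym, _, _) in enumerate(self.atoms):
            if sym == "H" and adj[idx]:
                out[idx] = adj[idx][0]
        return out


def atom_classes(graph: MolecularGraph, order: int) -> list[int]:
    """Equivalence-class label per atom after `order` neighbourhood refinements."""
    if len(graph) == 0:
        raise ValueError("empty graph")
    if order < 0:
        raise ValueError("order must be >= 0")
    labels = {sym: i for i, sym in enumerate(sorted(set(graph.elements)))}
    classes = [labels[sym] for sym in graph.elements]
    adj = graph.neighbors()
    for _ in range(order):
        keys = [
            (classes[i], tuple(sorted(classes[j] for j in adj[i])))
            for i in range(len(graph))
        ]
        relabel = {k: i for i, k in enumerate(sorted(set(keys)))}
        new = [relabel[k] for k in keys]
        if new == classes:
            break
        classes = new
    return classes


def mean_information_content(graph: MolecularGraph, order: int = 0) -> float:
    """Entropy (bits) of the order-k atom partition: -sum (n_i/n) log2(n_i/n)."""
    classes = atom_classes(graph, order)
    n = len(classes)
    counts = Counter(classes)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())
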