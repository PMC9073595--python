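"""Quantum-chemical descriptors over a ZDO electronic-structure backend.

Each operation consumes an :class:`ElectronicStructure` (from the bundled
SCF backend, or a mock) and reduces its matrices to a single number:

* total one-center electron-electron repulsion per atom,
* the minimum Fukui one-electron reactivity index over atoms of an element,
* the minimum resonance energy over bonds between an element pair,
* the minimum electron-nuclear attraction over atoms of an element.
"""

from __future__ import annotations

import numpy as np

from .types import ChargeSet, ElectronicStructure


def net_atomic_charges(es: ElectronicStructure, core_charges=None) -> ChargeSet:
    """Net atomic charges q_A = Z_A - P_AA from the backend density."""
    from .scf import CORE_CHARGE

    populations = np.bincount(np.asarray(es.basis_atoms),
                              weights=np.diag(es.density), minlength=es.n_atoms)
    if core_charges is None:
        core_charges = np.array([CORE_CHARGE[el] for el in es.elements], dtype=float)
    return ChargeSet(np.asarray(core_charges, dtype=float) - populations,
                     scheme="backend")


def ee_repulsion_per_atom(es: ElectronicStructure, n_atoms: int | None = None) -> float:
    """(sum over atoms of E_ee(A)) / number of atoms."""
    n = es.n_atoms if n_atoms is None else n_atoms
    if n == 0:
        raise ValueError("n_atoms must be positive")
    return float(np.sum(es.e_ee)) / n


def fukui_reaction_indices(es: ElectronicStructure, element: str) -> dict[int, float]:
    """Per-atom Fukui one-electron reactivity index for atoms of `element`.

    R_A = sum_{i in A} sum_{j in A} c_iHOMO * c_jLUMO / (eps_LUMO - eps_HOMO),
    with signed orbital-coefficient products.
    """
    gap = es.eps_lumo - es.eps_homo
    if gap == 0:
        raise ValueError("degenerate HOMO/LUMO gap")
    ch, cl = es.c_homo, es.c_lumo
    out: dict[int, float] = {}
    for atom, sym in enumerate(es.elements):
        if sym != element:
            continue
        idx = es.atom_basis_indices(atom)
        out[atom] = float(ch[idx].sum() * cl[idx].sum() / gap)
    if not out:
        raise ValueError(f"element {element} absent")
    return out


def fukui_min_reaction_index(es: ElectronicStructure, element: str) -> float:
    """Minimum Fukui one-electron reactivity index over atoms of `element`."""
    return min(fukui_reaction_indices(es, element).values())


def bond_resonance_energies(
    es: ElectronicStructure, element_pair: tuple[str, str]
) -> dict[tuple[int, int], float]:
    """E(A-B) = sum_{mu in A, nu in B} P_mu_nu * beta_mu_nu per matching bond."""
    a, b = element_pair
    out: dict[tuple[int, int], float] = {}
    for i, j in es.bonds:
        ei, ej = es.elements[i], es.elements[j]
        if {ei, ej} != {a, b} and not (a == b == ei == ej):
            continue
        bi, bj = es.atom_basis_indices(i), es.atom_basis_indices(j)
        out[(i, j)] = float(
            np.sum(es.density[np.ix_(bi, bj)] * es.beta[np.ix_(bi, bj)]))
    if not out:
        raise ValueError(f"no {a}-{b} bond present")
    return out


def min_resonance_energy_bond(
    es: ElectronicStructure, element_pair: tuple[str, str]
) -> float:
    """Minimum resonance energy over bonds between the named element pair."""
    return min(bond_resonance_energies(es, element_pair).values())


def min_en_attraction_atom(es: ElectronicStructure, element: str) -> float:
    """Minimum of the backend's per-atom electron-nuclear attraction sums."""
    vals = [float(es.e_ne[atom]) for atom, sym in enumerate(es.elements)
            if sym == element]
    if not vals:
        raise ValueError(f"element {element} absent")
    return min(vals)
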