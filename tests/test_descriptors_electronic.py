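"""Quantum-chemical descriptor reductions over mock electronic structures,
checked against brute-force summation oracles."""

import numpy as np
import pytest

from dienoneqsar.descriptors import (
    ElectronicStructure,
    bond_resonance_energies,
    ee_repulsion_per_atom,
    fukui_min_reaction_index,
    fukui_reaction_indices,
    min_en_attraction_atom,
    min_resonance_energy_bond,
)
from dienoneqsar.synth import gen_mock_electronic_structure


def simple_es(**overrides):
    """Tiny hand-buildable electronic structure (3 atoms, 1 basis fn each)."""
    base = dict(
        density=np.eye(3),
        mo_coefficients=np.eye(3),
        orbital_energies=np.array([-10.0, -8.0, 2.0]),
        homo_index=1,
        lumo_index=2,
        beta=np.zeros((3, 3)),
        e_ee=np.array([10.0, 20.0, 30.0]),
        e_ne=np.array([-150.0, -148.2, -20.0]),
        basis_atoms=np.array([0, 1, 2]),
        elements=("N", "N", "C"),
        bonds=((0, 1), (1, 2)),
    )
    base.update(overrides)
    return ElectronicStructure(**base)


def test_ee_repulsion_mean():
    assert ee_repulsion_per_atom(simple_es()) == pytest.approx(20.0)
    assert ee_repulsion_per_atom(simple_es(e_ee=np.zeros(3))) == 0.0
    with pytest.raises(ValueError):
        ee_repulsion_per_atom(simple_es(), n_atoms=0)


def test_fukui_single_basis_function():
    es = simple_es(
        mo_coefficients=np.array([[0.0, 0.6, 0.5],
                                  [1.0, 0.0, 0.0],
                                  [0.0, 0.8, -0.866]]),
        orbital_energies=np.array([-12.0, -8.0, -3.0]),
        elements=("O", "C", "C"),
    )
    # single O with one basis fn: c_H * c_L / gap = 0.6 * 0.5 / 5
    assert fukui_min_reaction_index(es, "O") == pytest.approx(0.06)


def test_fukui_minimum_and_errors():
    es = simple_es(elements=("O", "O", "C"),
                   mo_coefficients=np.array([[0.0, 0.6, 0.5],
                                             [0.0, 0.2, 0.5],
                                             [1.0, 0.0, 0.0]]),
                   orbital_energies=np.array([-12.0, -8.0, -3.0]))
    idx = fukui_reaction_indices(es, "O")
    assert fukui_min_reaction_index(es, "O") == pytest.approx(min(idx.values()))
    assert fukui_min_reaction_index(es, "O") == pytest.approx(0.02)
    # zero LUMO coefficients on the element -> zero index
    es0 = simple_es(elements=("O", "C", "C"),
                    mo_coefficients=np.array([[0.0, 0.6, 0.0],
                                              [1.0, 0.0, 0.7],
                                              [0.0, 0.8, 0.7]]),
                    orbital_energies=np.array([-12.0, -8.0, -3.0]))
    assert fukui_min_reaction_index(es0, "O") == 0.0
    with pytest.raises(ValueError, match="absent"):
        fukui_min_reaction_index(es, "F")
    bad = simple_es()
    bad.orbital_energies = np.array([-10.0, -8.0, -8.0])
    with pytest.raises(ValueError):
        fukui_min_reaction_index(bad, "N")


def test_resonance_energy_hand_case():
    es = simple_es(
        elements=("H", "C", "C"),
        bonds=((0, 1), (0, 2)),
        density=np.array([[1.0, 0.5, 0.4],
                          [0.5, 1.0, 0.0],
                          [0.4, 0.0, 1.0]]),
        beta=np.array([[0.0, -24.0, -27.5],
                       [-24.0, 0.0, 0.0],
                       [-27.5, 0.0, 0.0]]),
    )
    # bond sums: 0.5 * -24 = -12.0 and 0.4 * -27.5 = -11.0
    energies = bond_resonance_energies(es, ("H", "C"))
    assert sorted(energies.values()) == pytest.approx([-12.0, -11.0])
    assert min_resonance_energy_bond(es, ("H", "C")) == pytest.approx(-12.0)
    # single-bond molecule: the minimum is the bond's own sum
    es_single = simple_es(elements=("H", "C", "C"), bonds=((0, 1),),
                          density=es.density, beta=es.beta)
    assert min_resonance_energy_bond(es_single, ("H", "C")) == pytest.approx(-12.0)
    assert min_resonance_energy_bond(simple_es(elements=("H", "C", "C"),
                                               bonds=((0, 1),)),
                                     ("H", "C")) == 0.0  # beta identically zero
    with pytest.raises(ValueError, match="bond"):
        min_resonance_energy_bond(es, ("N", "N"))


def test_en_attraction_minimum():
    es = simple_es()
    assert min_en_attraction_atom(es, "N") == pytest.approx(-150.0)
    assert min_en_attraction_atom(es, "C") == pytest.approx(-20.0)  # single atom
    assert min_en_attraction_atom(simple_es(e_ne=np.zeros(3)), "N") == 0.0
    with pytest.raises(ValueError, match="absent"):
        min_en_attraction_atom(es, "S")


@pytest.mark.parametrize("seed", [1, 7, 42])
def test_minimum_descriptors_match_brute_force(seed):
    """Minimum-type descriptors equal explicit enumeration over all basis
    pairs of a seeded mock electronic structure."""
    es = gen_mock_electronic_structure(n_atoms=8, basis_per_atom=3, seed=seed)
    gap = es.eps_lumo - es.eps_homo

    def brute_fukui(element):
        vals = []
        for a, sym in enumerate(es.elements):
            if sym != element:
                continue
            idx = [k for k in range(len(es.basis_atoms)) if es.basis_atoms[k] == a]
            s = sum(es.c_homo[i] * es.c_lumo[j] for i in idx for j in idx)
            vals.append(s / gap)
        return min(vals)

    def brute_resonance(pair):
        vals = []
        for i, j in es.bonds:
            if {es.elements[i], es.elements[j]} != set(pair):
                continue
            bi = [k for k in range(len(es.basis_atoms)) if es.basis_atoms[k] == i]
            bj = [k for k in range(len(es.basis_atoms)) if es.basis_atoms[k] == j]
            vals.append(sum(es.density[m, n] * es.beta[m, n]
                            for m in bi for n in bj))
        return min(vals)

    assert fukui_min_reaction_index(es, "C") == pytest.approx(
        brute_fukui("C"), abs=1e-10)
    assert min_resonance_energy_bond(es, ("C", "H")) == pytest.approx(
        brute_resonance(("C", "H")), abs=1e-10)
    ns = [es.e_ne[a] for a, s in enumerate(es.elements) if s == "N"]
    assert min_en_attraction_atom(es, "N") == pytest.approx(min(ns), abs=1e-12)
    assert ee_repulsion_per_atom(es) == pytest.approx(
        sum(es.e_ee) / es.n_atoms, abs=1e-12)


def test_minimum_descriptors_bounded_by_candidates(mock_es):
    """Every minimum-type value is <= each per-atom/per-bond candidate."""
    es = mock_es
    idx = fukui_reaction_indices(es, "C")
    assert all(fukui_min_reaction_index(es, "C") <= v + 1e-15 for v in idx.values())
    energies = bond_resonance_energies(es, ("C", "H"))
    assert all(min_resonance_energy_bond(es, ("C", "H")) <= v + 1e-15
               for v in energies.values())
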