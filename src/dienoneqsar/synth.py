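"""Synthetic inputs for exercising every pipeline stage without external data:
planted-signal descriptor matrices, censored log-normal activity tables, mock
electronic structures and toy conformer geometries.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors.types import Conformer3D, ElectronicStructure
from .regression import ResponseVector

DEFAULT_SEED = 20191021


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a planted-signal linear descriptor dataset."""

    n_compounds: int = 24
    n_descriptors: int = 23
    true_terms: tuple = ((0, 2.0), (1, -1.5), (2, 1.0))  # (column index, coefficient)
    intercept: float = 0.5
    noise_sd: float = 0.75
    censor_rate: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        for idx, _ in self.true_terms:
            if not 0 <= idx < self.n_descriptors:
                raise ValueError(f"true-term index {idx} out of range")
        if self.n_compounds <= len(self.true_terms) + 2:
            raise ValueError("n_compounds too small for the planted model")


def gen_linear_dataset(spec: SyntheticSpec):
    """(X, y, truth): standard-normal descriptors with a k-term linear signal.

    truth records the generating intercept, coefficients and noise so that
    y can be reconstructed exactly when noise_sd = 0.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n_compounds, spec.n_descriptors))
    cols = [f"d{i:02d}" for i in range(spec.n_descriptors)]
    Xdf = pd.DataFrame(X, columns=cols)
    y = np.full(spec.n_compounds, spec.intercept)
    for idx, coef in spec.true_terms:
        y = y + coef * X[:, idx]
    noise = rng.normal(0.0, spec.noise_sd, spec.n_compounds) if spec.noise_sd > 0 else 0.0
    y = y + noise
    truth = {
        "intercept": spec.intercept,
        "terms": {cols[idx]: coef for idx, coef in spec.true_terms},
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    ids = tuple(range(1, spec.n_compounds + 1))
    return Xdf, ResponseVector(ids, y, "log_inverse_ic50"), truth


def gen_activity_table(
    classes,
    class_medians: dict,
    spread: float = 0.15,
    censor_at: float = 50.0,
    seed: int = DEFAULT_SEED,
    assay: str = "synthetic",
) -> pd.DataFrame:
    """Censored log-normal IC50 table stratified by substituent class.

    `classes` assigns one substituent class per synthetic compound; each IC50
    is drawn log-normally about its class median with log-scale sigma
    `spread`.  Draws above `censor_at` become bounds with censor =
    'greater_than', mirroring how weak compounds are reported as ">50.00".
    """
    for cls in classes:
        if cls not in class_medians:
            raise ValueError(f"no median for class {cls!r}")
        if class_medians[cls] <= 0:
            raise ValueError("class medians must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for i, cls in enumerate(classes, start=1):
        ic50 = class_medians[cls] * np.exp(rng.normal(0.0, spread))
        censored = np.isfinite(censor_at) and ic50 > censor_at
        rows.append({
            "compound_id": str(i),
            "assay": assay,
            "substituent_class": cls,
            "ic50_um": censor_at if censored else ic50,
            "sd_um": 0.1 * (censor_at if censored else ic50),
            "censor": "greater_than" if censored else "exact",
            "is_reference": 0,
        })
    return pd.DataFrame(rows)


def gen_mock_electronic_structure(
    n_atoms: int,
    basis_per_atom: int = 1,
    seed: int = DEFAULT_SEED,
    elements=None,
    bonds=None,
) -> ElectronicStructure:
    """Random (seeded) electronic structure honouring the backend contract:
    symmetric density, orthonormal MOs, HOMO below LUMO, per-atom energy
    tables.  Elements default to a C/H/O/N cycle and bonds to a chain."""
    if n_atoms < 1 or basis_per_atom < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    nb = n_atoms * basis_per_atom
    A = rng.standard_normal((nb, nb))
    density = (A + A.T) / 2.0
    Q, _ = np.linalg.qr(rng.standard_normal((nb, nb)))
    energies = np.sort(rng.normal(-8.0, 4.0, nb))
    n_occ = max(1, nb // 2)
    if n_occ == nb:
        n_occ = nb - 1 if nb > 1 else 1
    if nb == 1:
        energies = np.array([-8.0, 2.0])
        Q = np.array([[1.0, 0.0]])
        homo, lumo = 0, 1
    else:
        energies[n_occ] = energies[n_occ - 1] + abs(rng.normal(4.0, 1.0)) + 0.5
        energies = np.sort(energies)
        homo, lumo = n_occ - 1, n_occ
    B = rng.standard_normal((nb, nb))
    beta = -np.abs(B + B.T) / 2.0
    basis_atoms = np.repeat(np.arange(n_atoms), basis_per_atom)
    beta[basis_atoms[:, None] == basis_atoms[None, :]] = 0.0
    if elements is None:
        cycle = ("C", "H", "O", "N")
        elements = tuple(cycle[i % len(cycle)] for i in range(n_atoms))
    if bonds is None:
        bonds = tuple((i, i + 1) for i in range(n_atoms - 1))
    return ElectronicStructure(
        density=density,
        mo_coefficients=Q,
        orbital_energies=energies,
        homo_index=homo,
        lumo_index=lumo,
        beta=beta,
        e_ee=np.abs(rng.normal(50.0, 15.0, n_atoms)),
        e_ne=-np.abs(rng.normal(150.0, 30.0, n_atoms)),
        basis_atoms=basis_atoms,
        elements=tuple(elements),
        bonds=tuple(bonds),
    )


def gen_toy_conformers(separation: float = 3.0) -> dict[str, Conformer3D]:
    """Named analytic geometries for surface-area and charge tests."""
    ch = 1.09  # methane C-H bond length, Angstrom
    t = ch / np.sqrt(3.0)
    methane_xyz = np.array([
        [0.0, 0.0, 0.0], [t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t]])
    cc = 1.39  # benzene C-C bond length
    ang = np.arange(6) * np.pi / 3.0
    ring = cc * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
    hring = (cc + 1.09) * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
    benzene_xyz = np.vstack([ring, hring])
    return {
        "isolated_sphere": Conformer3D(np.zeros((1, 3)), np.array([1.7]), ("C",)),
        "two_spheres": Conformer3D(
            np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]),
            np.array([1.5, 1.5]), ("C", "C"), validate=False),
        "coincident_spheres": Conformer3D(
            np.zeros((2, 3)), np.array([1.7, 1.7]), ("C", "C"), validate=False),
        "methane": Conformer3D(methane_xyz, np.array([1.7] + [1.2] * 4),
                               ("C", "H", "H", "H", "H")),
        "benzene": Conformer3D(benzene_xyz, np.array([1.7] * 6 + [1.2] * 6),
                               tuple(["C"] * 6 + ["H"] * 6)),
    }
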