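"""Shared containers for the descriptor engine."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Conformer3D:
    """Cartesian coordinates (Angstrom) plus per-atom van der Waals radii."""

    coordinates: np.ndarray  # (n, 3)
    radii: np.ndarray        # (n,)
    elements: tuple[str, ...] | None = None
    #: set False for deliberately degenerate toy geometries (coincident spheres)
    validate: bool = True

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")
        if self.radii.shape != (len(self.coordinates),):
            raise ValueError("radii must match the atom count")
        if (self.radii <= 0).any():
            raise ValueError("radii must be positive")
        if self.validate and len(self.coordinates) > 1:
            d = np.linalg.norm(
                self.coordinates[:, None] - self.coordinates[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if (d < 0.5).any():
                raise ValueError("atoms closer than 0.5 Angstrom")

    def __len__(self):
        return len(self.coordinates)


@dataclass
class ChargeSet:
    """Per-atom partial charges in elementary-charge units."""

    charges: np.ndarray
    scheme: str = "empirical_equalization"  # or "backend"

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)

    def __len__(self):
        return len(self.charges)


@dataclass
class ElectronicStructure:
    """Closed-shell ZDO electronic structure over a minimal valence basis.

    The contract consumed by the quantum-chemical descriptors: a symmetric
    density matrix, identified frontier orbitals, resonance integrals, and
    per-atom one-center electron-electron repulsion and electron-nuclear
    attraction tables.  Energies are in eV, distances in Angstrom.
    """

    density: np.ndarray             # (nb, nb) symmetric
    mo_coefficients: np.ndarray     # (nb, nmo), columns are MOs
    orbital_energies: np.ndarray    # (nmo,), ascending
    homo_index: int
    lumo_index: int
    beta: np.ndarray                # (nb, nb) resonance integrals
    e_ee: np.ndarray                # (n_atoms,) one-center e-e repulsion
    e_ne: np.ndarray                # (n_atoms,) e-n attraction (<= 0 typically)
    basis_atoms: np.ndarray         # (nb,) basis function -> atom index
    elements: tuple[str, ...]       # (n_atoms,)
    bonds: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    electronic_energy: float | None = None
    scf_energies: tuple[float, ...] = ()  # per-iteration electronic energies

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        if not np.allclose(self.density, self.density.T, atol=1e-8):
            raise ValueError("density matrix must be symmetric")
        if len(self.basis_atoms) != len(self.density):
            raise ValueError("basis->atom map must cover the basis")
        if self.eps_homo >= self.eps_lumo:
            raise ValueError("HOMO energy must lie below LUMO energy")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def eps_homo(self) -> float:
        return float(self.orbital_energies[self.homo_index])

    @property
    def eps_lumo(self) -> float:
        return float(self.orbital_energies[self.lumo_index])

    @property
    def c_homo(self) -> np.ndarray:
        return self.mo_coefficients[:, self.homo_index]

    @property
    def c_lumo(self) -> np.ndarray:
        return self.mo_coefficients[:, self.lumo_index]

    def atom_basis_indices(self, atom: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.basis_atoms) == atom)


@dataclass
class DescriptorVector:
    """Named descriptor values with units and provenance tags."""

    values: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values
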