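"""Reference semiempirical electronic-structure backend (CNDO/2-level ZDO SCF).

Supplies the quantities the quantum-chemical descriptors consume -- density
matrix, frontier orbitals, resonance integrals, one-center electron-electron
repulsion and electron-nuclear attraction tables -- for molecules built from
H, C, N, O, F, S and Cl.

Model summary (closed shell, valence electrons only):

* minimal valence basis of Slater orbitals, each expanded in three Gaussians
  (STO-3G expansion coefficients); overlaps S_mu_nu evaluated analytically
  over the Gaussian expansions;
* two-center Coulomb integrals gamma_AB between valence-s charge clouds;
* CNDO/2 Fock matrix with published electronegativity parameters
  -(I+A)/2 and bonding parameters beta0;
* resonance integrals beta_mu_nu = 0.5 * (beta0_A + beta0_B) * S_mu_nu.

Energies are in eV and coordinates in Angstrom at the interface; Bohr and
Hartree are used internally for the integrals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .graph import MolecularGraph
from .types import Conformer3D, ElectronicStructure

BOHR_PER_ANGSTROM = 1.8897259886
HARTREE_EV = 27.211386
EV_ANGSTROM = 14.399645  # e^2 / (4 pi eps0), in eV * Angstrom

# STO-3G expansions for zeta = 1 (exponents scale as zeta^2).
_STO3G_1S = (np.array([2.227660584, 0.405771156, 0.109818]),
             np.array([0.154328967, 0.535328142, 0.444634542]))
_STO3G_2S = (np.array([0.994203, 0.231031, 0.0751386]),
             np.array([-0.09996723, 0.39951283, 0.70011547]))
_STO3G_2P = (np.array([0.994203, 0.231031, 0.0751386]),
             np.array([0.15591627, 0.60768372, 0.39195739]))
# Element-specific 3sp primitives (already scaled).
_STO3G_3SP_EXP = {
    "S": np.array([2.029194274, 0.5661400518, 0.2215833792]),
    "Cl": np.array([2.129386495, 0.5940934274, 0.2325241410]),
}
_STO3G_3S_C = np.array([-0.2196203690, 0.2255954336, 0.9003984260])
_STO3G_3P_C = np.array([0.01058760429, 0.5951670053, 0.4620010120])

#: Slater exponents for the valence shell (CNDO convention, H = 1.2).
SLATER_ZETA = {"H": 1.2, "C": 1.625, "N": 1.95, "O": 2.275, "F": 2.6}

#: CNDO/2 electronegativity parameters -(I + A)/2 per (element, subshell), eV.
ELECTRONEGATIVITY = {
    ("H", "s"): 7.176,
    ("C", "s"): 14.051, ("C", "p"): 5.572,
    ("N", "s"): 19.316, ("N", "p"): 7.275,
    ("O", "s"): 25.390, ("O", "p"): 9.111,
    ("F", "s"): 32.272, ("F", "p"): 11.080,
    ("S", "s"): 17.650, ("S", "p"): 6.989,
    ("Cl", "s"): 21.591, ("Cl", "p"): 8.708,
}

#: CNDO/2 bonding parameters -beta0, eV.
BETA0 = {"H": 9.0, "C": 21.0, "N": 25.0, "O": 31.0, "F": 39.0,
         "S": 18.150, "Cl": 22.330}

#: Valence (core) charges.
CORE_CHARGE = {"H": 1, "C": 4, "N": 5, "O": 6, "F": 7, "S": 6, "Cl": 7}

SUPPORTED_ELEMENTS = tuple(BETA0)


class SCFConvergenceError(RuntimeError):
    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"SCF not converged after {iterations} iterations "
            f"(last density residual {residual:.3e})")


def _valence_primitives(element: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(exponents, contraction coefficients) for the valence s and p shells."""
    if element == "H":
        a, c = _STO3G_1S
        return {"s": (a * SLATER_ZETA["H"] ** 2, c)}
    if element in ("C", "N", "O", "F"):
        z2 = SLATER_ZETA[element] ** 2
        return {"s": (_STO3G_2S[0] * z2, _STO3G_2S[1]),
                "p": (_STO3G_2P[0] * z2, _STO3G_2P[1])}
    if element in _STO3G_3SP_EXP:
        a = _STO3G_3SP_EXP[element]
        return {"s": (a, _STO3G_3S_C), "p": (a, _STO3G_3P_C)}
    raise ValueError(f"element {element} not supported by the ZDO backend")


def _normalized(alpha: np.ndarray, coeff: np.ndarray, l: int) -> np.ndarray:
    """Contraction coefficients absorbed into primitive norms, renormalized."""
    if l == 0:
        norms = (2.0 * alpha / np.pi) ** 0.75
    else:
        norms = (2.0 * alpha / np.pi) ** 0.75 * 2.0 * np.sqrt(alpha)
    d = coeff * norms
    # self-overlap of the contracted function
    p = alpha[:, None] + alpha[None, :]
    s = (np.pi / p) ** 1.5
    if l == 1:
        s = s / (2.0 * p)
    self_ov = float(np.einsum("i,j,ij->", d, d, s))
    return d / np.sqrt(self_ov)


@dataclass
class _Shell:
    atom: int
    l: int                 # 0 = s, 1 = p (px, py, pz)
    alpha: np.ndarray      # primitive exponents, Bohr^-2
    d: np.ndarray          # normalized contraction coefficients
    subshell: str          # "s" or "p"


def _build_shells(elements: tuple[str, ...]) -> list[_Shell]:
    shells: list[_Shell] = []
    for atom, el in enumerate(elements):
        for sub, (alpha, coeff) in _valence_primitives(el).items():
            l = 0 if sub == "s" else 1
            shells.append(_Shell(atom, l, alpha, _normalized(alpha, coeff, l), sub))
    return shells


def _shell_pair_overlap(sa: _Shell, sb: _Shell, ra: np.ndarray, rb: np.ndarray) -> np.ndarray:
    """Overlap block between two shells (1 or 3 functions each); coords in Bohr."""
    ab = ra - rb
    r2 = float(ab @ ab)
    a = sa.alpha[:, None]
    b = sb.alpha[None, :]
    p = a + b
    pref = (np.pi / p) ** 1.5 * np.exp(-a * b / p * r2)
    w = sa.d[:, None] * sb.d[None, :]
    # P - A = (b/p) * (B - A);  P - B = (a/p) * (A - B)
    if sa.l == 0 and sb.l == 0:
        return np.array([[np.sum(w * pref)]])
    if sa.l == 0 and sb.l == 1:
        coef = np.sum(w * pref * (a / p))  # times (A - B)_i
        return (coef * ab)[None, :]
    if sa.l == 1 and sb.l == 0:
        coef = np.sum(w * pref * (b / p))  # times (B - A)_i
        return (-coef * ab)[:, None]
    # p-p block: (P-A)_i (P-B)_j + delta_ij / (2p)
    c1 = np.sum(w * pref * (b / p) * (a / p))   # times (B-A)_i (A-B)_j
    c2 = np.sum(w * pref / (2.0 * p))
    block = np.outer(-ab, ab) * c1
    block[np.diag_indices(3)] += c2
    return block


def overlap_matrix(shells: list[_Shell], coords_bohr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full overlap matrix plus basis -> atom and basis -> subshell maps."""
    sizes = [1 if s.l == 0 else 3 for s in shells]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    nb = int(offsets[-1])
    S = np.zeros((nb, nb))
    basis_atoms = np.empty(nb, dtype=int)
    basis_sub = np.empty(nb, dtype=object)
    for i, sh in enumerate(shells):
        basis_atoms[offsets[i]:offsets[i] + sizes[i]] = sh.atom
        basis_sub[offsets[i]:offsets[i] + sizes[i]] = sh.subshell
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells[i:], start=i):
            block = _shell_pair_overlap(sa, sb, coords_bohr[sa.atom], coords_bohr[sb.atom])
            S[offsets[i]:offsets[i] + sizes[i], offsets[j]:offsets[j] + sizes[j]] = block
            if j != i:
                S[offsets[j]:offsets[j] + sizes[j], offsets[i]:offsets[i] + sizes[i]] = block.T
    return S, basis_atoms, basis_sub


def _gamma_pair(sa: _Shell, sb: _Shell, r_bohr: float) -> float:
    """Coulomb repulsion (Hartree) between the squared valence-s clouds."""
    pa = sa.alpha[:, None] + sa.alpha[None, :]
    da = np.outer(sa.d, sa.d)
    pb = sb.alpha[:, None] + sb.alpha[None, :]
    db = np.outer(sb.d, sb.d)
    p = pa.ravel()
    q = pb.ravel()
    wa = da.ravel()
    wb = db.ravel()
    P, Q = np.meshgrid(p, q, indexing="ij")
    t = P * Q / (P + Q) * r_bohr ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        f0 = np.where(t > 1e-12, 0.5 * np.sqrt(np.pi / np.maximum(t, 1e-300)) * erf(np.sqrt(t)), 1.0)
    integ = 2.0 * np.pi ** 2.5 / (P * Q * np.sqrt(P + Q)) * f0
    return float(wa @ integ @ wb)


def gamma_matrix(shells: list[_Shell], coords_bohr: np.ndarray, n_atoms: int) -> np.ndarray:
    """Atom-pair Coulomb matrix gamma_AB in eV (valence-s clouds)."""
    s_shell = {}
    for sh in shells:
        if sh.l == 0:
            s_shell[sh.atom] = sh
    G = np.zeros((n_atoms, n_atoms))
    for a in range(n_atoms):
        for b in range(a, n_atoms):
            r = float(np.linalg.norm(coords_bohr[a] - coords_bohr[b]))
            G[a, b] = G[b, a] = _gamma_pair(s_shell[a], s_shell[b], r) * HARTREE_EV
    return G


def density_from_fock(fock: np.ndarray, n_occ: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-shell density from one Fock diagonalization (P = 2 C_occ C_occ^T)."""
    eps, C = np.linalg.eigh(fock)
    P = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
    return P, eps, C


def zdo_scf(
    graph: MolecularGraph,
    conf: Conformer3D,
    max_iter: int = 200,
    tol: float = 1e-6,
    charge: int = 0,
    mixing: float = 0.5,
) -> ElectronicStructure:
    """Converge a closed-shell CNDO/2 density for the molecule.

    `graph` must carry explicit hydrogens and match `conf` atom for atom.
    Raises :class:`SCFConvergenceError` (with the last density residual) if
    the density does not settle within `max_iter` iterations.
    """
    elements = graph.elements
    if len(elements) != len(conf):
        raise ValueError("graph and conformer must refer to the same atom list")
    for el in elements:
        if el not in SUPPORTED_ELEMENTS:
            raise ValueError(f"element {el} not supported by the ZDO backend")
    n_atoms = len(elements)
    coords = conf.coordinates * BOHR_PER_ANGSTROM
    z = np.array([CORE_CHARGE[el] for el in elements], dtype=float)
    n_el = int(z.sum()) - charge
    if n_el % 2:
        raise ValueError("odd electron count: closed-shell SCF only")
    n_occ = n_el // 2

    shells = _build_shells(elements)
    S, basis_atoms, basis_sub = overlap_matrix(shells, coords)
    nb = len(S)
    G = gamma_matrix(shells, coords, n_atoms)
    g_basis = G[np.ix_(basis_atoms, basis_atoms)]

    en = np.array([ELECTRONEGATIVITY[(elements[a], basis_sub[k])]
                   for k, a in enumerate(basis_atoms)])
    beta0 = np.array([BETA0[elements[a]] for a in basis_atoms])
    beta = -0.5 * (beta0[:, None] + beta0[None, :]) * S
    same_atom = basis_atoms[:, None] == basis_atoms[None, :]
    beta[same_atom] = 0.0

    n_orb_atom = np.bincount(basis_atoms, minlength=n_atoms)
    # initial guess: valence electrons spread evenly over each atom's orbitals
    P = np.diag((z / n_orb_atom)[basis_atoms])

    def atom_populations(P):
        return np.bincount(basis_atoms, weights=np.diag(P), minlength=n_atoms)

    def fock(P):
        p_atom = atom_populations(P)
        net = p_atom - z                      # negative of net atomic charge
        diag = (-en
                + (net[basis_atoms] - 0.5 * (np.diag(P) - 1.0)) * np.diag(g_basis)
                + ((G @ net)[basis_atoms] - net[basis_atoms] * np.diag(g_basis)))
        F = beta - 0.5 * P * g_basis
        F[np.diag_indices(nb)] = diag
        return F

    def core_h():
        hdiag = (-en - (z[basis_atoms] - 0.5) * np.diag(g_basis)
                 - ((G @ z)[basis_atoms] - z[basis_atoms] * np.diag(g_basis)))
        H = beta.copy()
        H[np.diag_indices(nb)] = hdiag
        return H

    H = core_h()
    energies = []
    eps = C = None
    residual = np.inf
    for it in range(max_iter):
        F = fock(P)
        energies.append(0.5 * float(np.sum(P * (H + F))))
        P_new, eps, C = density_from_fock(F, n_occ)
        residual = float(np.max(np.abs(P_new - P)))
        if residual < tol:
            P = P_new
            break
        P = mixing * P_new + (1.0 - mixing) * P if it > 0 else P_new
    else:
        raise SCFConvergenceError(max_iter, residual)

    F = fock(P)
    electronic_energy = 0.5 * float(np.sum(P * (H + F)))

    # per-atom one-center e-e repulsion and e-n attraction tables
    p_atom = atom_populations(P)
    e_ee = np.empty(n_atoms)
    e_ne = np.empty(n_atoms)
    for a in range(n_atoms):
        idx = np.flatnonzero(basis_atoms == a)
        block = P[np.ix_(idx, idx)]
        e_ee[a] = 0.5 * G[a, a] * (p_atom[a] ** 2 - 0.5 * float(np.sum(block ** 2)))
        e_ne[a] = -p_atom[a] * float(np.sum(np.delete(G[a] * z, a)))

    return ElectronicStructure(
        density=P,
        mo_coefficients=C,
        orbital_energies=eps,
        homo_index=n_occ - 1,
        lumo_index=n_occ,
        beta=beta,
        e_ee=e_ee,
        e_ne=e_ne,
        basis_atoms=basis_atoms,
        elements=tuple(elements),
        bonds=tuple(ij for ij, _ in graph.bonds),
        electronic_energy=electronic_energy,
        scf_energies=tuple(energies),
    )
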