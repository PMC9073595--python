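"""Assemble the full descriptor vector for a compound.

The registry covers the nine descriptors appearing in the three cell-line
QSAR models: one topological (mean information content), one constitutional
count (hydrogen-donor sites), three CPSA-type charge/surface descriptors and
four quantum-chemical descriptors from the ZDO backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ..compounds import CompoundRecord
from .charges import equalized_charges
from .cpsa import cpsa_descriptors, h_donor_count
from .electronic import (
    ee_repulsion_per_atom,
    fukui_min_reaction_index,
    min_en_attraction_atom,
    min_resonance_energy_bond,
    net_atomic_charges,
)
from .graph import MolecularGraph, mean_information_content
from .sasa import BONDI_RADII, DEFAULT_POINTS, DEFAULT_PROBE
from .scf import zdo_scf
from .types import Conformer3D, DescriptorVector, ElectronicStructure

DEFAULT_SEED = 20191021

#: registry: name -> (units, provenance)
DESCRIPTOR_REGISTRY = {
    "ee_repulsion_per_atom": ("eV", "backend"),
    "min_fukui_reaction_index_O": ("1/eV", "backend"),
    "mean_information_content_0": ("bits", "topological"),
    "fpsa2": ("e", "backend"),
    "hdsa1": ("A^2", "empirical_charge"),
    "charged_surface_pos_C": ("e*A^2", "backend"),
    "h_donor_count": ("count", "empirical_charge"),
    "min_resonance_energy_HC": ("eV", "backend"),
    "min_en_attraction_N": ("eV", "backend"),
}

MODEL_DESCRIPTORS = {
    "HCT116": ("ee_repulsion_per_atom", "min_fukui_reaction_index_O",
               "mean_information_content_0"),
    "MCF7": ("fpsa2", "hdsa1", "charged_surface_pos_C"),
    "A431": ("h_donor_count", "min_resonance_energy_HC", "min_en_attraction_N"),
}


@dataclass
class DescriptorConfig:
    """Tunables of the descriptor engine (config-file surface)."""

    charges_scheme: str = "empirical_equalization"
    sasa_probe: float = DEFAULT_PROBE
    sasa_points: int = DEFAULT_POINTS
    backend: str = "zdo"          # "zdo" or "none"
    seed: int = DEFAULT_SEED
    h_donor_policy: str = "all_h"  # registry default; "hetero" also supported
    h_donor_threshold: float = 0.0
    scf_max_iter: int = 200
    scf_tol: float = 1e-6

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


class DescriptorProfileError(RuntimeError):
    """One or more sub-descriptors failed; lists every failure."""

    def __init__(self, failures: dict[str, str]):
        self.failures = failures
        msg = "; ".join(f"{k}: {v}" for k, v in failures.items())
        super().__init__(f"descriptor failures -- {msg}")


def embed_conformer(mol: Chem.Mol, seed: int = DEFAULT_SEED) -> Conformer3D:
    """Deterministic 3D conformer: one ETKDG embedding + MMFF relaxation."""
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError("conformer embedding failed")
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    except Exception:  # pragma: no cover - MMFF missing params; keep raw embed
        pass
    pos = mol.GetConformer().GetPositions()
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    radii = np.array([BONDI_RADII[el] for el in elements])
    return Conformer3D(np.asarray(pos), radii, elements)


def conformer_for_record(record: CompoundRecord, seed: int = DEFAULT_SEED) -> Conformer3D:
    return embed_conformer(record.mol(), seed=seed)


def descriptor_profile(
    record: CompoundRecord,
    backend: ElectronicStructure | None = None,
    config: DescriptorConfig | None = None,
    conformer: Conformer3D | None = None,
) -> DescriptorVector:
    """Full descriptor vector for one compound.

    `backend` may be a precomputed :class:`ElectronicStructure` (e.g. a mock);
    by default the bundled ZDO SCF runs on the embedded conformer.  Failures
    are collected per descriptor and raised together.
    """
    cfg = config or DescriptorConfig()
    graph = MolecularGraph.from_smiles(record.smiles, add_hs=True)
    if conformer is None:
        conformer = conformer_for_record(record, seed=cfg.seed)

    values: dict[str, float] = {}
    failures: dict[str, str] = {}

    try:
        charges = equalized_charges(graph)
    except Exception as exc:
        raise DescriptorProfileError({"equalized_charges": str(exc)}) from exc

    try:
        values["mean_information_content_0"] = mean_information_content(graph, 0)
    except Exception as exc:
        failures["mean_information_content_0"] = str(exc)

    es = backend
    backend_keys = ("ee_repulsion_per_atom", "min_fukui_reaction_index_O",
                    "min_resonance_energy_HC", "min_en_attraction_N")
    if es is None and cfg.backend == "zdo":
        try:
            es = zdo_scf(graph, conformer, max_iter=cfg.scf_max_iter, tol=cfg.scf_tol)
        except Exception as exc:
            for k in backend_keys:
                failures[k] = str(exc)

    # surface descriptors: backend charges where the registry names a
    # quantum charge scheme (FPSA2, per-element charged surface), empirical
    # equalization for the hydrogen-bond-donor area
    surface_charges = charges
    if es is not None and len(es.e_ee) == len(graph):
        surface_charges = net_atomic_charges(es)
    try:
        cpsa = cpsa_descriptors(conformer, surface_charges, graph=graph,
                                probe=cfg.sasa_probe, n_points=cfg.sasa_points,
                                element="C")
        values["fpsa2"] = cpsa["FPSA2"]
        values["hdsa1"] = cpsa["HDSA1"]
        values["charged_surface_pos_C"] = cpsa["charged_surface_pos_C"]
    except Exception as exc:
        for k in ("fpsa2", "hdsa1", "charged_surface_pos_C"):
            failures[k] = str(exc)

    try:
        # empirical charges: uniformly positive hydrogens make the count a
        # stable structural quantity under the "all_h" policy
        values["h_donor_count"] = float(h_donor_count(
            graph, charges, threshold=cfg.h_donor_threshold,
            policy=cfg.h_donor_policy))
    except Exception as exc:
        failures["h_donor_count"] = str(exc)

    if es is not None:
        for key, fn in (
            ("ee_repulsion_per_atom", lambda: ee_repulsion_per_atom(es)),
            ("min_fukui_reaction_index_O", lambda: fukui_min_reaction_index(es, "O")),
            ("min_resonance_energy_HC", lambda: min_resonance_energy_bond(es, ("H", "C"))),
            ("min_en_attraction_N", lambda: min_en_attraction_atom(es, "N")),
        ):
            try:
                values[key] = fn()
            except Exception as exc:
                failures[key] = str(exc)

    if failures:
        raise DescriptorProfileError(failures)
    units = {k: DESCRIPTOR_REGISTRY[k][0] for k in values}
    prov = {k: DESCRIPTOR_REGISTRY[k][1] for k in values}
    for k in ("fpsa2", "charged_surface_pos_C"):
        if k in prov:
            prov[k] = surface_charges.scheme
    return DescriptorVector(values=values, units=units, provenance=prov)


def descriptor_matrix(records, config: DescriptorConfig | None = None):
    """Descriptor profiles for many compounds as a pandas DataFrame."""
    import pandas as pd

    rows = {}
    for rec in records:
        rows[rec.id] = descriptor_profile(rec, config=config).values
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "compound_id"
    return df
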