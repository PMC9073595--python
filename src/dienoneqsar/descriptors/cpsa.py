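"""Charged-partial-surface-area (CPSA) descriptors.

These combine atomic partial charges q_A with solvent-accessible atomic
surface areas S_A:

* PPSA2 / PNSA2 -- "total charge weighted" partial surface areas: the total
  positive (negative) molecular charge multiplied by the total positively
  (negatively) charged surface area.
* FPSA2 = PPSA2 / TMSA, the fractional variant.
* HDSA1 -- the summed accessible area S_D of hydrogen-bond-donor hydrogens.
* Atomic charge-weighted surfaces: sum of q_A * S_A over the positively or
  negatively charged atoms, optionally restricted to one element (the
  "partial charged surface area for atom C" style descriptor).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .graph import MolecularGraph
from .sasa import DEFAULT_POINTS, DEFAULT_PROBE, shrake_rupley_sasa
from .types import ChargeSet, Conformer3D

DONOR_HEAVY_ELEMENTS = ("N", "O", "S")


def atomic_charge_weighted_surface(
    areas: Sequence[float],
    charges: Sequence[float],
    sign: int,
    elements: Sequence[str] | None = None,
    element: str | None = None,
) -> float:
    """sum of q_A * S_A over atoms with sign(q_A) == sign (optionally one element)."""
    areas = np.asarray(areas, dtype=float)
    q = np.asarray(charges, dtype=float)
    mask = q > 0 if sign > 0 else q < 0
    if element is not None:
        if elements is None:
            raise ValueError("element restriction requires element labels")
        mask &= np.asarray(elements) == element
    return float(np.sum(q[mask] * areas[mask]))


def donor_hydrogen_mask(graph: MolecularGraph) -> np.ndarray:
    """Boolean mask of explicit H atoms attached to N, O or S."""
    mask = np.zeros(len(graph), dtype=bool)
    for h_idx, heavy_idx in graph.hydrogen_attachment().items():
        if graph.elements[heavy_idx] in DONOR_HEAVY_ELEMENTS:
            mask[h_idx] = True
    return mask


def cpsa_from_areas(
    areas: Sequence[float],
    charges: ChargeSet | Sequence[float],
    elements: Sequence[str] | None = None,
    donor_h_mask: Sequence[bool] | None = None,
    element: str | None = None,
) -> dict[str, float]:
    """CPSA family from precomputed per-atom areas (pure arithmetic layer)."""
    areas = np.asarray(areas, dtype=float)
    q = np.asarray(charges.charges if isinstance(charges, ChargeSet) else charges,
                   dtype=float)
    if len(areas) != len(q):
        raise ValueError("areas and charges must refer to the same atom list")
    tmsa = float(areas.sum())
    if tmsa == 0:
        raise ValueError("TMSA is zero")
    pos, neg = q > 0, q < 0
    ppsa2 = float(q[pos].sum() * areas[pos].sum())
    pnsa2 = float(q[neg].sum() * areas[neg].sum())
    out = {
        "TMSA": tmsa,
        "PPSA2": ppsa2,
        "PNSA2": pnsa2,
        "FPSA2": ppsa2 / tmsa,
        "FNSA2": pnsa2 / tmsa,
        "charged_surface_pos": atomic_charge_weighted_surface(areas, q, +1),
        "charged_surface_neg": atomic_charge_weighted_surface(areas, q, -1),
    }
    if donor_h_mask is not None:
        out["HDSA1"] = float(areas[np.asarray(donor_h_mask, dtype=bool)].sum())
    if element is not None:
        out[f"charged_surface_pos_{element}"] = atomic_charge_weighted_surface(
            areas, q, +1, elements, element)
        out[f"charged_surface_neg_{element}"] = atomic_charge_weighted_surface(
            areas, q, -1, elements, element)
    return out


def cpsa_descriptors(
    conf: Conformer3D,
    charges: ChargeSet,
    graph: MolecularGraph | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    element: str | None = None,
) -> dict[str, float]:
    """CPSA descriptors from a conformer and a charge set.

    `graph` supplies donor-hydrogen identities for HDSA1; `element` adds the
    element-restricted charge-weighted surface pair.
    """
    if len(conf) != len(charges):
        raise ValueError("conformer and charges must refer to the same atom list")
    areas = shrake_rupley_sasa(conf, probe=probe, n_points=n_points)
    elements = conf.elements
    donor_mask = None
    if graph is not None:
        if len(graph) != len(conf):
            raise ValueError("graph and conformer must refer to the same atom list")
        donor_mask = donor_hydrogen_mask(graph)
        elements = graph.elements
    return cpsa_from_areas(areas, charges, elements=elements,
                           donor_h_mask=donor_mask, element=element)


def h_donor_count(
    graph: MolecularGraph,
    charges: ChargeSet,
    threshold: float = 0.0,
    policy: str = "hetero",
) -> int:
    """Count hydrogen-bond-donor hydrogen sites.

    policy="hetero": H bonded to N/O/S with charge >= threshold (the classical
    donor definition).  policy="all_h": every H with charge >= threshold --
    exposed because published donor-site counts for this compound family are
    far larger than their N-H counts.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if policy not in ("hetero", "all_h"):
        raise ValueError(f"unknown policy {policy!r}")
    q = charges.charges
    if policy == "hetero":
        mask = donor_hydrogen_mask(graph)
    else:
        mask = np.asarray([sym == "H" for sym in graph.elements])
    return int(np.sum(mask & (q >= threshold)))
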