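"""Empirical partial charges by Sanderson electronegativity equalization.

On molecule formation all atomic electronegativities are assumed to equalize
at the geometric mean of the isolated-atom values S_i.  The charge an atom
acquires is proportional to the equalization it undergoes, measured against
the change of one full electron, 2.08 * sqrt(S_i):

    q_i = (S_mol - S_i) / (2.08 * sqrt(S_i)),   S_mol = (prod S_i)^(1/n)

A uniform shift then enforces the exact total molecular charge; for neutral
organics the shift is tiny (the raw charges nearly balance already).  This is
the classical Zefirov-style scheme: fast, geometry-free and adequate for
charge-related surface descriptors, but it cannot distinguish atoms of one
element in different environments.
"""

from __future__ import annotations

import math

from .graph import MolecularGraph
from .types import ChargeSet

#: Sanderson electronegativities (dimensionless).
SANDERSON_EN = {
    "H": 2.31, "C": 2.47, "N": 2.93, "O": 3.46,
    "F": 3.92, "Cl": 3.28, "S": 2.66,
}


def equalized_charges(graph: MolecularGraph, total_charge: float | None = None) -> ChargeSet:
    """Sanderson-equalized partial charges for every atom of the graph.

    `total_charge` defaults to the sum of formal charges.  Atoms of the same
    element receive equal charges, so graph automorphisms are respected by
    construction.
    """
    if len(graph) == 0:
        raise ValueError("empty graph")
    try:
        s = [SANDERSON_EN[sym] for sym in graph.elements]
    except KeyError as exc:
        raise ValueError(f"no electronegativity parameter for element {exc}") from exc
    if total_charge is None:
        total_charge = float(sum(fc for _, fc, _ in graph.atoms))
    n = len(s)
    s_mol = math.exp(sum(math.log(v) for v in s) / n)
    raw = [(s_mol - si) / (2.08 * math.sqrt(si)) for si in s]
    shift = (total_charge - sum(raw)) / n
    return ChargeSet([q + shift for q in raw], scheme="empirical_equalization")
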