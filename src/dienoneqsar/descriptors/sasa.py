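"""Solvent-accessible surface areas by the Shrake-Rupley rolling-probe method.

Each atom is inflated by the probe radius and covered with a deterministic
quasi-uniform point set (golden-section spiral).  A point survives if it lies
outside every other inflated sphere; the accessible area of the atom is the
surviving fraction of its full sphere 4*pi*(r + probe)^2.  The total over all
atoms is the total molecular surface area (TMSA).
"""

from __future__ import annotations

import numpy as np

from .types import Conformer3D

#: Bondi van der Waals radii (Angstrom).
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "Cl": 1.75, "S": 1.80,
}

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-section spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(
    conf: Conformer3D,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible areas in Angstrom^2.

    The same quadrature is used for every atom, so summing the output gives
    TMSA exactly (no residual from mixed point sets).
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 96:
        raise ValueError("n_points must be at least 96")
    xyz = conf.coordinates
    big = conf.radii + probe
    unit = sphere_points(n_points)
    n = len(conf)
    eps = 1e-9
    areas = np.empty(n)
    for i in range(n):
        pts = xyz[i] + big[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            # only neighbours whose inflated sphere can reach atom i's shell
            if np.linalg.norm(xyz[j] - xyz[i]) >= big[i] + big[j]:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            lim = big[j] ** 2
            # boundary points (coincident spheres) stay with the lower index
            occluded = d2 < lim * (1 - eps)
            if j < i:
                occluded |= d2 <= lim * (1 + eps)
            exposed &= ~occluded
        areas[i] = 4.0 * np.pi * big[i] ** 2 * exposed.mean()
    return areas


def total_surface_area(conf: Conformer3D, probe: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_POINTS) -> float:
    return float(shrake_rupley_sasa(conf, probe, n_points).sum())
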