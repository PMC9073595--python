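"""Pharmacophore hypotheses, fit-value scoring and activity calibration.

A hypothesis is a set of weighted, toleranced chemical features (hydrogen-
bond acceptors and hydrophobic centroids).  A molecule mapped onto the
hypothesis scores a fit value

    fit = sum over mapped features of  w * (1 - (d / tol)^2)

where d is the displacement of the molecule feature from the hypothesis
feature centroid.  Published fit values relate to estimated activity through
a single per-hypothesis constant:  fit + log10(IC50_est) = c,  so
IC50_est = 10^(c - fit); `calibrate_activity_constant` recovers c from any
published (fit, estimated IC50) rows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from statistics import mean, stdev

from rdkit import Chem

from .compounds import CompoundRecord
from .descriptors.types import Conformer3D

FEATURE_KINDS = ("HBA", "hydrophobic")

#: feature inventory of the per-cell-line hypotheses
HYPOTHESIS_INVENTORY = {
    "HCT116": {"hydrophobic": 3, "HBA": 1},
    "MCF7": {"hydrophobic": 2, "HBA": 1},
    "A431": {"hydrophobic": 2, "HBA": 2},
}


@dataclass(frozen=True)
class Feature:
    kind: str
    centroid: tuple[float, float, float]
    tolerance: float = 1.6
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class PharmacophoreHypothesis:
    features: list[Feature]
    constant_c: float = 0.0      # log10(uM) offset of the fit->IC50 relation
    cell_line: str | None = None

    def inventory(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.kind] = out.get(f.kind, 0) + 1
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "cell_line": self.cell_line,
            "constant_c": self.constant_c,
            "features": [
                {"kind": f.kind, "centroid": list(f.centroid),
                 "tolerance": f.tolerance, "weight": f.weight}
                for f in self.features
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PharmacophoreHypothesis":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        feats = [Feature(f["kind"], tuple(f["centroid"]),
                         f.get("tolerance", 1.6), f.get("weight", 1.0))
                 for f in payload["features"]]
        return cls(feats, payload.get("constant_c", 0.0), payload.get("cell_line"))


@dataclass
class FeatureMapping:
    """Pairs of (hypothesis feature, molecule feature position)."""

    pairs: list[tuple[Feature, tuple[float, float, float]]] = field(default_factory=list)

    def displacements(self) -> list[float]:
        return [
            math.dist(f.centroid, pos) for f, pos in self.pairs
        ]


def fit_value(hyp: PharmacophoreHypothesis, mapping: FeatureMapping) -> float:
    """Weighted quadratic-displacement fit score; unmapped features score 0."""
    seen = set()
    total = 0.0
    for feature, pos in mapping.pairs:
        key = id(feature)
        if key in seen:
            raise ValueError("hypothesis feature mapped more than once")
        seen.add(key)
        d = math.dist(feature.centroid, pos)
        if d > feature.tolerance:
            raise ValueError(
                f"displacement {d:.3f} exceeds tolerance {feature.tolerance:.3f}")
        total += feature.weight * (1.0 - (d / feature.tolerance) ** 2)
    return total


@dataclass
class CalibrationResult:
    constant_c: float
    sd: float
    n: int


def calibrate_activity_constant(rows) -> CalibrationResult:
    """Recover c = mean(fit + log10(estimated IC50)) from (fit, IC50) rows."""
    rows = list(rows)
    if not rows:
        raise ValueError("no calibration rows")
    vals = []
    for fit, ic50 in rows:
        if ic50 <= 0:
            raise ValueError("estimated IC50 must be positive")
        vals.append(fit + math.log10(ic50))
    return CalibrationResult(
        constant_c=mean(vals),
        sd=stdev(vals) if len(vals) > 1 else 0.0,
        n=len(vals),
    )


def estimate_activity(fit: float, constant_c: float) -> float:
    """Estimated IC50 (uM) from a fit value: 10^(c - fit)."""
    return 10.0 ** (constant_c - fit)


# --- molecule feature perception -------------------------------------------

_ACCEPTOR_SMARTS = Chem.MolFromSmarts("[$([OX1]),$([OX2;!$([OX2]-[#1])]),$([SX2]),$([sX2])]")
_ALKYL_CARBON = Chem.MolFromSmarts("[CX4;!$(C-[!#6;!#1])]")


def detect_features(
    record: CompoundRecord | Chem.Mol,
    conf: Conformer3D,
) -> list[tuple[str, tuple[float, float, float]]]:
    """Perceive (kind, position) chemical features on a conformer.

    HBA features sit on carbonyl/ether oxygens and (thio)ether sulfurs;
    hydrophobic features sit on ring centroids and on centroids of connected
    alkyl-carbon fragments.  Atom order must match the conformer (explicit
    hydrogens appended after the heavy atoms, as RDKit's AddHs produces).
    """
    mol = record.mol(add_hs=False) if isinstance(record, CompoundRecord) else record
    xyz = conf.coordinates
    features: list[tuple[str, tuple[float, float, float]]] = []
    for match in mol.GetSubstructMatches(_ACCEPTOR_SMARTS):
        features.append(("HBA", tuple(xyz[match[0]])))
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        features.append(("hydrophobic", tuple(xyz[list(ring)].mean(axis=0))))
    # connected clusters of plain alkyl carbons (e.g. ethyl, methyl arms)
    alkyl = {m[0] for m in mol.GetSubstructMatches(_ALKYL_CARBON)
             if not mol.GetAtomWithIdx(m[0]).IsInRing()}
    seen: set[int] = set()
    for start in sorted(alkyl):
        if start in seen:
            continue
        stack, cluster = [start], []
        while stack:
            a = stack.pop()
            if a in seen:
                continue
            seen.add(a)
            cluster.append(a)
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                if nb.GetIdx() in alkyl and nb.GetIdx() not in seen:
                    stack.append(nb.GetIdx())
        features.append(("hydrophobic", tuple(xyz[cluster].mean(axis=0))))
    return features


def map_features(
    hyp: PharmacophoreHypothesis,
    molecule_features,
) -> FeatureMapping:
    """Greedy nearest-neighbour assignment of molecule features to hypothesis
    features of matching kind, honouring tolerances; unmapped features are
    simply left out (they score 0)."""
    available = list(molecule_features)
    pairs = []
    for feature in sorted(hyp.features, key=lambda f: -f.weight):
        best = None
        best_d = None
        for i, (kind, pos) in enumerate(available):
            if kind != feature.kind:
                continue
            d = math.dist(feature.centroid, pos)
            if d <= feature.tolerance and (best_d is None or d < best_d):
                best, best_d = i, d
        if best is not None:
            pairs.append((feature, available.pop(best)[1]))
    return FeatureMapping(pairs)


def example_hypothesis(cell_line: str, constant_c: float = 0.0) -> PharmacophoreHypothesis:
    """Synthetic example hypothesis with the published feature inventory.

    Geometries are illustrative only (the source hypotheses' coordinates are
    not published); feature counts per kind match the per-cell-line models.
    """
    inventory = HYPOTHESIS_INVENTORY[cell_line]
    positions = iter([(0.0, 0.0, 0.0), (4.5, 0.0, 0.0), (-4.5, 0.0, 0.0),
                      (0.0, 4.5, 0.0), (0.0, -4.5, 0.0)])
    feats = []
    for kind in ("HBA", "hydrophobic"):
        for _ in range(inventory.get(kind, 0)):
            feats.append(Feature(kind, next(positions), tolerance=1.6, weight=1.0))
    return PharmacophoreHypothesis(feats, constant_c=constant_c, cell_line=cell_line)


def calibrate_from_table(fits_table, cell_line: str) -> CalibrationResult:
    """Calibrate c from a printed fits table (columns fit_value, estimated_ic50)."""
    rows = fits_table[fits_table["cell_line"] == cell_line]
    return calibrate_activity_constant(
        list(zip(rows["fit_value"].astype(float), rows["estimated_ic50"].astype(float))))
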