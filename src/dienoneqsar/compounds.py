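"""Compound library: the 28 synthesized 3,5-bis(arylidene)-4-oxo-piperidine-
1-carboxamides, their printed analytical facts, and the bio-activity tables.

The molecules share one scaffold -- a 4-piperidone bearing two exocyclic
(E)-arylidene olefins at C-3/C-5 and a urea (carboxamide) at N-1.  Every
fixture SMILES is generated from a single template so that the arylidene and
carboxamide substituent classes are the only degrees of freedom.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from rdkit import Chem

ARYLIDENE_CLASSES = (
    "phenyl", "4-Cl-phenyl", "4-F-phenyl", "4-Me-phenyl", "4-MeO-phenyl", "2-thienyl",
)
CARBOXAMIDE_CLASSES = ("phenyl", "4-Cl-phenyl", "4-MeO-phenyl", "ethyl", "benzyl")

CELL_LINES = ("HCT116", "MCF7", "A431", "RPE1")
ASSAYS = CELL_LINES + ("TopoIIa",)
CENSOR_STATES = ("exact", "greater_than", "less_than")

#: CIAAW conventional atomic weights (g/mol), 3 decimals where defined.
ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Cl": 35.45, "S": 32.06,
}

_ARYLIDENE_SMILES = {
    "phenyl": "c2ccccc2",
    "4-Cl-phenyl": "c2ccc(Cl)cc2",
    "4-F-phenyl": "c2ccc(F)cc2",
    "4-Me-phenyl": "c2ccc(C)cc2",
    "4-MeO-phenyl": "c2ccc(OC)cc2",
    "2-thienyl": "c2cccs2",
}
_CARBOXAMIDE_SMILES = {
    "phenyl": "c3ccccc3",
    "4-Cl-phenyl": "c3ccc(Cl)cc3",
    "4-MeO-phenyl": "c3ccc(OC)cc3",
    "ethyl": "CC",
    "benzyl": "Cc3ccccc3",
}


class CompoundTableError(ValueError):
    """File-level problem with a compound table (missing columns, bad ids)."""


class CompoundRecordError(ValueError):
    """Record-level problem; carries the offending compound id."""

    def __init__(self, compound_id, message):
        self.compound_id = compound_id
        super().__init__(f"compound {compound_id}: {message}")


def scaffold_smiles(arylidene_class: str, carboxamide_class: str) -> str:
    """Build the scaffold SMILES for a (arylidene, carboxamide) class pair.

    Directional bond markers encode the E geometry on both exocyclic olefins.
    """
    ar = _ARYLIDENE_SMILES[arylidene_class]
    cx = _CARBOXAMIDE_SMILES[carboxamide_class]
    return f"O=C(N{cx})N1C/C(=C\\{ar})C(=O)/C(=C/{ar})C1"


@dataclass(frozen=True)
class CompoundRecord:
    id: int
    name: str
    smiles: str
    arylidene_class: str
    carboxamide_class: str
    printed_formula: dict | None = None
    printed_mw: float | None = None
    required_percent: dict | None = None  # element -> printed "required" %

    def mol(self, add_hs: bool = False) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - guarded at construction
            raise CompoundRecordError(self.id, f"unparsable SMILES {self.smiles!r}")
        return Chem.AddHs(m) if add_hs else m


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching how the tables print values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def parse_formula(text: str) -> dict:
    """'C26H19Cl3N2O2' -> {'C': 26, 'H': 19, 'Cl': 3, 'N': 2, 'O': 2}."""
    import re

    counts: dict[str, int] = {}
    for sym, num in re.findall(r"([A-Z][a-z]?)(\d*)", text):
        if sym:
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    return counts


def formula_to_string(counts: dict) -> str:
    """Hill-order formula string (C, H, then alphabetical)."""
    order = ["C", "H"] + sorted(k for k in counts if k not in ("C", "H"))
    return "".join(f"{el}{counts[el] if counts[el] > 1 else ''}"
                   for el in order if counts.get(el))


def molecular_formula(record: CompoundRecord | str) -> tuple[dict, float]:
    """Element counts (implicit H included) and molecular weight (2 decimals).

    Accepts a CompoundRecord or a bare SMILES string.
    """
    smiles = record if isinstance(record, str) else record.smiles
    cid = None if isinstance(record, str) else record.id
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CompoundRecordError(cid, f"unparsable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    counts = Counter(atom.GetSymbol() for atom in mol.GetAtoms())
    try:
        mw = sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())
    except KeyError as exc:
        raise CompoundRecordError(cid, f"no atomic weight for element {exc}") from exc
    return dict(counts), round_half_up(mw, 2)


def elemental_percent(record: CompoundRecord | str, element: str) -> float:
    """Mass percent of `element`, to 2 decimals (the 'required' convention)."""
    counts, _ = molecular_formula(record)
    if element not in counts:
        cid = None if isinstance(record, str) else record.id
        raise CompoundRecordError(cid, f"element {element} absent from formula")
    mass = sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())
    return round_half_up(100.0 * ATOMIC_WEIGHTS[element] * counts[element] / mass, 2)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("dienoneqsar").joinpath("data", name)))


def _record_from_row(row: dict) -> CompoundRecord:
    cid = int(row["id"])
    smiles = row["smiles"]
    if Chem.MolFromSmiles(smiles) is None:
        raise CompoundRecordError(cid, f"unparsable SMILES {smiles!r}")
    if row.get("arylidene_class") not in ARYLIDENE_CLASSES:
        raise CompoundRecordError(cid, f"unknown arylidene class {row.get('arylidene_class')!r}")
    if row.get("carboxamide_class") not in CARBOXAMIDE_CLASSES:
        raise CompoundRecordError(cid, f"unknown carboxamide class {row.get('carboxamide_class')!r}")
    req = None
    if row.get("required_pct_C"):
        req = {el: float(row[f"required_pct_{el}"]) for el in ("C", "H", "N")}
    return CompoundRecord(
        id=cid,
        name=row.get("name", f"compound {cid}"),
        smiles=smiles,
        arylidene_class=row["arylidene_class"],
        carboxamide_class=row["carboxamide_class"],
        printed_formula=parse_formula(row["printed_formula"]) if row.get("printed_formula") else None,
        printed_mw=float(row["printed_mw"]) if row.get("printed_mw") else None,
        required_percent=req,
    )


def parse_compound_table(path) -> list[CompoundRecord]:
    """Read a delimited compound table into validated records.

    The file must carry a header with at least id, smiles, arylidene_class
    and carboxamide_class columns; duplicate ids are rejected.
    """
    required = {"id", "smiles", "arylidene_class", "carboxamide_class"}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or ())
            raise CompoundTableError(f"{path}: missing columns {sorted(missing)}")
        records = []
        seen = set()
        for row in reader:
            rec = _record_from_row(row)
            if rec.id in seen:
                raise CompoundTableError(f"{path}: duplicate compound id {rec.id}")
            seen.add(rec.id)
            records.append(rec)
    return records


def write_compound_table(records: Iterable[CompoundRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "arylidene_class", "carboxamide_class",
                    "printed_formula", "printed_mw", "required_pct_C",
                    "required_pct_H", "required_pct_N", "name"])
        for r in records:
            req = r.required_percent or {}
            w.writerow([
                r.id, r.smiles, r.arylidene_class, r.carboxamide_class,
                formula_to_string(r.printed_formula) if r.printed_formula else "",
                f"{r.printed_mw:.2f}" if r.printed_mw is not None else "",
                *(f"{req[el]:.2f}" if el in req else "" for el in ("C", "H", "N")),
                r.name,
            ])


def validate_activity_table(table: pd.DataFrame) -> pd.DataFrame:
    cols = {"compound_id", "assay", "ic50_um", "sd_um", "censor"}
    if not cols.issubset(table.columns):
        raise CompoundTableError(f"activity table missing columns {sorted(cols - set(table.columns))}")
    if (table["ic50_um"] <= 0).any():
        raise CompoundTableError("activity table: non-positive IC50")
    if (table["sd_um"] < 0).any():
        raise CompoundTableError("activity table: negative SD")
    bad = set(table["censor"]) - set(CENSOR_STATES)
    if bad:
        raise CompoundTableError(f"activity table: unknown censor states {sorted(bad)}")
    bad = set(table["assay"]) - set(ASSAYS)
    if bad:
        raise CompoundTableError(f"activity table: unknown assays {sorted(bad)}")
    return table


def load_activity_table(path=None) -> pd.DataFrame:
    """Load an activity table (defaults to the packaged printed tables).

    Columns: compound_id, assay, ic50_um, sd_um, censor, is_reference.
    Censored entries store the bound (e.g. 50.00) with censor='greater_than'.
    """
    path = _data_path("activity.csv") if path is None else path
    table = pd.read_csv(path, dtype={"compound_id": str})
    if "is_reference" not in table.columns:
        table["is_reference"] = 0
    return validate_activity_table(table)


def build_fixture_library() -> tuple[list[CompoundRecord], pd.DataFrame]:
    """The 28 packaged compound records plus the packaged activity rows."""
    records = parse_compound_table(_data_path("compounds.csv"))
    return records, load_activity_table()


def load_printed_therapeutic_indices() -> pd.DataFrame:
    """Parenthesized therapeutic-index values as printed, with operators."""
    return pd.read_csv(_data_path("therapeutic_indices.csv"))


def load_qsar_estimates() -> pd.DataFrame:
    """Observed/estimated IC50 and error columns of the printed QSAR table."""
    return pd.read_csv(_data_path("qsar_estimates.csv"))


def load_pharmacophore_fits() -> pd.DataFrame:
    """Observed/estimated IC50 and fit values of the printed pharmacophore table."""
    return pd.read_csv(_data_path("pharmacophore_fits.csv"))
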