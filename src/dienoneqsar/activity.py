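"""Activity post-processing: therapeutic indices, prediction errors and
substituent-class SAR summaries, with explicit censoring propagation.

A therapeutic index is IC50(normal RPE1 cells) / IC50(cancer cells); a
censored normal-cell entry (">50.00") makes the index a bound.  Following
the source tables' printed convention, indices derived from a censored RPE1
entry carry the operator "less_than" and indices whose cancer-line entry is
censored are undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compounds import CompoundRecord, round_half_up


class ActivityLookupError(KeyError):
    pass


class CensoredGroupError(ValueError):
    pass


@dataclass(frozen=True)
class TherapeuticIndex:
    compound_id: str
    cell_line: str
    value: float | None          # None when undefined (cancer entry censored)
    operator: str                # "exact", "less_than", "greater_than", "undefined"

    @property
    def defined(self) -> bool:
        return self.value is not None


def _entry(table: pd.DataFrame, compound_id, assay: str):
    rows = table[(table["compound_id"].astype(str) == str(compound_id))
                 & (table["assay"] == assay)]
    if rows.empty:
        raise ActivityLookupError(f"no {assay} entry for compound {compound_id}")
    row = rows.iloc[0]
    return float(row["ic50_um"]), str(row["censor"])


def therapeutic_index(table: pd.DataFrame, compound_id, cell_line: str) -> TherapeuticIndex:
    """IC50(RPE1)/IC50(cancer line) with censoring operators propagated.

    The reported value is rounded half-up to 2 decimals, matching the printed
    parenthesized indices.
    """
    rpe1, rpe1_censor = _entry(table, compound_id, "RPE1")
    cancer, cancer_censor = _entry(table, compound_id, cell_line)
    if cancer_censor != "exact":
        return TherapeuticIndex(str(compound_id), cell_line, None, "undefined")
    value = round_half_up(rpe1 / cancer, 2)
    operator = "exact" if rpe1_censor == "exact" else "less_than"
    return TherapeuticIndex(str(compound_id), cell_line, value, operator)


def prediction_error(observed: float, estimated: float) -> float:
    """Observed minus estimated bio-activity."""
    if not (np.isfinite(observed) and np.isfinite(estimated)):
        raise ValueError("observed and estimated must be finite")
    return observed - estimated


def substituent_group_summary(
    table: pd.DataFrame,
    compounds: list[CompoundRecord],
    group,
    cell_line: str,
) -> tuple[float, float, float]:
    """(min, max, mean) IC50 over a substituent-class group of compounds.

    `group` is a predicate over CompoundRecord (or an iterable of compound
    ids).  Censored entries are excluded with a warning; an all-censored
    group is an error.
    """
    if callable(group):
        members = [r.id for r in compounds if group(r)]
    else:
        members = list(group)
    if not members:
        raise ValueError("empty substituent group")
    values = []
    skipped = []
    for cid in members:
        ic50, censor = _entry(table, cid, cell_line)
        if censor == "exact":
            values.append(ic50)
        else:
            skipped.append(cid)
    if skipped:
        warnings.warn(f"censored {cell_line} entries excluded for compounds {skipped}",
                      stacklevel=2)
    if not values:
        raise CensoredGroupError(f"every {cell_line} entry in the group is censored")
    arr = np.asarray(values)
    return float(arr.min()), float(arr.max()), float(arr.mean())


def therapeutic_index_table(table: pd.DataFrame, cell_lines=("HCT116", "MCF7", "A431")) -> pd.DataFrame:
    """Recomputed therapeutic indices for every non-reference compound."""
    is_ref = table.get("is_reference", pd.Series(0, index=table.index)) == 1
    ids = sorted(set(table.loc[~is_ref, "compound_id"].astype(str)), key=lambda s: (len(s), s))
    rows = []
    for cid in ids:
        if table[(table["compound_id"].astype(str) == cid) & (table["assay"] == "RPE1")].empty:
            continue
        for cl in cell_lines:
            try:
                ti = therapeutic_index(table, cid, cl)
            except ActivityLookupError:
                continue
            rows.append({"compound_id": cid, "assay": cl,
                         "value": ti.value, "operator": ti.operator})
    return pd.DataFrame(rows)


def prediction_error_table(estimates: pd.DataFrame) -> pd.DataFrame:
    """Observed - estimated columns recomputed from a printed-estimates table."""
    out = estimates.copy()
    out["recomputed_error"] = [
        round_half_up(prediction_error(o, e), 2)
        for o, e in zip(out["observed_ic50"], out["estimated_ic50"])
    ]
    return out
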