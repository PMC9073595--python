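"""End-to-end orchestration: descriptors -> model -> validation -> reports.

A run is fully described by a :class:`PipelineConfig`; given the same config
(including its seed) the report is byte-identical.  One global seed fans out
to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as activity_mod
from . import compounds as compounds_mod
from .descriptors import DescriptorConfig, MODEL_DESCRIPTORS, descriptor_matrix
from .pharmacophore import calibrate_from_table, estimate_activity
from .regression import (
    CensoredActivityError,
    bmlr_search,
    cross_validate,
    scale_activity,
)

logger = logging.getLogger("dienoneqsar.pipeline")

#: default response scale per cell line (potency modelled as 1/IC50 for
#: HCT116, plain IC50 for MCF7 and A431)
DEFAULT_SCALES = {"HCT116": "inverse_ic50", "MCF7": "ic50", "A431": "ic50"}

SEED_OFFSETS = {"descriptors": 0, "lmo": 1, "synth": 2}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    cell_line: str = "HCT116"
    scale: str | None = None            # None -> cell-line default
    compound_table: str | None = None   # None -> packaged fixtures
    activity_table: str | None = None
    descriptor_matrix: str | None = None  # precomputed matrix (CSV) to reuse
    k: int = 3
    beam: int = 10
    collinearity_max: float = 0.8
    leave_fraction: float = 1.0 / 3.0
    cv_repeats: int = 100
    seed: int = 20191021
    output_dir: str = "pipeline_out"
    descriptor_config: dict = field(default_factory=dict)

    def resolved_scale(self) -> str:
        return self.scale or DEFAULT_SCALES.get(self.cell_line, "ic50")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _load_inputs(config: PipelineConfig):
    try:
        if config.compound_table:
            records = compounds_mod.parse_compound_table(config.compound_table)
        else:
            records, _ = compounds_mod.build_fixture_library()
        table = compounds_mod.load_activity_table(config.activity_table)
    except FileNotFoundError as exc:
        raise PipelineError("load", str(exc)) from exc
    except compounds_mod.CompoundTableError as exc:
        raise PipelineError("load", str(exc)) from exc
    return records, table


def _modelled_records(records, table, cell_line):
    """The QSAR modelling set: benzylidene-series compounds (the thienylidene
    series is excluded from modelling) with an uncensored entry for the
    cell line."""
    ok = []
    for rec in records:
        if rec.arylidene_class == "2-thienyl":
            continue
        rows = table[(table["compound_id"].astype(str) == str(rec.id))
                     & (table["assay"] == cell_line)]
        if len(rows) and (rows["censor"] == "exact").all():
            ok.append(rec)
    return ok


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute descriptors -> BMLR -> validation -> activity reports.

    Returns the run report (also written to output_dir/report.json).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage=load cell_line=%s seed=%d", config.cell_line, config.seed)
    records, table = _load_inputs(config)
    modelled = _modelled_records(records, table, config.cell_line)
    scale = config.resolved_scale()

    logger.info("stage=descriptors n_compounds=%d", len(modelled))
    if config.descriptor_matrix:
        X = pd.read_csv(config.descriptor_matrix, index_col="compound_id")
        X = X.loc[[r.id for r in modelled]]
    else:
        dcfg = DescriptorConfig.from_dict(
            {"seed": config.seed + SEED_OFFSETS["descriptors"],
             **config.descriptor_config})
        try:
            X = descriptor_matrix(modelled, config=dcfg)
        except Exception as exc:
            raise PipelineError("descriptors", str(exc)) from exc
        X.to_csv(out / "descriptor_matrix.csv")

    logger.info("stage=fit scale=%s k=%d beam=%d", scale, config.k, config.beam)
    try:
        y = scale_activity(table, scale, config.cell_line,
                           compound_ids=[r.id for r in modelled])
    except CensoredActivityError as exc:
        raise PipelineError("fit", str(exc)) from exc
    ranked = bmlr_search(X, y, k=config.k, beam=config.beam,
                         collinearity_max=config.collinearity_max)
    if not ranked:
        raise PipelineError("fit", "BMLR search returned no admissible model")
    best = ranked[0]

    logger.info("stage=validate terms=%s", list(best.descriptor_names))
    cv = cross_validate(X, y, best.descriptor_names,
                        leave_fraction=config.leave_fraction,
                        repeats=config.cv_repeats,
                        seed=config.seed + SEED_OFFSETS["lmo"])

    logger.info("stage=report")
    fitted = best.predict(X)
    if scale == "inverse_ic50":
        est_ic50 = 1.0 / np.maximum(fitted, 1e-6)
    elif scale == "log_inverse_ic50":
        est_ic50 = 10.0 ** (-fitted)
    else:
        est_ic50 = np.maximum(fitted, 0.0)
    ids = [r.id for r in modelled]
    obs = table.set_index([table["compound_id"].astype(str), "assay"])
    observed = [float(obs.loc[(str(i), config.cell_line), "ic50_um"]) for i in ids]
    estimates = pd.DataFrame({
        "compound_id": ids,
        "observed_ic50": observed,
        "estimated_ic50": np.round(est_ic50, 2),
    })
    estimates["error"] = [
        compounds_mod.round_half_up(activity_mod.prediction_error(o, e), 2)
        for o, e in zip(estimates["observed_ic50"], estimates["estimated_ic50"])]
    ti = activity_mod.therapeutic_index_table(table, cell_lines=(config.cell_line,))

    report = {
        "config": asdict(config),
        "scale": scale,
        "model": best.report(),
        "cv": {"r2cv_loo": cv.r2cv_loo, "r2cv_lmo": cv.r2cv_lmo,
               "partitions": cv.partitions, "seed": cv.seed},
        "model_descriptor_registry": list(MODEL_DESCRIPTORS.get(config.cell_line, ())),
        "estimates": estimates.to_dict(orient="records"),
        "therapeutic_indices": ti.where(pd.notna(ti), None).to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("stage=done r2=%.4f loo=%.4f", best.r2, cv.r2cv_loo)
    return report


# --- printed-table reproduction checks -------------------------------------

def reproduce_tables(tol: float = 0.011) -> dict:
    """Recompute every derived column of the printed tables and diff.

    Returns {check_name: {"passed": bool, "detail": ...}} covering the
    therapeutic indices, the error cells, the printed-model R^2 values and
    the pharmacophore calibration consistency.
    """
    records, table = compounds_mod.build_fixture_library()
    checks: dict[str, dict] = {}

    printed = compounds_mod.load_printed_therapeutic_indices()
    max_dev, mismatches = 0.0, []
    for _, row in printed.iterrows():
        ti = activity_mod.therapeutic_index(table, row["compound_id"], row["assay"])
        if row["operator"] == "undefined":
            ok = ti.operator == "undefined"
            if not ok:
                mismatches.append((row["compound_id"], row["assay"], "operator"))
            continue
        ok = ti.operator == row["operator"] and ti.value is not None
        dev = abs(ti.value - float(row["value"])) if ti.value is not None else np.inf
        max_dev = max(max_dev, dev)
        if not ok or dev > tol:
            mismatches.append((row["compound_id"], row["assay"], dev))
    checks["therapeutic_indices"] = {
        "passed": not mismatches, "max_abs_dev": max_dev, "mismatches": mismatches}

    t2 = compounds_mod.load_qsar_estimates()
    errs = activity_mod.prediction_error_table(t2)
    dev = (errs["recomputed_error"] - errs["error"]).abs()
    checks["prediction_errors"] = {
        "passed": bool((dev <= tol).all()), "max_abs_dev": float(dev.max())}

    from .regression import model_scale_r2
    printed_r2 = {"HCT116": 0.934, "MCF7": 0.951, "A431": 0.901}
    r2_out = {}
    ok = True
    for cl, scale in DEFAULT_SCALES.items():
        rows = t2[t2["cell_line"] == cl]
        r2 = model_scale_r2(rows["observed_ic50"], rows["estimated_ic50"], scale)
        r2_out[cl] = r2
        ok &= abs(r2 - printed_r2[cl]) <= 0.01
    checks["model_r2"] = {"passed": ok, "recomputed": r2_out, "printed": printed_r2}

    t3 = compounds_mod.load_pharmacophore_fits()
    ok = True
    cal_out = {}
    for cl in DEFAULT_SCALES:
        cal = calibrate_from_table(t3, cl)
        cal_out[cl] = {"constant_c": cal.constant_c, "sd": cal.sd}
        ok &= cal.sd < 0.01
        rows = t3[t3["cell_line"] == cl]
        pred = [estimate_activity(f, cal.constant_c) for f in rows["fit_value"]]
        ok &= bool(np.max(np.abs(np.asarray(pred) - rows["estimated_ic50"].to_numpy()))
                   <= 0.02)
    checks["pharmacophore_calibration"] = {"passed": ok, "calibration": cal_out}

    checks["all_passed"] = {"passed": all(c.get("passed", False) for c in checks.values())}
    return checks
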