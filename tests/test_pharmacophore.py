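"""Pharmacophore features, fit-value scoring and activity calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dienoneqsar.compounds import load_pharmacophore_fits
from dienoneqsar.descriptors import BONDI_RADII, Conformer3D
from dienoneqsar.pharmacophore import (
    Feature,
    FeatureMapping,
    HYPOTHESIS_INVENTORY,
    PharmacophoreHypothesis,
    calibrate_activity_constant,
    calibrate_from_table,
    detect_features,
    estimate_activity,
    example_hypothesis,
    fit_value,
    map_features,
)

CELL_LINES = ("HCT116", "MCF7", "A431")


def conformer_for(record):
    from dienoneqsar.descriptors.profile import conformer_for_record

    return conformer_for_record(record)


def test_compound_24_has_two_acceptor_oxygens(records_by_id):
    rec = records_by_id[24]
    feats = detect_features(rec, conformer_for(rec))
    hba = [f for f in feats if f[0] == "HBA"]
    assert len(hba) == 2  # ketonic + amidic carbonyl oxygens


def test_compound_26_gains_methoxy_acceptor(records_by_id):
    rec = records_by_id[26]
    feats = detect_features(rec, conformer_for(rec))
    assert len([f for f in feats if f[0] == "HBA"]) == 3


def test_benzene_single_hydrophobic_feature():
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1"))
    params = AllChem.ETKDGv3()
    params.randomSeed = 5
    AllChem.EmbedMolecule(mol, params)
    pos = np.asarray(mol.GetConformer().GetPositions())
    radii = np.array([BONDI_RADII[a.GetSymbol()] for a in mol.GetAtoms()])
    conf = Conformer3D(pos, radii, tuple(a.GetSymbol() for a in mol.GetAtoms()))
    feats = detect_features(Chem.MolFromSmiles("c1ccccc1"), conf)
    assert [f[0] for f in feats] == ["hydrophobic"]


def test_fit_value_cases():
    f1 = Feature("HBA", (0, 0, 0), tolerance=2.0, weight=1.0)
    f2 = Feature("hydrophobic", (5, 0, 0), tolerance=2.0, weight=1.0)
    f3 = Feature("hydrophobic", (0, 5, 0), tolerance=2.0, weight=1.0)
    f4 = Feature("hydrophobic", (0, 0, 5), tolerance=2.0, weight=1.0)
    hyp = PharmacophoreHypothesis([f1, f2, f3, f4])
    perfect = FeatureMapping([(f, f.centroid) for f in hyp.features])
    assert fit_value(hyp, perfect) == pytest.approx(4.0)
    assert fit_value(hyp, FeatureMapping([])) == 0.0
    w2 = Feature("HBA", (0, 0, 0), tolerance=2.0, weight=2.0)
    half = FeatureMapping([(w2, (1.0, 0, 0))])  # displacement = tol / 2
    assert fit_value(PharmacophoreHypothesis([w2]), half) == pytest.approx(1.5)


def test_fit_value_rejects_out_of_tolerance_and_double_mapping():
    f = Feature("HBA", (0, 0, 0), tolerance=1.0)
    hyp = PharmacophoreHypothesis([f])
    with pytest.raises(ValueError, match="tolerance"):
        fit_value(hyp, FeatureMapping([(f, (1.5, 0, 0))]))
    with pytest.raises(ValueError, match="more than once"):
        fit_value(hyp, FeatureMapping([(f, (0.1, 0, 0)), (f, (0.2, 0, 0))]))


@settings(max_examples=50, deadline=None)
@given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
def test_fit_value_monotone_in_displacement(d1, d2):
    lo, hi = sorted((d1, d2))
    f = Feature("HBA", (0.0, 0.0, 0.0), tolerance=1.0, weight=1.3)
    hyp = PharmacophoreHypothesis([f])
    v_lo = fit_value(hyp, FeatureMapping([(f, (lo, 0.0, 0.0))]))
    v_hi = fit_value(hyp, FeatureMapping([(f, (hi, 0.0, 0.0))]))
    assert v_lo >= v_hi - 1e-12


def test_calibration_compound_42_row():
    cal = calibrate_activity_constant([(5.824, 11.50)])
    assert cal.constant_c == pytest.approx(5.824 + math.log10(11.50), abs=1e-12)
    assert cal.constant_c == pytest.approx(6.885, abs=0.005)


def test_calibration_single_row_unit_ic50():
    cal = calibrate_activity_constant([(4.321, 1.0)])
    assert cal.constant_c == pytest.approx(4.321)
    assert cal.sd == 0.0
    with pytest.raises(ValueError):
        calibrate_activity_constant([(4.0, -1.0)])
    with pytest.raises(ValueError):
        calibrate_activity_constant([])


@pytest.mark.parametrize("cell_line", CELL_LINES)
def test_published_rows_share_one_constant(cell_line):
    """fit + log10(estimated IC50) is constant across all 24 published rows
    of each cell line (SD < 0.01): the log-linear relation holds."""
    fits = load_pharmacophore_fits()
    cal = calibrate_from_table(fits, cell_line)
    assert cal.n == 24
    assert cal.sd < 0.01
    rows = fits[fits["cell_line"] == cell_line]
    per_row = rows["fit_value"] + np.log10(rows["estimated_ic50"])
    assert np.max(np.abs(per_row - cal.constant_c)) <= 0.01


def test_cross_row_predictions():
    fits = load_pharmacophore_fits()
    h = fits[fits["cell_line"] == "HCT116"].set_index("compound_id")
    c_from_42 = 5.824 + math.log10(11.50)
    assert estimate_activity(6.951, c_from_42) == pytest.approx(0.86, abs=0.01)
    m = fits[fits["cell_line"] == "MCF7"].set_index("compound_id")
    c_from_24 = float(m.loc[24, "fit_value"]) + math.log10(float(m.loc[24, "estimated_ic50"]))
    assert estimate_activity(5.929, c_from_24) == pytest.approx(3.10, abs=0.02)
    assert estimate_activity(6.0, 6.0) == pytest.approx(1.0)


@pytest.mark.parametrize("cell_line", CELL_LINES)
def test_calibrate_then_estimate_round_trip(cell_line):
    fits = load_pharmacophore_fits()
    cal = calibrate_from_table(fits, cell_line)
    rows = fits[fits["cell_line"] == cell_line]
    pred = np.array([estimate_activity(f, cal.constant_c)
                     for f in rows["fit_value"]])
    assert np.max(np.abs(pred - rows["estimated_ic50"].to_numpy())) <= 0.02


def test_example_hypotheses_match_inventories():
    for cl, inventory in HYPOTHESIS_INVENTORY.items():
        hyp = example_hypothesis(cl)
        assert hyp.inventory() == inventory


def test_hypothesis_json_round_trip(tmp_path):
    hyp = example_hypothesis("A431", constant_c=7.605)
    path = tmp_path / "hyp.json"
    hyp.to_json(path)
    back = PharmacophoreHypothesis.from_json(path)
    assert back.constant_c == hyp.constant_c
    assert back.inventory() == hyp.inventory()
    assert [f.centroid for f in back.features] == [f.centroid for f in hyp.features]


def test_map_features_respects_kind_and_tolerance():
    hyp = PharmacophoreHypothesis([
        Feature("HBA", (0, 0, 0), tolerance=1.0),
        Feature("hydrophobic", (5, 0, 0), tolerance=1.0),
    ])
    feats = [("HBA", (0.5, 0, 0)), ("hydrophobic", (9, 9, 9)),
             ("hydrophobic", (5.2, 0, 0))]
    mapping = map_features(hyp, feats)
    assert len(mapping.pairs) == 2
    assert all(d <= 1.0 for d in mapping.displacements())
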