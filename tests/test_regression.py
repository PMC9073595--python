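"""MLR fitting, BMLR subset search and cross-validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dienoneqsar.regression import (
    CensoredActivityError,
    RankDeficiencyError,
    ResponseVector,
    bmlr_search,
    fit_mlr,
    lmo_cv,
    loo_cv,
    loo_cv_refit,
    model_scale_r2,
    scale_activity,
    transform_scale,
)
from dienoneqsar.synth import SyntheticSpec, gen_linear_dataset


def rv(values, scale="log_inverse_ic50"):
    return ResponseVector(tuple(range(len(values))), np.asarray(values, float), scale)


def test_exact_linear_fit_recovers_line():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    X = pd.DataFrame({"x": x})
    m = fit_mlr(X, rv(1.0 + 2.0 * x), ["x"])
    assert m.intercept == pytest.approx(1.0, abs=1e-10)
    assert m.terms[0][1] == pytest.approx(2.0, abs=1e-10)
    assert m.r2 == pytest.approx(1.0, abs=1e-12)
    assert m.s2 == pytest.approx(0.0, abs=1e-18)


def test_five_point_fit_matches_normal_equations():
    X = pd.DataFrame({"a": [0.2, 1.1, -0.7, 2.2, 0.4],
                      "b": [1.0, -0.3, 0.8, 0.1, -1.2]})
    y = np.array([0.7, 2.4, -1.1, 3.9, 1.0])
    m = fit_mlr(X, rv(y), ["a", "b"])
    design = np.column_stack([np.ones(5), X["a"], X["b"]])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    assert m.intercept == pytest.approx(beta[0], abs=1e-10)
    assert m.terms[0][1] == pytest.approx(beta[1], abs=1e-10)
    assert m.terms[1][1] == pytest.approx(beta[2], abs=1e-10)
    # |t| = |coef / stderr|
    for _, coef, se, t in m.terms:
        assert abs(t) == pytest.approx(abs(coef / se), abs=1e-10)


def test_constant_response_flagged():
    X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
    m = fit_mlr(X, rv([2.0, 2.0, 2.0, 2.0]), ["x"])
    assert m.degenerate
    assert m.r2 == 0.0


def test_rank_deficiency_names_columns():
    x = np.arange(6.0)
    X = pd.DataFrame({"a": x, "b": 2 * x})
    with pytest.raises(RankDeficiencyError) as exc:
        fit_mlr(X, rv(x + 1), ["a", "b"])
    assert set(exc.value.columns) & {"a", "b"}


def test_ols_identity_corr_equals_r2():
    """corr(fitted, observed)^2 == 1 - SSE/SST to 1e-10."""
    X, y, _ = gen_linear_dataset(SyntheticSpec(seed=3))
    m = fit_mlr(X, y, ["d00", "d01", "d02"])
    fitted = m.predict(X)
    corr2 = float(np.corrcoef(fitted, y.values)[0, 1] ** 2)
    sse = float(np.sum((y.values - fitted) ** 2))
    sst = float(np.sum((y.values - y.values.mean()) ** 2))
    assert corr2 == pytest.approx(1.0 - sse / sst, abs=1e-10)
    assert m.r2 == pytest.approx(corr2, abs=1e-10)


def test_loo_hat_matrix_equals_explicit_refits():
    X, y, _ = gen_linear_dataset(SyntheticSpec(seed=9))
    terms = ["d00", "d01", "d02"]
    assert loo_cv(X, y, terms) == pytest.approx(
        loo_cv_refit(X, y, terms), abs=1e-10)


def test_loo_on_exact_data_is_one():
    X, y, _ = gen_linear_dataset(SyntheticSpec(seed=2, noise_sd=0.0))
    assert loo_cv(X, y, ["d00", "d01", "d02"]) == pytest.approx(1.0, abs=1e-10)


def test_loo_less_than_training_r2():
    """Optimism: cross-validated R^2 never exceeds the training R^2."""
    for seed in (1, 5, 11, 23):
        X, y, _ = gen_linear_dataset(SyntheticSpec(seed=seed, noise_sd=1.5))
        terms = ["d00", "d01", "d02"]
        m = fit_mlr(X, y, terms)
        assert loo_cv(X, y, terms) <= m.r2 + 1e-12


def test_loo_needs_enough_rows():
    X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
    with pytest.raises(ValueError):
        loo_cv(X, rv([0.0, 1.1, 1.9]), ["x"])


def test_lmo_exhaustive_leave_one_limit():
    """Leave-fraction 1/n with every partition visited reduces to LOO."""
    spec = SyntheticSpec(n_compounds=12, n_descriptors=4,
                        true_terms=((0, 1.5),), seed=21, noise_sd=0.5)
    X, y, _ = gen_linear_dataset(spec)
    n = len(y)
    # replay lmo accumulation deterministically over all n singleton holdouts
    sse = sst = 0.0
    ybar = y.values.mean()
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        Xi, yi = X.iloc[keep], rv(y.values[keep])
        m = fit_mlr(Xi, yi, ["d00"])
        sse += float((y.values[i] - m.predict(X.iloc[[i]])[0]) ** 2)
        sst += float((y.values[i] - ybar) ** 2)
    assert 1.0 - sse / sst == pytest.approx(loo_cv(X, y, ["d00"]), abs=1e-10)


def test_lmo_exact_data_and_determinism():
    X, y, _ = gen_linear_dataset(SyntheticSpec(seed=4, noise_sd=0.0))
    terms = ["d00", "d01", "d02"]
    assert lmo_cv(X, y, terms, repeats=20, seed=77) == pytest.approx(1.0, abs=1e-10)
    X2, y2, _ = gen_linear_dataset(SyntheticSpec(seed=4))
    a = lmo_cv(X2, y2, terms, repeats=30, seed=123)
    b = lmo_cv(X2, y2, terms, repeats=30, seed=123)
    assert a == b  # bit-identical under a fixed seed
    with pytest.raises(ValueError):
        lmo_cv(X2, y2, terms, leave_fraction=0.7)


def test_bmlr_recovers_planted_signal():
    X, y, truth = gen_linear_dataset(SyntheticSpec(seed=20191021))
    top = bmlr_search(X, y, k=3)[0]
    assert set(truth["terms"]) <= set(top.descriptor_names)


def test_bmlr_k1_equals_brute_force():
    X, y, _ = gen_linear_dataset(SyntheticSpec(seed=6))
    best = bmlr_search(X, y, k=1)[0]
    brute = max((fit_mlr(X, y, [c]) for c in X.columns), key=lambda m: m.r2)
    assert best.descriptor_names == brute.descriptor_names
    assert best.r2 == pytest.approx(brute.r2, abs=1e-12)


def test_bmlr_exhaustive_equals_brute_force_subsets():
    spec = SyntheticSpec(n_compounds=20, n_descriptors=8, seed=13)
    X, y, _ = gen_linear_dataset(spec)
    best = bmlr_search(X, y, k=3, exhaustive=True)[0]
    subsets = [s for size in (1, 2, 3)
               for s in itertools.combinations(X.columns, size)]
    admissible = [s for s in subsets
                  if all(abs(X[list(s)].corr().iloc[i, j]) <= 0.8
                         for i in range(len(s)) for j in range(i + 1, len(s)))]
    brute = max((fit_mlr(X, y, list(s)) for s in admissible), key=lambda m: m.r2)
    assert set(best.descriptor_names) == set(brute.descriptor_names)
    assert best.r2 == pytest.approx(brute.r2, abs=1e-10)


def test_bmlr_collinear_duplicates_never_coselected():
    X, y, _ = gen_linear_dataset(SyntheticSpec(n_descriptors=5, seed=8))
    X = X.copy()
    X["dup"] = X["d00"]
    for m in bmlr_search(X, y, k=3, collinearity_max=0.0):
        names = m.descriptor_names
        assert not ("d00" in names and "dup" in names)


def test_bmlr_empty_pool_rejected():
    X = pd.DataFrame({"flat": np.zeros(10)})
    with pytest.raises(ValueError, match="empty"):
        bmlr_search(X, rv(np.arange(10.0)), k=1)


def test_coefficient_recovery_within_three_se():
    """On y = X beta + noise at R^2 ~ 0.9 (n=24, k=3), the fitted
    coefficients land within 3 standard errors of truth in >= 95% of
    200 seeded replicates."""
    hits = total = 0
    for seed in range(200):
        X, y, truth = gen_linear_dataset(SyntheticSpec(seed=seed))
        m = fit_mlr(X, y, list(truth["terms"]))
        ok = all(abs(coef - truth["terms"][name]) <= 3 * se
                 for name, coef, se, _ in m.terms)
        hits += ok
        total += 1
    assert hits / total >= 0.95


# --- activity scaling -------------------------------------------------------

def test_scale_activity_inverse(activity_table):
    y = scale_activity(activity_table, "inverse_ic50", "HCT116",
                       compound_ids=[24])
    assert y.values[0] == pytest.approx(1 / 1.08)
    y2 = scale_activity(activity_table, "ic50", "HCT116", compound_ids=[24])
    assert y2.values[0] == 1.08  # identity on the native scale


def test_scale_activity_rejects_censored(activity_table):
    with pytest.raises(CensoredActivityError) as exc:
        scale_activity(activity_table, "inverse_ic50", "HCT116",
                       compound_ids=[24, 48])
    assert "48" in map(str, exc.value.ids)


def test_transform_scale_simple():
    assert transform_scale(np.array([2.0]), "inverse_ic50")[0] == 0.5
    assert transform_scale(np.array([10.0]), "log_inverse_ic50")[0] == -1.0


def test_model_scale_r2_identity_and_errors():
    obs = np.array([1.0, 2.0, 3.0])
    assert model_scale_r2(obs, obs, "ic50") == pytest.approx(1.0)
    with pytest.raises(ValueError):
        model_scale_r2(obs, np.array([1.0, 1.0, 1.0]), "ic50")
    with pytest.raises(ValueError):
        model_scale_r2(obs[:2], obs[:2], "ic50")
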