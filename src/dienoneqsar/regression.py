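"""Best-multilinear-regression (BMLR) QSAR model building and validation.

A QSAR model here is an intercept plus k descriptor terms fitted by ordinary
least squares to an activity response (IC50, 1/IC50 or log 1/IC50).  The
BMLR search ranks single descriptors, forms low-collinearity pairs from the
best of them, and extends the best pairs by one more descriptor -- the
classical heuristic for picking a small, non-collinear subset.  Internal
validation uses leave-one-out (PRESS via the hat matrix) and repeated
leave-many-out cross-validation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

RESPONSE_SCALES = ("ic50", "inverse_ic50", "log_inverse_ic50")


class RankDeficiencyError(ValueError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear/rank-deficient descriptor columns: {self.columns}")


@dataclass
class ResponseVector:
    compound_ids: tuple
    values: np.ndarray
    scale: str = "ic50"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in RESPONSE_SCALES:
            raise ValueError(f"unknown response scale {self.scale!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite response values")
        if self.scale in ("ic50", "inverse_ic50") and (self.values <= 0).any():
            raise ValueError(f"non-positive values on scale {self.scale}")

    def __len__(self):
        return len(self.values)


@dataclass
class MLRModel:
    intercept: float
    terms: list  # (descriptor name, coefficient, standard error, t-criterion)
    r2: float
    f: float
    s2: float
    n: int
    scale: str
    intercept_se: float = float("nan")
    degenerate: bool = False  # constant response: slope t-criteria undefined

    @property
    def descriptor_names(self) -> tuple:
        return tuple(t[0] for t in self.terms)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        y = np.full(len(X), self.intercept)
        for name, coef, _, _ in self.terms:
            y = y + coef * np.asarray(X[name], dtype=float)
        return y

    def report(self) -> dict:
        return {
            "scale": self.scale,
            "n": self.n,
            "intercept": self.intercept,
            "terms": [
                {"descriptor": d, "coefficient": c, "stderr": se, "t": t}
                for d, c, se, t in self.terms
            ],
            "r2": self.r2,
            "f": self.f,
            "s2": self.s2,
        }


@dataclass
class CVResult:
    r2cv_loo: float
    r2cv_lmo: float
    partitions: int
    seed: int


def _design(X: pd.DataFrame, terms) -> np.ndarray:
    terms = list(terms)
    missing = [t for t in terms if t not in X.columns]
    if missing:
        raise KeyError(f"descriptors not in matrix: {missing}")
    return np.asarray(X[terms], dtype=float)


def _align(X: pd.DataFrame, y: ResponseVector) -> pd.DataFrame:
    if len(X) != len(y):
        raise ValueError("descriptor matrix and response length differ")
    return X


def fit_mlr(X: pd.DataFrame, y: ResponseVector, terms) -> MLRModel:
    """OLS fit of y on an intercept plus the named descriptor columns."""
    terms = list(terms)
    _align(X, y)
    n, k = len(y), len(terms)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} rows to fit {k} terms, got {n}")
    M = _design(X, terms)
    design = sm.add_constant(M, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [t for i, t in enumerate(terms)
               if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1))
               == np.linalg.matrix_rank(design)]
        raise RankDeficiencyError(bad or terms)
    degenerate = bool(np.allclose(y.values, y.values[0]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y.values, design).fit()
    r2 = 0.0 if degenerate else float(res.rsquared)
    s2 = float(res.ssr / res.df_resid) if res.df_resid > 0 else 0.0
    fstat = float(res.fvalue) if np.isfinite(res.fvalue) else float("inf")
    model_terms = [
        (t, float(res.params[i + 1]), float(res.bse[i + 1]), float(res.tvalues[i + 1]))
        for i, t in enumerate(terms)
    ]
    return MLRModel(
        intercept=float(res.params[0]),
        terms=model_terms,
        r2=max(0.0, min(1.0, r2)),
        f=0.0 if degenerate else fstat,
        s2=s2,
        n=n,
        scale=y.scale,
        intercept_se=float(res.bse[0]),
        degenerate=degenerate,
    )


def bmlr_search(
    X: pd.DataFrame,
    y: ResponseVector,
    k: int = 3,
    collinearity_max: float = 0.8,
    beam: int = 10,
    exhaustive: bool = False,
) -> list[MLRModel]:
    """Heuristic best-subset search for a k-descriptor model.

    Stage 1 ranks single descriptors by R^2; stage 2 pairs the top `beam`,
    discarding pairs with |pairwise correlation| > collinearity_max; further
    stages extend the best subsets by one descriptor.  With exhaustive=True
    every admissible subset of size <= k is scored (testing oracle for small
    pools).  Returns models sorted by decreasing R^2.
    """
    pool = [c for c in X.columns if np.asarray(X[c]).std() > 0]
    if not pool:
        raise ValueError("empty descriptor pool")
    if k < 1:
        raise ValueError("k must be >= 1")
    corr = X[pool].corr().abs()
    cols = {c: np.asarray(X[c], dtype=float) for c in pool}
    yv = y.values
    sst = float(np.sum((yv - yv.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero response variance")
    ones = np.ones(len(yv))

    def admissible(subset) -> bool:
        return all(corr.loc[a, b] <= collinearity_max
                   for a, b in itertools.combinations(subset, 2))

    def fast_r2(subset) -> float | None:
        """R^2 by one least-squares solve; None when rank deficient."""
        design = np.column_stack([ones] + [cols[c] for c in subset])
        sol, res, rank, _ = np.linalg.lstsq(design, yv, rcond=None)
        if rank < design.shape[1]:
            return None
        sse = float(res[0]) if res.size else float(np.sum((yv - design @ sol) ** 2))
        return 1.0 - sse / sst

    scored: dict[tuple, float] = {}
    if exhaustive:
        for size in range(1, min(k, len(pool)) + 1):
            for subset in itertools.combinations(pool, size):
                if admissible(subset):
                    r2 = fast_r2(subset)
                    if r2 is not None:
                        scored[tuple(sorted(subset))] = r2
    else:
        singles = [((c,), fast_r2((c,))) for c in pool]
        singles = [(s, r) for s, r in singles if r is not None]
        singles.sort(key=lambda sr: -sr[1])
        scored.update(dict(singles))
        frontier = [s for s, _ in singles[:beam]]
        for _size in range(2, min(k, len(pool)) + 1):
            candidates: dict[tuple, float] = {}
            for subset in frontier:
                for c in pool:
                    if c in subset:
                        continue
                    new = tuple(sorted(subset + (c,)))
                    if new in scored or new in candidates or not admissible(new):
                        continue
                    r2 = fast_r2(new)
                    if r2 is not None:
                        candidates[new] = r2
            scored.update(candidates)
            frontier = sorted(candidates, key=lambda s: -candidates[s])[:beam]
            if not frontier:
                break
    ranked = sorted(scored, key=lambda s: -scored[s])
    # full OLS statistics for the leading subsets only (the returned surface)
    top = ranked[: max(beam, 25)]
    return [fit_mlr(X, y, list(s)) for s in top]


def loo_cv(X: pd.DataFrame, y: ResponseVector, terms) -> float:
    """Leave-one-out cross-validated R^2 = 1 - PRESS/SST (hat-matrix identity)."""
    terms = list(terms)
    n = len(y)
    if n <= len(terms) + 2:
        raise ValueError("too few rows for leave-one-out validation")
    model = fit_mlr(X, y, terms)
    design = sm.add_constant(_design(X, terms), has_constant="add")
    hat = design @ np.linalg.solve(design.T @ design, design.T)
    resid = y.values - model.predict(X)
    press = float(np.sum((resid / (1.0 - np.diag(hat))) ** 2))
    sst = float(np.sum((y.values - y.values.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero response variance")
    return 1.0 - press / sst


def loo_cv_refit(X: pd.DataFrame, y: ResponseVector, terms) -> float:
    """Leave-one-out by n explicit refits (independent check of loo_cv)."""
    terms = list(terms)
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        Xi = X.iloc[keep]
        yi = ResponseVector(tuple(np.asarray(y.compound_ids)[keep]),
                            y.values[keep], y.scale)
        m = fit_mlr(Xi, yi, terms)
        press += float((y.values[i] - m.predict(X.iloc[[i]])[0]) ** 2)
    sst = float(np.sum((y.values - y.values.mean()) ** 2))
    return 1.0 - press / sst


def lmo_cv(
    X: pd.DataFrame,
    y: ResponseVector,
    terms,
    leave_fraction: float = 1.0 / 3.0,
    repeats: int = 100,
    seed: int = 20191021,
) -> float:
    """Repeated leave-many-out cross-validated R^2.

    Each repeat holds out round(leave_fraction * n) rows, fits on the rest and
    accumulates held-out squared errors; the result pools errors over repeats:
    1 - sum(SSE_held) / sum(SST_held), with SST taken about the full-sample
    mean so that the exhaustive leave-one-out limit equals loo_cv_refit.
    """
    if not 0 < leave_fraction < 0.5:
        raise ValueError("leave_fraction must lie in (0, 0.5)")
    terms = list(terms)
    n = len(y)
    n_out = max(1, int(round(leave_fraction * n)))
    if n - n_out < len(terms) + 2:
        raise ValueError("training group too small to fit")
    rng = np.random.default_rng(seed)
    ybar = y.values.mean()
    sse = sst = 0.0
    for _ in range(repeats):
        held = rng.choice(n, size=n_out, replace=False)
        keep = np.setdiff1d(np.arange(n), held)
        Xi = X.iloc[keep]
        yi = ResponseVector(tuple(np.asarray(y.compound_ids)[keep]),
                            y.values[keep], y.scale)
        m = fit_mlr(Xi, yi, terms)
        pred = m.predict(X.iloc[held])
        sse += float(np.sum((y.values[held] - pred) ** 2))
        sst += float(np.sum((y.values[held] - ybar) ** 2))
    if sst == 0:
        raise ValueError("zero held-out response variance")
    return 1.0 - sse / sst


def cross_validate(X, y, terms, leave_fraction=1.0 / 3.0, repeats=100,
                   seed=20191021) -> CVResult:
    return CVResult(
        r2cv_loo=loo_cv(X, y, terms),
        r2cv_lmo=lmo_cv(X, y, terms, leave_fraction, repeats, seed),
        partitions=repeats,
        seed=seed,
    )


class CensoredActivityError(ValueError):
    def __init__(self, ids):
        self.ids = list(ids)
        super().__init__(f"censored IC50 entries for compounds: {self.ids}")


def transform_scale(values: np.ndarray, scale: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if scale == "ic50":
        return values
    if scale == "inverse_ic50":
        return 1.0 / values
    if scale == "log_inverse_ic50":
        return np.log10(1.0 / values)
    raise ValueError(f"unknown response scale {scale!r}")


def scale_activity(
    table: pd.DataFrame,
    scale: str,
    assay: str,
    compound_ids=None,
) -> ResponseVector:
    """Extract one assay's IC50 values as a ResponseVector on the given scale.

    Censored entries are never admitted into a fit: requesting one raises
    :class:`CensoredActivityError` listing the offending compound ids.
    """
    rows = table[(table["assay"] == assay) & (table.get("is_reference", 0) == 0)]
    if compound_ids is not None:
        wanted = [str(c) for c in compound_ids]
        rows = rows.set_index(rows["compound_id"].astype(str)).loc[wanted]
    censored = rows[rows["censor"] != "exact"]
    if len(censored):
        raise CensoredActivityError(censored["compound_id"].tolist())
    ids = tuple(rows["compound_id"].tolist())
    return ResponseVector(ids, transform_scale(rows["ic50_um"].to_numpy(), scale), scale)


def model_scale_r2(observed, estimated, scale: str) -> float:
    """Squared Pearson correlation of observed vs estimated on a given scale."""
    obs = transform_scale(np.asarray(observed, dtype=float), scale)
    est = transform_scale(np.asarray(estimated, dtype=float), scale)
    if len(obs) != len(est):
        raise ValueError("length mismatch")
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs")
    if obs.std() == 0 or est.std() == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(obs, est)[0, 1] ** 2)
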