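"""Group-level models linking per-subject WM features to cortical thickness.

Per subject the features are either the gamma-mixture reduction
``(m1, m2, lam)`` or the classical lesion-mask summaries (mean lesion MWF,
mean NAWM MWF), plus demographic covariates (age, gender, disease duration
``dd``, treatment duration ``dmt``).  The analysis:

* exhaustively searches all predictor subsets (intercept-only included) and
  selects the one minimizing 10-fold cross-validated MSE, with one seeded
  subject-level fold assignment shared across subsets so the CV errors are
  comparable;
* compares the two predictor families by the adjusted R² of their selected
  models;
* decomposes the selected model's R² into per-predictor LMG relative
  importances (average R² gain of a predictor over all orderings in which
  it can enter the model);
* interprets coefficients as the all-else-equal predictor change associated
  with a fixed cortical-thickness change (0.05 mm by default);
* compares groups with Welch two-sample t-tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

__all__ = [
    "CollinearityError",
    "RegressionModel",
    "ImportanceTable",
    "WelchResult",
    "ExhaustiveSubsetCV",
    "fit_ols",
    "exhaustive_cv_select",
    "lmg_importance",
    "welch_t",
    "delta_for_thickness_change",
    "compare_predictor_sets",
    "PredictorSetComparison",
    "round_sig",
]


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


# --------------------------------------------------------------------------
# design-matrix plumbing
# --------------------------------------------------------------------------


def _encode_column(col: pd.Series) -> np.ndarray:
    """Numeric columns pass through; binary categories become a 0/1 indicator."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    levels = sorted(pd.unique(col.astype(str)))
    if len(levels) > 2:
        raise ValueError(f"column {col.name!r} has {len(levels)} categories; "
                         "only binary categories are supported")
    mapping = {lev: float(i) for i, lev in enumerate(levels)}
    return col.astype(str).map(mapping).to_numpy(dtype=float)


def _design(table: pd.DataFrame, predictors) -> np.ndarray:
    """Stack encoded predictor columns after an intercept column of ones."""
    n = len(table)
    cols = [np.ones(n)]
    for name in predictors:
        if name not in table.columns:
            raise KeyError(f"unknown predictor {name!r}")
        col = table[name]
        if col.isna().any():
            raise ValueError(f"predictor {name!r} contains missing values")
        cols.append(_encode_column(col))
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    offending = []
    for j, name in enumerate(names):
        reduced = np.delete(X, j + 1, axis=1)  # column 0 is the intercept
        if np.linalg.matrix_rank(reduced) == rank:
            offending.append(name)
    raise CollinearityError(f"design matrix is rank deficient; "
                            f"linearly dependent columns: {offending or list(names)}")


def _r2_from_fit(y: np.ndarray, fitted: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0
    return 1.0 - float(np.sum((y - fitted) ** 2)) / sst


def adjusted_r2(r2: float, n: int, n_predictors: int) -> float:
    """``1 - (1 - R²)(n - 1) / (n - p - 1)``."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


# --------------------------------------------------------------------------
# OLS
# --------------------------------------------------------------------------


@dataclass
class RegressionModel:
    """A fitted linear model on a predictor subset."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]  # includes "intercept"
    r2: float
    adjusted_r2: float
    n: int
    response: str
    p_values: dict[str, float] | None = None
    std_errors: dict[str, float] | None = None
    cv_mse: float | None = None

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = _design(table, self.predictors)
        beta = np.array([self.coefficients["intercept"]] +
                        [self.coefficients[p] for p in self.predictors])
        return X @ beta

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "coefficients": self.coefficients,
            "p_values": self.p_values,
            "std_errors": self.std_errors,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "cv_mse": self.cv_mse,
            "n": self.n,
        }


def fit_ols(table: pd.DataFrame, predictors, response: str,
            cv_mse: float | None = None) -> RegressionModel:
    """Ordinary least squares of ``response`` on a predictor subset.

    Raises :class:`CollinearityError` (naming the dependent columns) on a
    rank-deficient design.  A constant response yields R² = 0 with all
    slopes 0.
    """
    predictors = tuple(predictors)
    n = len(table)
    if n <= len(predictors) + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={len(predictors)}")
    y = table[response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    X = _design(table, predictors)
    _check_rank(X, predictors)
    res = sm.OLS(y, X).fit()
    names = ("intercept",) + predictors
    r2 = _r2_from_fit(y, res.fittedvalues)
    return RegressionModel(
        predictors=predictors,
        coefficients={name: float(b) for name, b in zip(names, res.params)},
        p_values={name: float(p) for name, p in zip(names, res.pvalues)},
        std_errors={name: float(s) for name, s in zip(names, res.bse)},
        r2=r2,
        adjusted_r2=adjusted_r2(r2, n, len(predictors)),
        n=n,
        response=response,
        cv_mse=cv_mse,
    )


# --------------------------------------------------------------------------
# exhaustive best-subset search with shared-fold cross-validation
# --------------------------------------------------------------------------


class ExhaustiveSubsetCV(BaseEstimator, RegressorMixin):
    """Best-subset linear regression scored by k-fold cross-validation.

    All ``2^p`` subsets of the columns of ``X`` (including the intercept-only
    model) are scored by k-fold CV mean squared error.  Subjects are shuffled
    once with ``random_state`` and the same folds are reused for every
    subset, so the CV errors are directly comparable.  Ties are broken by
    fewer predictors, then lexicographic column-name order.  The winning
    subset is refitted on all data.

    Fitted attributes: ``subset_`` (tuple of winning column names),
    ``model_`` (:class:`RegressionModel` refit on all data, with ``cv_mse``),
    ``ranking_`` (DataFrame of every subset's CV MSE, best first),
    ``coef_`` / ``intercept_``.
    """

    def __init__(self, cv: int = 10, random_state=None):
        self.cv = cv
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame of candidate predictor columns")
        names = list(X.columns)
        y = np.asarray(y, dtype=float)
        n = len(X)
        if self.cv > n:
            raise ValueError(f"cv={self.cv} folds exceed n={n} subjects")
        if not names:
            raise ValueError("candidate predictor set is empty")
        full = _design(X, names)
        _check_rank(full, names)
        col_of = {name: j + 1 for j, name in enumerate(names)}

        folds = list(KFold(n_splits=self.cv, shuffle=True,
                           random_state=self.random_state).split(np.arange(n)))

        rows = []
        for size in range(len(names) + 1):
            for subset in itertools.combinations(names, size):
                idx = [0] + [col_of[p] for p in subset]
                Xs = full[:, idx]
                sq_err = 0.0
                for train, test in folds:
                    beta, *_ = np.linalg.lstsq(Xs[train], y[train], rcond=None)
                    resid = y[test] - Xs[test] @ beta
                    sq_err += float(resid @ resid)
                rows.append((subset, sq_err / n))
        rows.sort(key=lambda r: (r[1], len(r[0]), r[0]))

        table = X.copy()
        table["__response__"] = y
        best_subset, best_mse = rows[0]
        self.subset_ = best_subset
        self.model_ = fit_ols(table, best_subset, "__response__", cv_mse=best_mse)
        self.cv_mse_ = best_mse
        self.intercept_ = self.model_.coefficients["intercept"]
        self.coef_ = np.array([self.model_.coefficients[p] for p in best_subset])
        self.ranking_ = pd.DataFrame(
            {"subset": [r[0] for r in rows],
             "size": [len(r[0]) for r in rows],
             "cv_mse": [r[1] for r in rows]})
        return self

    def predict(self, X: pd.DataFrame):
        return _design(X, self.subset_) @ np.concatenate([[self.intercept_], self.coef_])


def exhaustive_cv_select(table: pd.DataFrame, candidates, response: str,
                         k: int = 10, seed=None) -> tuple[RegressionModel, pd.DataFrame]:
    """Best predictor subset by exhaustive search with shared k-fold CV.

    Returns the winning model (refit on all data, ``response`` name
    restored) and the full subset ranking.
    """
    candidates = list(candidates)
    est = ExhaustiveSubsetCV(cv=k, random_state=seed).fit(
        table[candidates], table[response].to_numpy(dtype=float))
    best = fit_ols(table, est.subset_, response, cv_mse=est.cv_mse_)
    return best, est.ranking_


# --------------------------------------------------------------------------
# LMG relative importance
# --------------------------------------------------------------------------


@dataclass
class ImportanceTable:
    """LMG decomposition of a model's R² into per-predictor shares."""

    shares: dict[str, float]       # sum to the full model's R²
    relative: dict[str, float]     # normalized to sum 1
    r2: float


def lmg_importance(table: pd.DataFrame, predictors, response: str) -> ImportanceTable:
    """Average sequential R² gain of each predictor over all entry orders.

    For predictor ``j`` the share is the mean, over all orderings of the
    predictors, of the R² increase when ``j`` enters after the predictors
    preceding it; equivalently a weighted average over subsets ``S`` not
    containing ``j`` with weights ``|S|! (p - 1 - |S|)! / p!``.  The shares
    are nonnegative for a least-squares fit and sum exactly to the full
    model's R².
    """
    predictors = list(predictors)
    p = len(predictors)
    if p == 0:
        raise ValueError("need at least one predictor")
    if p > 10:
        raise ValueError("LMG averaging over subsets is limited to 10 predictors")
    y = table[response].to_numpy(dtype=float)
    full = _design(table, predictors)
    _check_rank(full, predictors)
    col_of = {name: j + 1 for j, name in enumerate(predictors)}

    r2_cache: dict[frozenset, float] = {}
    for size in range(p + 1):
        for subset in itertools.combinations(predictors, size):
            idx = [0] + [col_of[q] for q in subset]
            beta, *_ = np.linalg.lstsq(full[:, idx], y, rcond=None)
            r2_cache[frozenset(subset)] = _r2_from_fit(y, full[:, idx] @ beta)

    fact = math.factorial
    shares = {}
    for name in predictors:
        others = [q for q in predictors if q != name]
        total = 0.0
        for size in range(p):
            w = fact(size) * fact(p - 1 - size) / fact(p)
            for subset in itertools.combinations(others, size):
                s = frozenset(subset)
                total += w * (r2_cache[s | {name}] - r2_cache[s])
        shares[name] = total
    r2_full = r2_cache[frozenset(predictors)]
    total = sum(shares.values())
    relative = {k: (v / total if total > 0 else np.nan) for k, v in shares.items()}
    return ImportanceTable(shares=shares, relative=relative, r2=r2_full)


# --------------------------------------------------------------------------
# Welch t-test and coefficient interpretation
# --------------------------------------------------------------------------


class WelchResult(NamedTuple):
    statistic: float
    df: float
    p_value: float


def welch_t(a, b) -> WelchResult:
    """Two-sided Welch two-sample t-test (unequal variances).

    Uses the Welch–Satterthwaite degrees of freedom.  Both samples having
    zero variance is degenerate and raises; identical equal-variance lists
    give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both samples have zero variance; Welch test degenerate")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1)))


def delta_for_thickness_change(model: RegressionModel | float, predictor: str | None = None,
                               delta_thickness: float = 0.05) -> float:
    """Predictor change associated with a given cortical-thickness change.

    All else equal, a thickness change of ``delta_thickness`` (mm)
    corresponds to a predictor change of ``delta_thickness / |coefficient|``
    in the predictor's own units.  Accepts either a fitted
    :class:`RegressionModel` plus a predictor name, or a bare coefficient.
    Returned at full precision; round for presentation with
    :func:`round_sig`.
    """
    if isinstance(model, RegressionModel):
        if predictor not in model.coefficients:
            raise KeyError(f"predictor {predictor!r} is not in the model")
        coef = model.coefficients[predictor]
    else:
        coef = float(model)
    if coef == 0.0:
        raise ZeroDivisionError("coefficient is zero; the associated predictor change "
                                "is undefined")
    return delta_thickness / abs(coef)


# --------------------------------------------------------------------------
# predictor-set comparison
# --------------------------------------------------------------------------


@dataclass
class PredictorSetComparison:
    """Selected models for two predictor families and which explains more."""

    model_gamma: RegressionModel
    model_mask: RegressionModel
    ranking_gamma: pd.DataFrame
    ranking_mask: pd.DataFrame
    better: str  # "gamma" | "mask" | "tie" by adjusted R² of the selected models

    def to_dict(self) -> dict:
        return {"gamma": self.model_gamma.to_dict(),
                "mask": self.model_mask.to_dict(),
                "better": self.better}


def compare_predictor_sets(table: pd.DataFrame, set_gamma, set_mask, response: str,
                           k: int = 10, seed=None) -> PredictorSetComparison:
    """Run the exhaustive CV selection for both predictor families.

    ``set_gamma`` is typically ``{m1, m2, lam}`` plus covariates and
    ``set_mask`` ``{mean_lesion_mwf, mean_nawm_mwf}`` plus covariates; the
    two families are never mixed in one model.  The same fold seed is used
    for both searches.
    """
    model_g, rank_g = exhaustive_cv_select(table, set_gamma, response, k=k, seed=seed)
    model_m, rank_m = exhaustive_cv_select(table, set_mask, response, k=k, seed=seed)
    if model_g.adjusted_r2 > model_m.adjusted_r2:
        better = "gamma"
    elif model_g.adjusted_r2 < model_m.adjusted_r2:
        better = "mask"
    else:
        better = "tie"
    return PredictorSetComparison(model_gamma=model_g, model_mask=model_m,
                                  ranking_gamma=rank_g, ranking_mask=rank_m,
                                  better=better)
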