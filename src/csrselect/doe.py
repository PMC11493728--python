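"""Design-of-experiments factor importance via repeated cross-validated Lasso.

Selection-yield responses are background-corrected against negative-control
reactions (divide for gel densitometry, subtract for spectrophotometric
readouts), min-max normalized to 0-100%, and regressed on the design's
factors with the Lasso.  The regularization strength is chosen by
cross-validation; the whole fit is repeated (default 100 times) with
reshuffled folds, and the averaged (absolute) coefficients are the factor
importances.  R-squared, MSE, MAE, AIC and BIC are reported per repeat with
the number of nonzero coefficients as the effective degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold


def normalize_responses(
    raw: Sequence[float],
    negatives: Sequence[float] | None = None,
    mode: str | None = None,
) -> np.ndarray:
    """Background-correct then min-max scale responses to [0, 100].

    ``mode="divide"`` divides by the negative-control mean (densitometry);
    ``mode="subtract"`` subtracts it, clamping at zero (absorbance /
    fluorometric).  The smallest corrected yield maps to 0% and the largest
    to 100%.
    """
    values = np.asarray(raw, dtype=float)
    if mode is not None:
        if negatives is None or len(negatives) == 0:
            raise ValueError("background correction requires negative controls")
        background = float(np.mean(negatives))
        if mode == "divide":
            if background == 0:
                raise ValueError("negative-control mean is zero in divide mode")
            values = values / background
        elif mode == "subtract":
            values = np.clip(values - background, 0.0, None)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise ValueError("responses have zero range; cannot normalize")
    return (values - lo) / (hi - lo) * 100.0


def expand_design(
    design: pd.DataFrame,
    continuous: Sequence[str] = (),
    categorical: Mapping[str, Sequence[str]] | Sequence[str] = (),
    order: str = "main",
) -> pd.DataFrame:
    """Build the model matrix from a runs x factors design table.

    Continuous factors are standardized (zero mean, unit variance) before
    expansion; categorical factors are one-hot encoded against a declared
    reference level (the first declared level, or the first level in sorted
    order).  ``order`` adds all pairwise products ("interactions") and the
    squares of continuous factors ("quadratic", which includes
    interactions).  Constant columns are dropped with a warning.
    """
    if order not in ("main", "interactions", "quadratic"):
        raise ValueError(f"unknown order {order!r}")
    columns: dict[str, np.ndarray] = {}
    cont_cols: list[str] = []
    for name in continuous:
        x = design[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            warnings.warn(f"dropping constant factor {name!r}")
            continue
        columns[name] = (x - x.mean()) / sd
        cont_cols.append(name)
    if not isinstance(categorical, Mapping):
        categorical = {name: None for name in categorical}
    for name, levels in categorical.items():
        observed = design[name].astype(str)
        if levels is None:
            levels = sorted(observed.unique())
        else:
            unknown = set(observed) - set(levels)
            if unknown:
                raise ValueError(f"undeclared levels for {name!r}: {sorted(unknown)}")
        reference, *others = list(levels)
        for level in others:
            col = (observed == level).to_numpy(dtype=float)
            if col.std() == 0:
                warnings.warn(f"dropping constant indicator {name}[{level}]")
                continue
            columns[f"{name}[{level}]"] = col
    main_names = list(columns)
    if order in ("interactions", "quadratic"):
        for a, b in combinations(main_names, 2):
            columns[f"{a}:{b}"] = columns[a] * columns[b]
    if order == "quadratic":
        for name in cont_cols:
            columns[f"{name}^2"] = columns[name] ** 2
    return pd.DataFrame(columns, index=design.index)


@dataclass
class FactorImportance:
    """Averaged Lasso coefficients and per-repeat fit metrics."""

    coefficients: pd.DataFrame  # feature, mean_coef, mean_abs_coef
    metrics: pd.DataFrame  # metric, mean, sd
    lambdas: np.ndarray
    repeats: int

    @property
    def ranking(self) -> pd.DataFrame:
        return self.coefficients.sort_values("mean_abs_coef", ascending=False)


def lasso_importance(
    X: pd.DataFrame,
    y: Sequence[float],
    repeats: int = 100,
    cv_folds: int = 5,
    n_lambdas: int = 100,
    seed: int = 0,
) -> FactorImportance:
    """Repeated cross-validated Lasso factor importance.

    Each repeat reshuffles the fold assignment, picks the regularization
    strength minimizing CV error over a log-spaced grid of ``n_lambdas``
    values, refits on all runs, and records coefficients and in-sample
    metrics.  Means over repeats are the reported importances.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(y) < cv_folds:
        raise ValueError("fewer runs than CV folds")
    features = list(X.columns)
    n = len(y)
    if y.std() == 0:  # degenerate response: nothing to explain
        coefficients = pd.DataFrame(
            {"feature": features, "mean_coef": 0.0, "mean_abs_coef": 0.0}
        )
        metrics = pd.DataFrame(
            {"metric": ["r2", "mse", "mae", "aic", "bic"],
             "mean": [float("nan"), 0.0, 0.0, float("nan"), float("nan")],
             "sd": 0.0}
        )
        return FactorImportance(coefficients, metrics, np.array([]), repeats)

    coefs = np.zeros((repeats, len(features)))
    lambdas = np.zeros(repeats)
    metric_rows = np.zeros((repeats, 5))
    child_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    Xv = X.to_numpy(dtype=float)
    # canonicalize run order so fold assignment (and hence the whole output)
    # does not depend on how the design rows happened to be sorted
    order = np.lexsort(np.vstack([Xv.T, y]))
    Xv = Xv[order]
    y = y[order]
    for rep in range(repeats):
        rs = int(child_seeds[rep])
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=rs)
        model = LassoCV(
            alphas=n_lambdas, cv=cv, random_state=rs, max_iter=100_000
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xv, y)
        coefs[rep] = model.coef_
        lambdas[rep] = model.alpha_
        pred = model.predict(Xv)
        mse = mean_squared_error(y, pred)
        mae = mean_absolute_error(y, pred)
        r2 = r2_score(y, pred)
        df_eff = int(np.count_nonzero(model.coef_))
        log_mse = np.log(max(mse, 1e-300))
        aic = n * log_mse + 2 * df_eff
        bic = n * log_mse + np.log(n) * df_eff
        metric_rows[rep] = (r2, mse, mae, aic, bic)
    coefficients = pd.DataFrame(
        {
            "feature": features,
            "mean_coef": coefs.mean(axis=0),
            "mean_abs_coef": np.abs(coefs).mean(axis=0),
        }
    )
    metrics = pd.DataFrame(
        {
            "metric": ["r2", "mse", "mae", "aic", "bic"],
            "mean": metric_rows.mean(axis=0),
            "sd": metric_rows.std(axis=0),
        }
    )
    return FactorImportance(coefficients, metrics, lambdas, repeats)
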