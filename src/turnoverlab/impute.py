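"""Chained-equation imputation with predictive mean matching.

Continuous columns are imputed by predictive mean matching (PMM): a linear
regression of the observed values on the other features yields predictions,
and each missing cell receives the *observed* value of one of the k nearest
neighbours in prediction space (donor pool k = 5).  Binary columns use
logistic regression (a draw from the predicted class probability) and
multi-category columns multinomial logistic regression.  Columns are cycled
until the imputed values stabilize or 10 iterations pass.

Four strategies control which rows are completed, matching how the turnover
models are trained: ``none``, ``labelled_only`` (rows with an output value),
``unlabelled_only`` (rows predictions are made for) and ``all``.  The output
(turnover) column itself is never used as a predictor, so imputation cannot
leak the response into the features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

__all__ = ["impute", "ImputationError", "STRATEGIES"]

STRATEGIES = ("none", "labelled_only", "unlabelled_only", "all")


class ImputationError(ValueError):
    pass


def _column_kind(series: pd.Series) -> str:
    vals = series.dropna().unique()
    if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
        return "binary" if len(vals) == 2 else "categorical"
    if len(vals) == 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
        return "binary"
    return "continuous"


def _design(frame: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    """Numeric design matrix from current (partially imputed) values."""
    blocks = []
    for col in predictors:
        s = frame[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            blocks.append(pd.get_dummies(s, prefix=col, dtype=float))
        else:
            blocks.append(s.astype(float).to_frame(col))
    X = pd.concat(blocks, axis=1).to_numpy(dtype=float)
    return np.nan_to_num(X)


def impute(
    table: pd.DataFrame,
    strategy: str,
    labelled: pd.Series | np.ndarray | None = None,
    output_column: str | None = None,
    rng: np.random.Generator | int = 0,
    donors: int = 5,
    max_iter: int = 10,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Return a copy of ``table`` with missing cells filled per ``strategy``.

    Parameters
    ----------
    strategy
        One of :data:`STRATEGIES`.
    labelled
        Boolean mask of rows that carry an output observation (required for
        the ``labelled_only``/``unlabelled_only`` strategies).
    output_column
        Name of the response column, excluded from the predictors and never
        imputed.

    Raises
    ------
    ImputationError
        Unknown strategy, or a column with no observed values in the rows to
        be imputed.
    """
    if strategy not in STRATEGIES:
        raise ImputationError(f"unknown imputation strategy {strategy!r}")
    out = table.copy()
    if strategy == "none":
        return out
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    if strategy == "all":
        target_rows = pd.Series(True, index=out.index)
    else:
        if labelled is None:
            raise ImputationError(f"strategy {strategy!r} requires a labelled mask")
        labelled = pd.Series(np.asarray(labelled, dtype=bool), index=out.index)
        target_rows = labelled if strategy == "labelled_only" else ~labelled

    feature_cols = [c for c in out.columns if c != output_column]
    to_impute = [
        c for c in feature_cols if out.loc[target_rows, c].isna().any()
    ]
    if not to_impute:
        return out

    kinds = {c: _column_kind(out[c]) for c in to_impute}
    for c in to_impute:
        if out[c].notna().sum() == 0:
            raise ImputationError(f"column {c!r} has no observed values to learn from")

    # initialize missing target cells with column median / mode
    filled = out.copy()
    for c in feature_cols:
        if kinds.get(c, _column_kind(out[c])) == "continuous":
            fill = out[c].astype(float).median()
        else:
            fill = out[c].mode(dropna=True).iloc[0]
        filled[c] = filled[c].fillna(fill)

    masks = {c: out[c].isna() & target_rows for c in to_impute}
    for _ in range(max_iter):
        delta = 0.0
        for c in to_impute:
            miss = masks[c]
            if not miss.any():
                continue
            obs = out[c].notna()
            predictors = [p for p in feature_cols if p != c]
            X = _design(filled, predictors)
            y_obs = out.loc[obs, c]
            if kinds[c] == "continuous":
                reg = LinearRegression().fit(X[obs.to_numpy()], y_obs.astype(float))
                pred_obs = reg.predict(X[obs.to_numpy()])
                pred_mis = reg.predict(X[miss.to_numpy()])
                donors_vals = y_obs.to_numpy(dtype=float)
                new_vals = np.empty(len(pred_mis))
                k = min(donors, len(donors_vals))
                for i, p in enumerate(pred_mis):
                    nearest = np.argsort(np.abs(pred_obs - p), kind="stable")[:k]
                    new_vals[i] = donors_vals[nearest[rng.integers(k)]]
            else:
                codes, uniques = pd.factorize(y_obs)
                if len(uniques) < 2:
                    new_vals = np.repeat(uniques[0], int(miss.sum()))
                else:
                    clf = LogisticRegression(max_iter=500).fit(
                        X[obs.to_numpy()], codes
                    )
                    proba = clf.predict_proba(X[miss.to_numpy()])
                    draws = [rng.choice(len(uniques), p=p / p.sum()) for p in proba]
                    new_vals = uniques.take(draws)
            old = filled.loc[miss, c].to_numpy()
            filled.loc[miss, c] = new_vals
            if kinds[c] == "continuous":
                scale = max(1.0, float(np.nanstd(out[c].astype(float))))
                delta = max(delta, float(np.max(np.abs(new_vals - old.astype(float)))) / scale)
            else:
                delta = max(delta, float(np.mean(new_vals != old)))
        if delta < tol:
            break

    for c in to_impute:
        out.loc[masks[c], c] = filled.loc[masks[c], c]
    return out
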