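"""Regression models of log10 turnover numbers.

The modelling surface follows the Model -> fit() -> Results idiom:

* :class:`TurnoverModel` fits one algorithm family (elastic net, random
  forest, small multilayer perceptron, ordinary linear regression or partial
  least squares) with hyperparameters chosen to minimize RMSE under
  five-times-repeated 5-fold cross-validation (one repeat for the neural
  net), and returns a :class:`TurnoverModelResults` carrying the 25
  per-validation R²/RMSE scores.
* :class:`TurnoverEnsemble` trains the 12-member prediction ensemble —
  {elastic net, random forest, neural net} × {no imputation, impute
  labelled, impute unlabelled-for-prediction, impute all} — and predicts by
  averaging the 12 log10 predictions, substituting a member's fallback
  median where it cannot predict, then exponentiating back to s⁻¹.
* :class:`BaggedForest` plus :func:`permutation_importance` provide per-tree
  out-of-bag permutation feature importance (mean MSE increase across trees
  scaled by its standard deviation) with a response-permutation significance
  test.

All responses are on the log10 scale; all randomness flows from explicit
seeds, so identical seeds give identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor

from .impute import impute

__all__ = [
    "ALGORITHMS",
    "ENSEMBLE_STRATEGIES",
    "ModelSpec",
    "CVResult",
    "TurnoverModel",
    "TurnoverModelResults",
    "TurnoverEnsemble",
    "TurnoverEnsembleResults",
    "BaggedForest",
    "permutation_importance",
    "train_cv",
    "design_matrix",
]

ALGORITHMS = ("elastic_net", "random_forest", "neural_net", "linear", "pls")
ENSEMBLE_ALGORITHMS = ("elastic_net", "random_forest", "neural_net")
ENSEMBLE_STRATEGIES = ("none", "labelled_only", "unlabelled_only", "all")


def _default_grid(algorithm: str) -> list[dict]:
    if algorithm == "elastic_net":
        return [
            {"alpha": a, "l1_ratio": l}
            for a in (0.001, 0.01, 0.1, 1.0)
            for l in (0.2, 0.5, 0.8)
        ]
    if algorithm == "random_forest":
        return [
            {"n_estimators": 200, "max_features": f} for f in ("sqrt", 1.0)
        ]
    if algorithm == "linear":
        return [{}]
    if algorithm == "pls":
        return [{"n_components": k} for k in (1, 2, 3, 4)]
    if algorithm == "neural_net":
        return []  # drawn by random search, see ModelSpec.candidates
    raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class ModelSpec:
    """Configuration of one algorithm family.

    ``grid`` is an explicit hyperparameter grid (list of keyword dicts); the
    neural net instead draws ``n_random`` configurations at random from a
    documented search space.  ``repeats`` defaults to 5 but to 1 for the
    neural net, whose training is the costly member.
    """

    algorithm: str
    grid: list[dict] | None = None
    folds: int = 5
    repeats: int | None = None
    n_random: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.repeats is None:
            self.repeats = 1 if self.algorithm == "neural_net" else 5
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def candidates(self, rng: np.random.Generator) -> list[dict]:
        if self.grid is not None:
            return list(self.grid)
        if self.algorithm != "neural_net":
            return _default_grid(self.algorithm)
        out = []
        for _ in range(max(1, self.n_random)):
            out.append(
                {
                    "hidden_layer_sizes": (int(rng.choice([8, 16, 32, 64])),),
                    "alpha": float(10 ** rng.uniform(-5, -1)),
                    "learning_rate_init": float(10 ** rng.uniform(-3.5, -1.5)),
                }
            )
        return out


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "elastic_net":
        return make_pipeline(
            StandardScaler(), ElasticNet(max_iter=20_000, **params)
        )
    if algorithm == "random_forest":
        return RandomForestRegressor(random_state=seed, **params)
    if algorithm == "neural_net":
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(
                max_iter=800, random_state=seed, solver="adam", **params
            ),
        )
    if algorithm == "linear":
        return make_pipeline(StandardScaler(), LinearRegression(**params))
    if algorithm == "pls":
        return make_pipeline(StandardScaler(), PLSRegression(**params))
    raise ValueError(f"unknown algorithm {algorithm!r}")


def design_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categorical columns; numeric columns pass through."""
    blocks = []
    for col in features.columns:
        s = features[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            blocks.append(pd.get_dummies(s, prefix=col, dtype=float))
        else:
            blocks.append(s.astype(float).to_frame(col))
    return pd.concat(blocks, axis=1)


@dataclass
class CVResult:
    """Cross-validation scores for the selected hyperparameters."""

    r2: np.ndarray  # folds x repeats validation R² scores
    rmse: np.ndarray
    best_params: dict
    folds: int
    repeats: int
    test_r2: float | None = None

    @property
    def median_r2(self) -> float:
        return float(np.median(self.r2))

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse))


def _cv_scores(algorithm, params, X, y, folds, repeats, seed):
    rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    r2s, rmses = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, (tr, va) in enumerate(rkf.split(X)):
            est = _make_estimator(algorithm, params, seed + k)
            est.fit(X[tr], y[tr])
            pred = np.ravel(est.predict(X[va]))
            sse = float(np.sum((y[va] - pred) ** 2))
            sst = float(np.sum((y[va] - np.mean(y[va])) ** 2))
            r2s.append(1.0 - sse / sst)
            rmses.append(float(np.sqrt(sse / len(va))))
    return np.array(r2s), np.array(rmses)


@dataclass
class TurnoverModelResults:
    """Fitted single-algorithm model plus its cross-validation record."""

    model: object
    cv: CVResult
    spec: ModelSpec
    feature_names: list[str]

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = design_matrix(X).reindex(columns=self.feature_names, fill_value=0.0)
            X = X.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.ravel(self.model.predict(X))

    def summary(self) -> str:
        cv = self.cv
        lines = [
            f"Turnover regression ({self.spec.algorithm})",
            f"  CV protocol      : {cv.repeats} x {cv.folds}-fold "
            f"({len(cv.r2)} validations)",
            f"  median R2        : {cv.median_r2:.3f}",
            f"  mean R2          : {cv.mean_r2:.3f}",
            f"  mean RMSE (log10): {cv.mean_rmse:.3f}",
            f"  hyperparameters  : {cv.best_params}",
        ]
        if cv.test_r2 is not None:
            lines.append(f"  held-out test R2 : {cv.test_r2:.3f}")
        return "\n".join(lines)


class TurnoverModel:
    """One regression model of log10 turnover built from a feature table.

    Parameters
    ----------
    features
        Reaction-level feature table (numeric and categorical columns);
        rows with any missing value are dropped before training.
    y
        log10 turnover numbers aligned with ``features``.
    spec
        Algorithm family and CV protocol.
    test_fraction
        Optional held-out fraction (stratified by response quantile) whose
        R² is reported but never used for hyperparameter selection.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        y: pd.Series | np.ndarray,
        spec: ModelSpec,
        test_fraction: float = 0.0,
    ):
        y = pd.Series(np.asarray(y, dtype=float), index=features.index)
        complete = features.notna().all(axis=1) & y.notna()
        self.features = features.loc[complete]
        self.y = y.loc[complete]
        self.spec = spec
        self.test_fraction = test_fraction
        if len(self.y) < 2 * spec.folds:
            raise ValueError(
                f"too few complete observations ({len(self.y)}) for "
                f"{spec.folds}-fold cross-validation"
            )
        if np.ptp(self.y.to_numpy()) == 0:
            raise ValueError("response is constant; nothing to fit")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        algorithm: str = "elastic_net",
        **spec_kwargs,
    ) -> "TurnoverModel":
        """Build from one frame holding features plus a response column."""
        y = data[response]
        X = data.drop(columns=[response])
        return cls(X, y, ModelSpec(algorithm, **spec_kwargs))

    def fit(self) -> TurnoverModelResults:
        rng = np.random.default_rng(self.spec.seed)
        Xd = design_matrix(self.features)
        names = list(Xd.columns)
        X = Xd.to_numpy(dtype=float)
        y = self.y.to_numpy(dtype=float)

        test_idx = np.array([], dtype=int)
        if self.test_fraction > 0:
            # stratify by response quantile so the split spans the range
            order = np.argsort(y, kind="stable")
            n_test = max(1, int(round(self.test_fraction * len(y))))
            stride = max(1, len(y) // n_test)
            test_idx = order[::stride][:n_test]
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        Xt, yt = X[train_idx], y[train_idx]

        best = None
        for params in self.spec.candidates(rng):
            r2s, rmses = _cv_scores(
                self.spec.algorithm, params, Xt, yt,
                self.spec.folds, self.spec.repeats, self.spec.seed,
            )
            key = float(np.mean(rmses))
            if best is None or key < best[0]:
                best = (key, params, r2s, rmses)
        _, params, r2s, rmses = best

        est = _make_estimator(self.spec.algorithm, params, self.spec.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xt, yt)
        test_r2 = None
        if len(test_idx):
            pred = np.ravel(est.predict(X[test_idx]))
            sse = float(np.sum((y[test_idx] - pred) ** 2))
            sst = float(np.sum((y[test_idx] - np.mean(y[test_idx])) ** 2))
            test_r2 = 1.0 - sse / sst
        cv = CVResult(r2s, rmses, params, self.spec.folds, self.spec.repeats, test_r2)
        return TurnoverModelResults(est, cv, self.spec, names)


def train_cv(
    features: pd.DataFrame,
    y,
    spec: ModelSpec,
    test_fraction: float = 0.0,
) -> tuple[object, CVResult]:
    """Functional wrapper: fit one model, return (fitted results, CVResult)."""
    res = TurnoverModel(features, y, spec, test_fraction).fit()
    return res, res.cv


# ---------------------------------------------------------------------------
# bagged forest with per-tree out-of-bag permutation importance
# ---------------------------------------------------------------------------


class BaggedForest:
    """Bootstrap-aggregated regression trees with explicit OOB bookkeeping.

    Each tree is trained on a bootstrap sample; the rows a tree never saw
    (its out-of-bag set) provide an honest error estimate used by the
    permutation-importance measure.  Defaults mirror the classical
    regression random forest: 500 trees, p/3 features per split.
    """

    def __init__(self, n_trees: int = 500, max_features: float | str = 0.334,
                 seed: int = 0, min_samples_leaf: int = 5):
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed
        self.min_samples_leaf = min_samples_leaf
        self.trees_: list[DecisionTreeRegressor] = []
        self.oob_: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        rng = np.random.default_rng(self.seed)
        self.trees_, self.oob_ = [], []
        for t in range(self.n_trees):
            boot = rng.integers(n, size=n)
            oob = np.setdiff1d(np.arange(n), np.unique(boot))
            tree = DecisionTreeRegressor(
                max_features=self.max_features,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            self.oob_.append(oob)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.mean([t.predict(X) for t in self.trees_], axis=0)


def _forest_importance(forest: BaggedForest, X, y, rng) -> np.ndarray:
    """Scaled per-feature OOB permutation importance for one fitted forest."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    increases = np.full((len(forest.trees_), p), np.nan)
    used = 0
    for t, (tree, oob) in enumerate(zip(forest.trees_, forest.oob_)):
        if len(oob) == 0:
            warnings.warn("tree with no out-of-bag samples skipped")
            continue
        used += 1
        Xo = X[oob]
        n_oob = len(oob)
        # one batched predict: [base | feature-1 permuted | ... | feature-p]
        stack = np.tile(Xo, (p + 1, 1))
        for j in range(p):
            block = stack[(j + 1) * n_oob : (j + 2) * n_oob]
            block[:, j] = Xo[rng.permutation(n_oob), j]
        pred = tree.predict(stack).reshape(p + 1, n_oob)
        mses = np.mean((y[oob][None, :] - pred) ** 2, axis=1)
        increases[t] = mses[1:] - mses[0]
    if used == 0:
        raise ValueError("no tree had out-of-bag samples")
    mean = np.nanmean(increases, axis=0)
    sd = np.nanstd(increases, axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return mean / sd


def permutation_importance(
    forest: BaggedForest,
    features: pd.DataFrame | np.ndarray,
    y,
    n_response_permutations: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature importance with response-permutation significance.

    Importance is the mean increase in out-of-bag MSE across trees after
    permuting the feature, scaled by the standard deviation of that increase
    across trees.  Significance: the forest is refitted on
    ``n_response_permutations`` permutations of the response, and the
    p-value is the fraction of permuted importances that meet or exceed the
    observed one (with the +1 correction, so p ∈ (0, 1]).

    Returns a DataFrame indexed by feature with columns ``importance`` and
    ``p_value``.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        observed = _forest_importance(forest, X, y, rng)
        exceed = np.zeros(len(names))
        for _ in range(n_response_permutations):
            yp = y[rng.permutation(len(y))]
            f = BaggedForest(
                forest.n_trees, forest.max_features,
                seed=int(rng.integers(2**31 - 1)),
                min_samples_leaf=forest.min_samples_leaf,
            ).fit(X, yp)
            perm_imp = _forest_importance(f, X, yp, rng)
            exceed += perm_imp >= observed
    p = (1.0 + exceed) / (1.0 + n_response_permutations)
    return pd.DataFrame({"importance": observed, "p_value": p}, index=names)


# ---------------------------------------------------------------------------
# 12-member ensemble
# ---------------------------------------------------------------------------


@dataclass
class _Member:
    algorithm: str
    strategy: str
    results: TurnoverModelResults
    fallback_median: float


@dataclass
class TurnoverEnsembleResults:
    """Fitted 12-member ensemble.

    ``members`` holds {elastic net, random forest, neural net} × the four
    imputation strategies; ``global_median`` is the training-set median of
    log10 turnover, the value the median-imputed baseline parameterization
    assigns to every unobserved reaction.
    """

    members: list[_Member]
    global_median: float
    _train_features: pd.DataFrame = field(repr=False)
    _predict_tables: dict[str, pd.DataFrame] = field(repr=False)

    def predict_log10(self, rows: pd.DataFrame | None = None) -> pd.Series:
        """Mean of the 12 member predictions on the log10 scale."""
        contributions = []
        for m in self.members:
            if rows is None:
                table = self._predict_tables[m.strategy]
            else:
                table = rows
                if m.strategy in ("unlabelled_only", "all"):
                    table = impute(rows, "all", rng=0)
            complete = table.notna().all(axis=1)
            vals = pd.Series(m.fallback_median, index=table.index, dtype=float)
            if complete.any():
                vals.loc[complete] = m.results.predict(table.loc[complete])
            contributions.append(vals)
        return sum(contributions) / len(contributions)

    def predict(self, rows: pd.DataFrame | None = None) -> pd.Series:
        """Ensemble turnover prediction in s⁻¹."""
        out = 10.0 ** self.predict_log10(rows)
        out.name = "turnover_per_s"
        return out

    def member_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "algorithm": m.algorithm,
                    "strategy": m.strategy,
                    "median_cv_r2": m.results.cv.median_r2,
                    "fallback_median_log10": m.fallback_median,
                }
                for m in self.members
            ]
        )

    def summary(self) -> str:
        df = self.member_frame()
        lines = [
            f"Turnover ensemble: {len(self.members)} members "
            f"({df.algorithm.nunique()} algorithms x "
            f"{df.strategy.nunique()} imputation strategies)",
            f"  global training median (log10 s^-1): {self.global_median:.3f}",
            df.to_string(index=False),
        ]
        return "\n".join(lines)


class TurnoverEnsemble:
    """The 12-member turnover-prediction ensemble.

    Parameters
    ----------
    features
        Feature table for *all* reactions (labelled and unlabelled), on the
        linearized scale; may contain missing values.
    y
        log10 turnover observations indexed by a subset of ``features``'s
        index (the labelled reactions).
    specs
        Optional per-algorithm :class:`ModelSpec` overrides.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        y: pd.Series,
        specs: dict[str, ModelSpec] | None = None,
        seed: int = 0,
    ):
        self.features = features
        self.y = y.astype(float)
        self.seed = seed
        self.specs = dict(specs or {})
        for algo in ENSEMBLE_ALGORITHMS:
            self.specs.setdefault(algo, ModelSpec(algo, seed=seed))
        unknown = set(self.y.index) - set(features.index)
        if unknown:
            raise ValueError(f"labelled reactions missing from features: {unknown}")

    def fit(self) -> TurnoverEnsembleResults:
        labelled = pd.Series(
            self.features.index.isin(self.y.index), index=self.features.index
        )
        rng = np.random.default_rng(self.seed)
        tables = {
            "none": self.features,
            "labelled_only": impute(
                self.features, "labelled_only", labelled, rng=rng
            ),
            "unlabelled_only": self.features,  # training side untouched
            "all": impute(self.features, "all", labelled, rng=rng),
        }
        predict_tables = {
            "none": self.features,
            "labelled_only": self.features,
            "unlabelled_only": impute(
                self.features, "unlabelled_only", labelled, rng=rng
            ),
            "all": tables["all"],
        }
        members: list[_Member] = []
        for algo in ENSEMBLE_ALGORITHMS:
            ok = 0
            for strategy in ENSEMBLE_STRATEGIES:
                table = tables[strategy].loc[labelled]
                try:
                    res = TurnoverModel(table, self.y.reindex(table.index),
                                        self.specs[algo]).fit()
                    train_complete = table.notna().all(axis=1)
                    preds = res.predict(table.loc[train_complete])
                    members.append(
                        _Member(algo, strategy, res, float(np.median(preds)))
                    )
                    ok += 1
                except ValueError as err:
                    warnings.warn(
                        f"ensemble member ({algo}, {strategy}) dropped: {err}"
                    )
            if ok == 0:
                raise RuntimeError(
                    f"no ensemble member of family {algo!r} could be trained"
                )
        return TurnoverEnsembleResults(
            members,
            float(np.median(self.y)),
            self.features,
            predict_tables,
        )
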