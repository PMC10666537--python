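"""Per-endpoint binary toxicity classifiers on molecular fingerprints.

Each toxicity endpoint gets its own classifier (default family: extreme
gradient boosted trees), trained on an 80/20 stratified split with SMOTE
oversampling nested inside cross-validation folds, hyperparameters tuned by
random grid search with early stopping, and the winning configuration
selected by cross-validated F1.  Test sets are withdrawn before any
oversampling, bit filtering, or tuning.  Models are eligible to vote on
unknown features only when their held-out test sensitivity AND precision
strictly exceed the eligibility threshold (0.65 by default): a model that
cannot reliably detect true toxic cases must not contribute.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import NearestNeighbors

from .errors import PreconditionError, SplitError


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass
class MetricSet:
    """Classification metrics; a metric whose denominator is zero is
    ``None`` (undefined), never 0."""

    sensitivity: float | None = None
    precision: float | None = None
    balanced_accuracy: float | None = None
    f1: float | None = None


def confusion(y_true: Sequence[int],
              y_pred: Sequence[int]) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def metrics_from_confusion(cc: ConfusionCounts) -> MetricSet:
    """sensitivity = TP/(TP+FN); precision = TP/(TP+FP); balanced accuracy
    = (TP/(TP+FN) + TN/(TN+FP))/2; F1 = 2·precision·sensitivity /
    (precision + sensitivity)."""
    sens = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) else None
    prec = cc.tp / (cc.tp + cc.fp) if (cc.tp + cc.fp) else None
    spec = cc.tn / (cc.tn + cc.fp) if (cc.tn + cc.fp) else None
    bal = (sens + spec) / 2 if (sens is not None and spec is not None) else None
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricSet(sensitivity=sens, precision=prec,
                     balanced_accuracy=bal, f1=f1)


@dataclass
class EndpointModel:
    endpoint_id: str
    model_family: str
    hyperparams: dict
    kept_bits: list
    predictor: object
    cv_metrics: MetricSet = field(default_factory=MetricSet)
    test_metrics: MetricSet = field(default_factory=MetricSet)
    eligible: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.predictor.predict(X), dtype=int)


def derive_endpoint_seed(global_seed: int, endpoint_id: str) -> int:
    """One deterministic seed stream per endpoint, independent of the order
    in which endpoints are trained."""
    return (int(global_seed) + zlib.crc32(endpoint_id.encode("utf-8"))) % (
        2 ** 31
    )


def split_train_test(
    X: np.ndarray,
    y: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test split; the test set is withdrawn before any
    oversampling, bit filtering, or tuning touches the data."""
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise SplitError(
            f"each class needs >= 2 members for a stratified split, "
            f"got {counts[0]} negatives / {counts[1]} positives"
        )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    return X_tr, X_te, y_tr, y_te


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to class parity.

    Each synthetic sample is a convex combination x + u·(x_nn − x) with
    u ~ Uniform(0,1) and x_nn one of the k nearest minority neighbours
    (Euclidean).  Synthetic fingerprint coordinates stay fractional in
    [0,1]; they are NOT re-binarized.  Must only ever be applied inside a
    training fold — never before the test split (leakage).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    n_min, n_maj = counts[minority], counts[1 - minority]
    if n_min == 0:
        raise PreconditionError("minority class is empty")
    need = n_maj - n_min
    if need <= 0:
        return X.copy(), y.copy()

    rng = np.random.default_rng(seed)
    X_min = X[y == minority]
    if n_min == 1:
        warnings.warn("single minority sample: duplicating instead of SMOTE")
        synth = np.repeat(X_min, need, axis=0)
    else:
        k_eff = min(k, n_min - 1)
        if k_eff < k:
            warnings.warn(
                f"minority count {n_min} <= k={k}; using k={k_eff}"
            )
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
        _, idx = nn.kneighbors(X_min)  # column 0 is the point itself
        base = rng.integers(0, n_min, size=need)
        pick = rng.integers(1, k_eff + 1, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        neigh = X_min[idx[base, pick]]
        synth = X_min[base] + u[:, None] * (neigh - X_min[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(need, minority, dtype=int)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# model registry

def _make_xgboost(params: dict, seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(
        max_depth=int(params.get("max_depth", 6)),
        learning_rate=float(params.get("learning_rate", 0.1)),
        n_estimators=int(params.get("n_estimators", 100)),
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )


def _make_forest(params: dict, seed: int):
    return RandomForestClassifier(
        n_estimators=int(params.get("n_estimators", 100)),
        max_depth=(int(params["max_depth"])
                   if params.get("max_depth") else None),
        random_state=seed,
        n_jobs=1,
    )


def _make_logistic(params: dict, seed: int):
    return LogisticRegression(
        C=float(params.get("C", 1.0)), max_iter=2000, random_state=seed
    )


def _make_naive_bayes(params: dict, seed: int):
    return BernoulliNB(alpha=float(params.get("alpha", 1.0)))


@dataclass
class ModelFamily:
    name: str
    factory: Callable[[dict, int], object]
    # hyperparameter grid: name -> ("int"|"float"|"logfloat", low, high)
    grid: dict


MODEL_REGISTRY: dict[str, ModelFamily] = {
    # default family; grid spans 1 < max_depth < 10, 0.01 < eta < 0.3
    "xgboost": ModelFamily(
        "xgboost",
        _make_xgboost,
        {
            "max_depth": ("int", 2, 9),
            "learning_rate": ("logfloat", 0.01, 0.3),
            "n_estimators": ("int", 50, 200),
        },
    ),
    "random_forest": ModelFamily(
        "random_forest",
        _make_forest,
        {"n_estimators": ("int", 25, 200), "max_depth": ("int", 4, 20)},
    ),
    "logistic": ModelFamily(
        "logistic", _make_logistic, {"C": ("logfloat", 0.01, 10.0)}
    ),
    "naive_bayes": ModelFamily(
        "naive_bayes", _make_naive_bayes,
        {"alpha": ("logfloat", 0.01, 10.0)},
    ),
}


def _draw_params(grid: Mapping, rng: np.random.Generator) -> dict:
    params = {}
    for name, spec in grid.items():
        if isinstance(spec, (list, tuple)) and spec and spec[0] in (
            "int", "float", "logfloat"
        ):
            kind, lo, hi = spec
            if kind == "int":
                params[name] = int(rng.integers(lo, hi + 1))
            elif kind == "float":
                params[name] = float(rng.uniform(lo, hi))
            else:
                params[name] = float(
                    math.exp(rng.uniform(math.log(lo), math.log(hi)))
                )
        elif isinstance(spec, (list, tuple)):
            params[name] = spec[int(rng.integers(0, len(spec)))]
        else:
            params[name] = spec  # fixed value
    return params


def _cv_f1(
    family: ModelFamily,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int,
    repeats: int,
    seed: int,
    nested_smote: bool = True,
) -> tuple[float | None, ConfusionCounts]:
    """Cross-validated F1 with SMOTE applied inside each fold's training
    part only (``nested_smote=False`` exists solely so the leakage detector
    can demonstrate the optimistic bias of oversampling before splitting)."""
    pooled = ConfusionCounts()
    for rep in range(repeats):
        skf = StratifiedKFold(
            n_splits=cv_folds, shuffle=True, random_state=seed + rep
        )
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            X_tr, y_tr = X[tr], y[tr]
            if nested_smote:
                X_tr, y_tr = smote_oversample(
                    X_tr, y_tr, seed=seed + 1000 * rep + fold
                )
            clf = family.factory(params, seed)
            clf.fit(X_tr, y_tr)
            pooled = pooled + confusion(y[te], clf.predict(X[te]))
    return metrics_from_confusion(pooled).f1, pooled


def tune_and_train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    model_family: str = "xgboost",
    grid_spec: Mapping | None = None,
    cv_folds: int = 10,
    repeats: int = 1,
    grid_draws: int = 50,
    early_stop: int = 20,
    seed: int = 0,
    endpoint_id: str = "",
    presmote: bool = False,
) -> EndpointModel:
    """Random grid search over the family's hyperparameter grid, selected
    by cross-validated F1, with early stopping after ``early_stop``
    consecutive draws without improvement; the winner is refit on the full
    training set oversampled to parity.

    ``presmote=True`` applies SMOTE to the entire training set BEFORE
    cross-validation — a deliberately leaky pipeline used only by the
    leakage-detector tests; real training always nests SMOTE within folds.
    """
    family = MODEL_REGISTRY[model_family]
    grid = dict(grid_spec) if grid_spec is not None else dict(family.grid)
    rng = np.random.default_rng(seed)
    y_train = np.asarray(y_train, dtype=int)
    X_train = np.asarray(X_train, dtype=float)

    X_cv, y_cv = X_train, y_train
    if presmote:  # leaky variant: synthetic points cross fold boundaries
        X_cv, y_cv = smote_oversample(X_train, y_train, seed=seed)

    best_f1: float | None = None
    best: tuple[dict, ConfusionCounts] | None = None
    stale = 0
    for draw in range(grid_draws):
        params = _draw_params(grid, rng)
        f1, pooled = _cv_f1(
            family, params, X_cv, y_cv, cv_folds, repeats,
            seed=seed + 7919 * draw, nested_smote=not presmote,
        )
        improved = f1 is not None and (best_f1 is None or f1 > best_f1)
        if improved:
            best_f1, best = f1, (params, pooled)
            stale = 0
        else:
            stale += 1
        if stale >= early_stop:
            break

    if best is None:
        raise PreconditionError(
            f"no hyperparameter draw produced a defined F1 for endpoint "
            f"{endpoint_id or '<unnamed>'}: the model never predicted a "
            "positive"
        )
    params, pooled = best
    X_fit, y_fit = (X_cv, y_cv) if presmote else smote_oversample(
        X_train, y_train, seed=seed + 104729
    )
    predictor = family.factory(params, seed)
    predictor.fit(X_fit, y_fit)
    return EndpointModel(
        endpoint_id=endpoint_id,
        model_family=model_family,
        hyperparams=params,
        kept_bits=[],
        predictor=predictor,
        cv_metrics=metrics_from_confusion(pooled),
    )


def evaluate(
    model: EndpointModel, X_test: np.ndarray, y_test: np.ndarray
) -> tuple[MetricSet, ConfusionCounts]:
    cc = confusion(y_test, model.predict(np.asarray(X_test, dtype=float)))
    metrics = metrics_from_confusion(cc)
    model.test_metrics = metrics
    return metrics, cc


def gate_eligibility(
    model: EndpointModel, threshold: float = 0.65
) -> EndpointModel:
    """Eligible to vote iff test sensitivity AND precision are strictly
    greater than the threshold; undefined metrics fail the gate."""
    m = model.test_metrics
    model.eligible = bool(
        m.sensitivity is not None
        and m.precision is not None
        and m.sensitivity > threshold
        and m.precision > threshold
    )
    return model


def train_endpoint(
    fpm,
    y: np.ndarray,
    endpoint_id: str,
    config,
    model_family: str | None = None,
) -> EndpointModel:
    """End-to-end training for one endpoint from a binary FingerprintMatrix.

    Splits 80/20 stratified, fits the bit filter on the training partition
    only, tunes/trains with fold-nested SMOTE, evaluates on the untouched
    test set, and applies the eligibility gate.
    """
    from .fpkit import filter_bits

    seed = derive_endpoint_seed(config.seed, endpoint_id)
    y = np.asarray(y, dtype=int)
    idx = np.arange(len(y))
    idx_tr, idx_te, y_tr, y_te = split_train_test(
        idx, y, test_fraction=config.test_fraction, seed=seed
    )
    train_m = type(fpm)(
        sample_ids=[fpm.sample_ids[i] for i in idx_tr],
        bit_ids=list(fpm.bit_ids),
        values=fpm.values[idx_tr],
        mode_tag=fpm.mode_tag,
        smarts=dict(fpm.smarts),
    )
    reduced, _report = filter_bits(
        train_m,
        min_variability=config.min_bit_variability,
        max_correlation=config.max_bit_correlation,
    )
    kept = reduced.bit_ids
    bit_pos = {b: i for i, b in enumerate(fpm.bit_ids)}
    col_idx = [bit_pos[b] for b in kept]
    X_tr = fpm.values[np.ix_(idx_tr, col_idx)]
    X_te = fpm.values[np.ix_(idx_te, col_idx)]

    model = tune_and_train(
        X_tr, y_tr,
        model_family=model_family or config.model_family,
        cv_folds=config.cv_folds,
        repeats=config.cv_repeats,
        grid_draws=config.grid_draws,
        early_stop=config.early_stop,
        seed=seed,
        endpoint_id=endpoint_id,
    )
    model.kept_bits = list(kept)
    evaluate(model, X_te, y_te)
    gate_eligibility(model, config.eligibility_threshold)
    return model
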