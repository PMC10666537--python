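import numpy as np
import pytest

from toxfinger.endpoint_models import (
    ConfusionCounts,
    EndpointModel,
    confusion,
    derive_endpoint_seed,
    evaluate,
    gate_eligibility,
    metrics_from_confusion,
    MetricSet,
    smote_oversample,
    split_train_test,
    tune_and_train,
)
from toxfinger.errors import SplitError


# ---------------------------------------------------------------- metrics

def test_metric_formulas_on_worked_confusion():
    m = metrics_from_confusion(ConfusionCounts(tp=3, fn=1, tn=4, fp=2))
    assert m.sensitivity == pytest.approx(0.75)
    assert m.precision == pytest.approx(0.6)
    assert m.balanced_accuracy == pytest.approx((0.75 + 4 / 6) / 2)
    assert m.f1 == pytest.approx(2 * 0.6 * 0.75 / 1.35)


def test_perfect_confusion_gives_all_ones():
    m = metrics_from_confusion(ConfusionCounts(tp=1, fn=0, tn=1, fp=0))
    assert (m.sensitivity, m.precision, m.balanced_accuracy, m.f1) == (
        1.0, 1.0, 1.0, 1.0,
    )


def test_no_predicted_positives_leaves_precision_undefined():
    m = metrics_from_confusion(ConfusionCounts(tp=0, fn=3, tn=5, fp=0))
    assert m.precision is None
    assert m.sensitivity == 0.0


def test_confusion_counts_sum_to_sample_count():
    rng = np.random.default_rng(0)
    yt = rng.integers(0, 2, 57)
    yp = rng.integers(0, 2, 57)
    assert confusion(yt, yp).total == 57


# ------------------------------------------------------------------ split

def test_stratified_split_arithmetic():
    X = np.arange(200).reshape(100, 2)
    y = np.array([1] * 10 + [0] * 90)
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, 0.2, seed=0)
    assert len(y_te) == 20
    assert y_te.sum() == 2
    assert y_tr.sum() == 8


def test_split_deterministic_under_seed():
    X = np.arange(100).reshape(50, 2)
    y = np.array([1] * 5 + [0] * 45)
    a = split_train_test(X, y, 0.2, seed=7)
    b = split_train_test(X, y, 0.2, seed=7)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[3], b[3])


def test_single_class_split_is_error():
    with pytest.raises(SplitError):
        split_train_test(np.zeros((10, 2)), np.zeros(10, dtype=int))


# ------------------------------------------------------------------ SMOTE

def test_balanced_classes_unchanged():
    X = np.random.default_rng(0).uniform(size=(20, 3))
    y = np.array([0, 1] * 10)
    X2, y2 = smote_oversample(X, y, seed=0)
    assert X2.shape == X.shape


def test_oversampling_reaches_parity():
    rng = np.random.default_rng(1)
    X = rng.uniform(size=(100, 4))
    y = np.array([1] * 10 + [0] * 90)
    X2, y2 = smote_oversample(X, y, seed=1)
    assert (y2 == 1).sum() == (y2 == 0).sum() == 90


def test_synthetic_points_are_convex_combinations():
    rng = np.random.default_rng(2)
    X = np.round(rng.uniform(size=(60, 5)))
    y = np.array([1] * 12 + [0] * 48)
    X2, y2 = smote_oversample(X, y, seed=2)
    synth = X2[len(X):]
    assert synth.min() >= 0.0 and synth.max() <= 1.0
    # coordinates stay fractional: SMOTE never re-binarizes
    lo = X[y == 1].min(axis=0)
    hi = X[y == 1].max(axis=0)
    assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()


def test_identical_minority_points_yield_identical_synthetics():
    X = np.vstack([np.ones((3, 2)), np.zeros((9, 2))])
    y = np.array([1] * 3 + [0] * 9)
    X2, _ = smote_oversample(X, y, seed=3)
    assert np.array_equal(X2[12:], np.ones((6, 2)))


def test_small_minority_reduces_k_with_warning():
    X = np.random.default_rng(4).uniform(size=(20, 2))
    y = np.array([1] * 3 + [0] * 17)
    with pytest.warns(UserWarning, match="using k=2"):
        smote_oversample(X, y, k=5, seed=4)


def test_single_minority_sample_duplicates_with_warning():
    X = np.random.default_rng(5).uniform(size=(10, 2))
    y = np.array([1] + [0] * 9)
    with pytest.warns(UserWarning, match="duplicating"):
        X2, y2 = smote_oversample(X, y, seed=5)
    assert (y2 == 1).sum() == 9


# ------------------------------------------------------------- tuning/gate

def _separable_data(n=120, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, 5))
    y = (X[:, 0] > 0.5).astype(int)
    X[:, 0] = np.round(X[:, 0])
    return X, y


def test_single_configuration_grid_is_returned():
    X, y = _separable_data()
    grid = {"max_depth": 3, "learning_rate": 0.2, "n_estimators": 30}
    model = tune_and_train(X, y, grid_spec=grid, cv_folds=3, grid_draws=1,
                           early_stop=1, seed=0)
    assert model.hyperparams == grid


def test_better_configuration_wins_by_cv_f1():
    # XOR labels: additive depth-1 boosting cannot separate them, while a
    # deeper tree separates perfectly -> the deep config must win on CV F1
    rng = np.random.default_rng(1)
    X = np.round(rng.uniform(size=(160, 4)))
    y = (X[:, 0] != X[:, 1]).astype(int)
    grid = {
        "max_depth": [1, 3],
        "learning_rate": [0.3],
        "n_estimators": [100],
    }
    model = tune_and_train(X, y, grid_spec=grid, cv_folds=3, grid_draws=8,
                           early_stop=8, seed=1)
    assert model.hyperparams["max_depth"] == 3
    assert model.cv_metrics.f1 == pytest.approx(1.0)


def test_tuning_deterministic_under_seed():
    X, y = _separable_data(seed=2)
    kwargs = dict(cv_folds=3, grid_draws=4, early_stop=4, seed=9)
    a = tune_and_train(X, y, **kwargs)
    b = tune_and_train(X, y, **kwargs)
    assert a.hyperparams == b.hyperparams
    assert a.cv_metrics.f1 == b.cv_metrics.f1


def test_evaluate_matches_brute_force_confusion():
    X, y = _separable_data(seed=3)
    grid = {"max_depth": 2, "learning_rate": 0.3, "n_estimators": 50}
    model = tune_and_train(X, y, grid_spec=grid, cv_folds=3, grid_draws=1,
                           early_stop=1, seed=3)
    metrics, cc = evaluate(model, X, y)
    preds = model.predict(X)
    tp = sum(1 for t, p in zip(y, preds) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y, preds) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y, preds) if t == 1 and p == 0)
    tn = sum(1 for t, p in zip(y, preds) if t == 0 and p == 0)
    assert (cc.tp, cc.fp, cc.fn, cc.tn) == (tp, fp, fn, tn)


@pytest.mark.parametrize(
    "sens,prec,expected",
    [
        (0.66, 0.66, True),
        (0.65, 0.90, False),   # strictly greater required
        (0.90, 0.65, False),
        (1.0, None, False),    # undefined precision fails the gate
    ],
)
def test_eligibility_gate_boundaries(sens, prec, expected):
    model = EndpointModel(
        endpoint_id="e", model_family="xgboost", hyperparams={},
        kept_bits=[], predictor=None,
        test_metrics=MetricSet(sensitivity=sens, precision=prec),
    )
    assert gate_eligibility(model, 0.65).eligible is expected


def test_endpoint_seed_stream_is_order_independent():
    s1 = derive_endpoint_seed(42, "EP001")
    s2 = derive_endpoint_seed(42, "EP002")
    assert s1 != s2
    assert s1 == derive_endpoint_seed(42, "EP001")
    assert 0 <= s1 < 2 ** 31
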