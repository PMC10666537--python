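"""End-to-end synthetic study harness.

Runs the pipeline under the emulated study conditions (2000 training
chemicals per endpoint, 10% actives, 10 planted toxicophore bits,
replicate fingerprint noise with per-bit flip probability ~0.02) and
measures the quantities the validation suite and the reproduction script
report: hit-call error rates, analytic-vs-bisection ACC agreement,
held-out endpoint-model metrics, voted per-target balanced accuracy on
held-out compounds, the oversampling-leakage margin, and toxicophore
recovery by surrogate feature importance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .endpoint_models import split_train_test, train_endpoint, tune_and_train
from .gfi import surrogate_importance
from .io_core import RunConfig
from .synthdata import (
    SynthSpec,
    gen_chemicals,
    gen_endpoint_labels,
    gen_replicate_fingerprints,
    implied_cutoff,
)
from .toxcurate import (
    DoseResponseSeries,
    acc_hill,
    call_hit,
    compute_bmad,
    fit_models,
    hill_curve,
)
from .toxfp_predict import (
    predict_compound_endpoint_calls,
    predict_replicates,
    vote,
)


@dataclass
class StudyResult:
    spec: SynthSpec
    config: RunConfig
    fpm: object
    toxicophore_bits: list
    labels: dict          # endpoint_id -> labels over the full universe
    train_idx: list
    val_idx: list
    train_fpm: object
    val_fpm: object
    models: dict          # endpoint_id -> EndpointModel


def run_study(
    seed: int,
    n_train: int = 2000,
    n_validation: int = 300,
    grid_draws: int = 8,
    early_stop: int = 5,
) -> StudyResult:
    """Generate the synthetic universe, hold out validation compounds, and
    train one gated classifier per endpoint on the remainder.

    Validation compounds come from the same chemical universe (same
    planted toxicophore bits and label rule) but are withdrawn before any
    training — the synthetic analog of excluding spectral-library
    compounds from model training.
    """
    spec = SynthSpec(seed=seed, n_chemicals=n_train + n_validation)
    config = RunConfig.retrain_mode(seed=seed, grid_draws=grid_draws,
                                    early_stop=early_stop)
    fpm, tox_bits = gen_chemicals(spec)
    labels = {}
    for k, ep in enumerate(spec.endpoint_ids()):
        labels[ep], _ = gen_endpoint_labels(fpm, tox_bits, spec,
                                            endpoint_index=k)
    train_idx = list(range(n_train))
    val_idx = list(range(n_train, n_train + n_validation))
    train_fpm = fpm.subset_samples(train_idx)
    val_fpm = fpm.subset_samples(val_idx)
    models = {
        ep: train_endpoint(train_fpm, labels[ep][train_idx], ep, config)
        for ep in spec.endpoint_ids()
    }
    return StudyResult(
        spec=spec, config=config, fpm=fpm, toxicophore_bits=tox_bits,
        labels=labels, train_idx=train_idx, val_idx=val_idx,
        train_fpm=train_fpm, val_fpm=val_fpm, models=models,
    )


def endpoint_metric_means(result: StudyResult) -> dict:
    """Held-out test sensitivity/precision averaged over endpoints (the
    per-target averaging convention)."""
    sens = [m.test_metrics.sensitivity for m in result.models.values()]
    prec = [m.test_metrics.precision for m in result.models.values()]
    return {
        "sensitivity": float(np.mean([s for s in sens if s is not None])),
        "precision": float(np.mean([p for p in prec if p is not None])),
        "n_endpoints": len(result.models),
    }


def validation_repsets(result: StudyResult, min_replicates: int = 8):
    """Replicate probabilistic fingerprints for the held-out compounds with
    at least ``min_replicates`` replicates each, at default bit noise."""
    vspec = dataclasses.replace(result.spec,
                                min_replicates=min_replicates)
    return gen_replicate_fingerprints(result.val_fpm, vspec, stream=301)


def validation_truth(result: StudyResult) -> pd.DataFrame:
    rows = []
    for ep in result.spec.endpoint_ids():
        y = result.labels[ep]
        for cid, j in zip(result.val_fpm.sample_ids, result.val_idx):
            rows.append(
                {"chemical_id": cid, "endpoint_id": ep, "hitc": int(y[j])}
            )
    return pd.DataFrame(rows)


def validation_balanced_accuracy(result: StudyResult,
                                 min_replicates: int = 8) -> pd.DataFrame:
    """Voted per-target balanced accuracy on the held-out compounds."""
    from .toxfp_predict import validate_against_truth

    repsets = validation_repsets(result, min_replicates)
    calls = predict_compound_endpoint_calls(
        result.models, repsets, result.config.binarize_threshold
    )
    return validate_against_truth(
        calls, validation_truth(result), result.spec.target_map(),
        train_compounds=set(result.train_fpm.sample_ids),
    )


def gfi_recovery(result: StudyResult) -> dict:
    """Toxicophore recovery by surrogate importance, averaged over
    endpoints: how many of the planted bits rank in each surrogate's
    top-10, and the planted bits' share of total importance mass."""
    planted = set(result.toxicophore_bits)
    overlaps, masses = [], []
    for ep, model in sorted(result.models.items()):
        X = result.train_fpm.select_bits(model.kept_bits).values
        table = surrogate_importance(model, X, seed=result.config.seed)
        top10 = set(table.top_bits(10))
        overlaps.append(len(top10 & planted))
        imp = dict(zip(table.bit_ids, table.importance))
        masses.append(sum(imp.get(b, 0.0) for b in planted))
    return {
        "mean_top10_overlap": float(np.mean(overlaps)),
        "min_top10_overlap": int(min(overlaps)),
        "mean_importance_mass": float(np.mean(masses)),
    }


def leakage_comparison(seed: int) -> dict:
    """Cross-validated F1 of the deliberately leaky pipeline (SMOTE before
    splitting) versus the correctly nested pipeline on identical data.

    Uses a noisier label rule so F1 sits below 1 and the optimistic bias
    of leakage is visible rather than saturated.
    """
    spec = SynthSpec(seed=seed, n_chemicals=600, label_beta=1.0,
                     active_fraction=0.15)
    fpm, tox = gen_chemicals(spec)
    labels, _ = gen_endpoint_labels(fpm, tox, spec)
    X_tr, _, y_tr, _ = split_train_test(fpm.values, labels, 0.2,
                                        seed=seed)
    grid = {"max_depth": 4, "learning_rate": 0.1, "n_estimators": 100}
    nested = tune_and_train(X_tr, y_tr, grid_spec=grid, cv_folds=5,
                            grid_draws=1, early_stop=1, seed=seed)
    leaky = tune_and_train(X_tr, y_tr, grid_spec=grid, cv_folds=5,
                           grid_draws=1, early_stop=1, seed=seed,
                           presmote=True)
    return {
        "nested_cv_f1": nested.cv_metrics.f1,
        "presmote_cv_f1": leaky.cv_metrics.f1,
    }


def acc_inversion_max_error(n_draws: int = 100, seed: int = 0) -> float:
    """Largest |analytic − bisection| ACC disagreement (log10 units) over
    random hill parameter draws; the bisection oracle refines a coarse
    bracket to 1e-7."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        tp = rng.uniform(2.0, 20.0)
        ga = rng.uniform(-1.0, 2.0)
        gw = rng.uniform(0.3, 8.0)
        cutoff = rng.uniform(0.5, 0.9 * tp)
        analytic = acc_hill(tp, ga, gw, cutoff)
        lo, hi = ga - 10.0, ga + 10.0
        xs = np.linspace(lo, hi, 4000)
        ys = hill_curve(xs, tp, ga, gw) - cutoff
        oracle = None
        for i in range(len(xs) - 1):
            if ys[i] <= 0.0 <= ys[i + 1]:
                a, b = xs[i], xs[i + 1]
                while b - a > 1e-7:
                    m = (a + b) / 2
                    if hill_curve(m, tp, ga, gw) - cutoff <= 0:
                        a = m
                    else:
                        b = m
                oracle = (a + b) / 2
                break
        worst = max(worst, abs(analytic - oracle))
    return float(worst)


def hitcall_rates(n_runs: int = 200, seed: int = 0,
                  noise_sd: float = 1.0) -> dict:
    """False-positive rate on pure-noise series and detection rate on
    strong hill series (top = 10× cutoff) over seeded runs."""
    grid = np.repeat(np.linspace(-1.0, 2.0, 8), 2)
    false_pos = true_pos = 0
    base_rng = np.random.default_rng(seed)
    for run_seed in base_rng.integers(0, 2 ** 31, size=n_runs):
        rng = np.random.default_rng(run_seed)
        baseline = rng.normal(0.0, noise_sd, 30)
        bmad = compute_bmad(baseline)
        cutoff = 6.0 * bmad if bmad > 0 else implied_cutoff(noise_sd)

        noise_series = DoseResponseSeries(
            "c", "e", grid, rng.normal(0.0, noise_sd, len(grid)),
            baseline,
        )
        _, winner = fit_models(noise_series)
        false_pos += call_hit(noise_series, winner, cutoff).hitc

        resp = hill_curve(grid, 10.0 * cutoff, 0.5, 1.0) \
            + rng.normal(0.0, noise_sd, len(grid))
        strong_series = DoseResponseSeries("c", "e", grid, resp, baseline)
        _, winner = fit_models(strong_series)
        true_pos += call_hit(strong_series, winner, cutoff).hitc
    return {
        "false_positive_rate": false_pos / n_runs,
        "detection_rate": true_pos / n_runs,
        "n_runs": n_runs,
    }


def vote_count_worked_example(models: dict | None = None) -> int:
    """Number of replicate votes for a feature with 5 spectra, 10
    candidate fingerprints per spectrum, and 6 eligible endpoints."""
    from .endpoint_models import EndpointModel, MetricSet
    from .fpkit import FingerprintMatrix
    from .toxfp_predict import ReplicateFingerprintSet

    bits = ["b0", "b1"]
    if models is None:
        class _One:
            def predict(self, X):
                return np.ones(len(X), dtype=int)

        models = {
            f"e{i}": EndpointModel(
                endpoint_id=f"e{i}", model_family="stub", hyperparams={},
                kept_bits=bits, predictor=_One(),
                test_metrics=MetricSet(0.9, 0.9, 0.9, 0.9), eligible=True,
            )
            for i in range(6)
        }
    n = 50  # 5 spectra x 10 candidates
    repset = ReplicateFingerprintSet(
        feature_id="feature",
        spectrum_ids=[f"s{i // 10}" for i in range(n)],
        candidate_ranks=[i % 10 + 1 for i in range(n)],
        fingerprints=FingerprintMatrix(
            sample_ids=[f"r{i}" for i in range(n)],
            bit_ids=bits,
            values=np.ones((n, len(bits))),
            mode_tag="probabilistic",
        ),
    )
    preds = predict_replicates(models, repset)
    record = vote(preds, "feature", "target")
    return record.n_votes
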