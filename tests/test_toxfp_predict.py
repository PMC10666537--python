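import numpy as np
import pandas as pd
import pytest

from toxfinger.endpoint_models import EndpointModel, MetricSet
from toxfinger.errors import (
    LeakageError,
    MissingBitError,
    PreconditionError,
)
from toxfinger.fpkit import FingerprintMatrix
from toxfinger.toxfp_predict import (
    ReplicateFingerprintSet,
    UNTESTED,
    assemble_toxicity_fingerprint,
    predict_replicates,
    replicate_sets_from_frame,
    replicate_sets_to_frame,
    validate_against_truth,
    vote,
    vote_feature,
)

BITS = ["b0", "b1", "b2"]


class BitRulePredictor:
    """Predicts the value of one bit (column index)."""

    def __init__(self, col=0):
        self.col = col

    def predict(self, X):
        return np.asarray(X)[:, self.col].astype(int)


def make_model(endpoint_id, eligible=True, col=0, bits=BITS):
    return EndpointModel(
        endpoint_id=endpoint_id, model_family="stub", hyperparams={},
        kept_bits=list(bits), predictor=BitRulePredictor(col),
        test_metrics=MetricSet(0.9, 0.9, 0.9, 0.9), eligible=eligible,
    )


def make_repset(feature_id, n_spectra, candidates_per_spectrum,
                bit_value=1.0, bits=BITS):
    n = n_spectra * candidates_per_spectrum
    return ReplicateFingerprintSet(
        feature_id=feature_id,
        spectrum_ids=[f"sp{i // candidates_per_spectrum}"
                      for i in range(n)],
        candidate_ranks=[i % candidates_per_spectrum + 1
                         for i in range(n)],
        fingerprints=FingerprintMatrix(
            sample_ids=[f"{feature_id}#{i}" for i in range(n)],
            bit_ids=list(bits),
            values=np.full((n, len(bits)), bit_value),
            mode_tag="probabilistic",
        ),
    )


def test_single_replicate_single_endpoint_gives_one_prediction():
    preds = predict_replicates({"e1": make_model("e1")},
                               make_repset("f", 1, 1))
    assert len(preds) == 1


def test_worked_example_five_spectra_ten_candidates_six_endpoints():
    models = {f"e{i}": make_model(f"e{i}") for i in range(6)}
    preds = predict_replicates(models, make_repset("f", 5, 10))
    assert len(preds) == 300


def test_ineligible_endpoints_do_not_predict():
    models = {"e1": make_model("e1"), "e2": make_model("e2",
                                                       eligible=False)}
    preds = predict_replicates(models, make_repset("f", 2, 3))
    assert set(preds["endpoint_id"]) == {"e1"}


def test_missing_kept_bit_is_hard_error_naming_the_bit():
    model = make_model("e1", bits=["b0", "b9"])
    with pytest.raises(MissingBitError, match="b9"):
        predict_replicates({"e1": model}, make_repset("f", 1, 2))


def test_candidate_rank_above_cap_rejected():
    with pytest.raises(PreconditionError):
        make_repset("f", 1, 11)


# ------------------------------------------------------------------ voting

def pred_frame(votes):
    return pd.DataFrame(
        {
            "feature_id": "f",
            "replicate_index": range(len(votes)),
            "spectrum_id": "s",
            "candidate_rank": 1,
            "endpoint_id": "e1",
            "pred": votes,
        }
    )


def test_unanimous_votes_are_toxic():
    rec = vote(pred_frame([1] * 300), "f", "T")
    assert rec.hitc == 1 and rec.n_votes == 300


def test_exact_tie_is_nontoxic():
    rec = vote(pred_frame([1] * 150 + [0] * 150), "f", "T")
    assert rec.hitc == 0


def test_two_of_three_is_toxic():
    assert vote(pred_frame([1, 1, 0]), "f", "T").hitc == 1


def test_vote_invariant_to_order_and_duplication():
    votes = [1, 0, 1, 1, 0]
    base = vote(pred_frame(votes), "f", "T")
    shuffled = vote(pred_frame(list(reversed(votes))), "f", "T")
    doubled = vote(pred_frame(votes * 2), "f", "T")
    assert base.hitc == shuffled.hitc == doubled.hitc


def test_vote_on_empty_predictions_is_error():
    with pytest.raises(PreconditionError):
        vote(pred_frame([]), "f", "T")


# --------------------------------------------------------------- assembly

def test_target_without_eligible_endpoint_is_untested_not_nontoxic():
    models = {"e1": make_model("e1"), "e2": make_model("e2",
                                                       eligible=False)}
    target_map = {"e1": "T1", "e2": "T2"}
    records = vote_feature(models, make_repset("f", 2, 3), target_map)
    toxfp = assemble_toxicity_fingerprint("f", records, ["T1", "T2"])
    assert toxfp.calls["T1"] == 1
    assert toxfp.calls["T2"] == UNTESTED


def test_fingerprint_table_composes_from_per_feature_votes():
    models = {"e1": make_model("e1", col=0), "e2": make_model("e2",
                                                              col=1)}
    target_map = {"e1": "T1", "e2": "T2"}
    rows = {}
    for fid, val in (("f1", 1.0), ("f2", 1.0), ("f3", 0.0), ("f4", 0.0)):
        repset = make_repset(fid, 1, 3, bit_value=val)
        records = vote_feature(models, repset, target_map)
        toxfp = assemble_toxicity_fingerprint(fid, records, ["T1", "T2"])
        rows[fid] = toxfp.calls
        for rec in records:
            assert rec.hitc == int(val)
    assert rows["f1"] == {"T1": 1, "T2": 1}
    assert rows["f3"] == {"T1": 0, "T2": 0}


def test_replicate_table_round_trip():
    repsets = [make_repset("f1", 2, 3, 0.8), make_repset("f2", 1, 4, 0.2)]
    frame = replicate_sets_to_frame(repsets)
    back = replicate_sets_from_frame(frame)
    assert [r.feature_id for r in back] == ["f1", "f2"]
    assert back[0].n_replicates == 6
    assert np.allclose(back[0].fingerprints.values, 0.8)


# ------------------------------------------------------------- validation

def _truth(calls):
    return pd.DataFrame(
        [{"chemical_id": c, "endpoint_id": e, "hitc": h}
         for c, e, h in calls]
    )


def test_perfect_predictions_score_one_per_target():
    voted = pd.DataFrame(
        {
            "chemical_id": ["c1", "c2", "c3", "c4"],
            "endpoint_id": "e1",
            "hitc_pred": [1, 0, 1, 0],
        }
    )
    truth = _truth([("c1", "e1", 1), ("c2", "e1", 0), ("c3", "e1", 1),
                    ("c4", "e1", 0)])
    report = validate_against_truth(voted, truth, {"e1": "T"})
    assert report.loc[0, "balanced_accuracy"] == 1.0


def test_coin_flip_predictions_near_half():
    rng = np.random.default_rng(0)
    n = 2000
    chems = [f"c{i}" for i in range(n)]
    truth = _truth([(c, "e1", int(i < n // 2))
                    for i, c in enumerate(chems)])
    voted = pd.DataFrame(
        {
            "chemical_id": chems,
            "endpoint_id": "e1",
            "hitc_pred": rng.integers(0, 2, n),
        }
    )
    report = validate_against_truth(voted, truth, {"e1": "T"})
    se = np.sqrt(0.25 / (n // 2))  # per-class binomial s.e.
    assert abs(report.loc[0, "balanced_accuracy"] - 0.5) < 3 * se


def test_target_score_is_unweighted_endpoint_mean():
    # endpoint e1 scores 0.6 (3/5 on each class), e2 scores 0.8
    chems = [f"c{i}" for i in range(10)]
    truth_rows, voted_rows = [], []
    for ep, correct in (("e1", 3), ("e2", 4)):
        for i, c in enumerate(chems):
            t = int(i < 5)
            per_class_idx = i if i < 5 else i - 5
            p = t if per_class_idx < correct else 1 - t
            truth_rows.append((c, ep, t))
            voted_rows.append(
                {"chemical_id": c, "endpoint_id": ep, "hitc_pred": p}
            )
    report = validate_against_truth(
        pd.DataFrame(voted_rows), _truth(truth_rows),
        {"e1": "T", "e2": "T"},
    )
    assert report.loc[0, "balanced_accuracy"] == pytest.approx(0.7)


def test_train_validation_overlap_is_leakage_error():
    voted = pd.DataFrame(
        {"chemical_id": ["c1"], "endpoint_id": ["e1"], "hitc_pred": [1]}
    )
    with pytest.raises(LeakageError, match="c1"):
        validate_against_truth(voted, _truth([("c1", "e1", 1)]),
                               {"e1": "T"}, train_compounds={"c1", "c9"})
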