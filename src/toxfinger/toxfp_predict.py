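"""Toxicity-fingerprint prediction for unidentified features by replicate
voting.

An unidentified HRMS/MS feature typically carries several fragmentation
spectra, each yielding up to 10 candidate probabilistic fingerprints from a
spectrum-based predictor.  Every replicate fingerprint is binarized,
projected onto each eligible endpoint model's kept bits, and classified;
the final hit call per mechanistic target is a strict majority vote over
all replicate × endpoint predictions (an exact tie is called nontoxic —
the prioritization context favours precision of the toxic list).  A target
with no eligible endpoint model is reported as 'untested', never as
nontoxic: absence of a usable model must not masquerade as safety.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .endpoint_models import EndpointModel, confusion, metrics_from_confusion
from .errors import LeakageError, MissingBitError, PreconditionError
from .fpkit import FingerprintMatrix, binarize

UNTESTED = "untested"


@dataclass
class ReplicateFingerprintSet:
    """All replicate fingerprints for one feature (or compound): one row per
    (spectrum, candidate) pair, with candidate_rank capped per spectrum."""

    feature_id: str
    spectrum_ids: list
    candidate_ranks: list
    fingerprints: FingerprintMatrix  # probabilistic or binary, one row/repl.
    max_candidates_per_spectrum: int = 10

    def __post_init__(self):
        n = len(self.spectrum_ids)
        if n == 0:
            raise PreconditionError(
                f"feature {self.feature_id}: at least one replicate required"
            )
        if not (n == len(self.candidate_ranks)
                == len(self.fingerprints.sample_ids)):
            raise PreconditionError("replicate bookkeeping out of sync")
        for r in self.candidate_ranks:
            if not (1 <= r <= self.max_candidates_per_spectrum):
                raise PreconditionError(
                    f"candidate rank {r} outside 1.."
                    f"{self.max_candidates_per_spectrum}"
                )

    @property
    def n_replicates(self) -> int:
        return len(self.spectrum_ids)


@dataclass
class FeatureVoteRecord:
    feature_id: str
    target_id: str
    n_votes: int
    n_toxic_votes: int
    hitc: int
    contributing_endpoints: list = field(default_factory=list)


@dataclass
class ToxicityFingerprint:
    feature_id: str
    calls: dict  # target_id -> 0 | 1 | "untested"


def predict_replicates(
    models: Mapping[str, EndpointModel],
    repset: ReplicateFingerprintSet,
    binarize_threshold: float = 0.5,
) -> pd.DataFrame:
    """One {0,1} prediction per replicate × eligible endpoint.

    Replicate fingerprints are binarized and projected onto each model's
    kept bits; a replicate lacking a kept bit is a hard error naming the
    bit.  Ineligible models are excluded.
    """
    fpm = repset.fingerprints
    if fpm.mode_tag != "binary":
        fpm = binarize(fpm, binarize_threshold)
    bit_pos = {b: i for i, b in enumerate(fpm.bit_ids)}

    rows = []
    for ep_id, model in sorted(models.items()):
        if not model.eligible:
            continue
        missing = [b for b in model.kept_bits if b not in bit_pos]
        if missing:
            raise MissingBitError(
                f"feature {repset.feature_id}: replicate fingerprints lack "
                f"bit(s) required by endpoint {ep_id}: {missing[:5]}"
            )
        X = fpm.values[:, [bit_pos[b] for b in model.kept_bits]]
        preds = model.predict(X)
        for i, p in enumerate(preds):
            rows.append(
                {
                    "feature_id": repset.feature_id,
                    "replicate_index": i,
                    "spectrum_id": repset.spectrum_ids[i],
                    "candidate_rank": repset.candidate_ranks[i],
                    "endpoint_id": ep_id,
                    "pred": int(p),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "replicate_index", "spectrum_id",
                 "candidate_rank", "endpoint_id", "pred"],
    )


def vote(
    predictions: pd.DataFrame, feature_id: str, target_id: str
) -> FeatureVoteRecord:
    """Strict-majority vote over all replicate × endpoint predictions for
    one feature × target; an exact tie is nontoxic.  Votes are unweighted
    across spectra, candidate ranks, and endpoints."""
    if predictions.empty:
        raise PreconditionError(
            f"no predictions to vote on for {feature_id}/{target_id}"
        )
    n_votes = len(predictions)
    n_toxic = int(predictions["pred"].sum())
    return FeatureVoteRecord(
        feature_id=feature_id,
        target_id=target_id,
        n_votes=n_votes,
        n_toxic_votes=n_toxic,
        hitc=int(n_toxic > n_votes / 2),
        contributing_endpoints=sorted(predictions["endpoint_id"].unique()),
    )


def vote_feature(
    models: Mapping[str, EndpointModel],
    repset: ReplicateFingerprintSet,
    target_map: Mapping[str, str],
    binarize_threshold: float = 0.5,
) -> list[FeatureVoteRecord | tuple]:
    """Predict and vote one feature across all targets present in the map.

    Returns one FeatureVoteRecord per target with at least one eligible
    endpoint; targets without any eligible endpoint are reported as
    (feature_id, target_id, 'untested') sentinels by the assembler.
    """
    preds = predict_replicates(models, repset, binarize_threshold)
    records = []
    for target in sorted(set(target_map.values())):
        eps = [e for e, t in target_map.items()
               if t == target and e in models and models[e].eligible]
        if not eps:
            continue
        sub = preds[preds["endpoint_id"].isin(eps)]
        records.append(vote(sub, repset.feature_id, target))
    return records


def assemble_toxicity_fingerprint(
    feature_id: str,
    vote_records: Iterable[FeatureVoteRecord],
    targets: Sequence[str],
) -> ToxicityFingerprint:
    """Vector of per-target hit calls; targets with no vote record are
    marked untested."""
    by_target = {r.target_id: r.hitc for r in vote_records
                 if r.feature_id == feature_id}
    return ToxicityFingerprint(
        feature_id=feature_id,
        calls={t: by_target.get(t, UNTESTED) for t in targets},
    )


def votes_to_frame(records: Iterable[FeatureVoteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "target_id": r.target_id,
                "n_votes": r.n_votes,
                "n_toxic_votes": r.n_toxic_votes,
                "hitc": r.hitc,
                "contributing_endpoints": ";".join(
                    r.contributing_endpoints
                ),
            }
            for r in records
        ]
    )


def replicate_sets_to_frame(
    repsets: Iterable[ReplicateFingerprintSet],
) -> pd.DataFrame:
    """Long-format replicate table: feature_id, spectrum_id, candidate_rank
    followed by one column per bit."""
    frames = []
    for rs in repsets:
        df = rs.fingerprints.to_frame().drop(columns=["sample_id"])
        df.insert(0, "candidate_rank", rs.candidate_ranks)
        df.insert(0, "spectrum_id", rs.spectrum_ids)
        df.insert(0, "feature_id", rs.feature_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def replicate_sets_from_frame(
    df: pd.DataFrame,
    mode_tag: str = "probabilistic",
    max_candidates_per_spectrum: int = 10,
) -> list[ReplicateFingerprintSet]:
    bit_ids = [c for c in df.columns
               if c not in ("feature_id", "spectrum_id", "candidate_rank")]
    repsets = []
    for fid, grp in df.groupby("feature_id", sort=True):
        fpm = FingerprintMatrix(
            sample_ids=[f"{fid}#{i}" for i in range(len(grp))],
            bit_ids=bit_ids,
            values=grp[bit_ids].to_numpy(dtype=float),
            mode_tag=mode_tag,
        )
        repsets.append(
            ReplicateFingerprintSet(
                feature_id=str(fid),
                spectrum_ids=list(grp["spectrum_id"]),
                candidate_ranks=[int(r) for r in grp["candidate_rank"]],
                fingerprints=fpm,
                max_candidates_per_spectrum=max_candidates_per_spectrum,
            )
        )
    return repsets


def predict_compound_endpoint_calls(
    models: Mapping[str, EndpointModel],
    repsets: Iterable[ReplicateFingerprintSet],
    binarize_threshold: float = 0.5,
) -> pd.DataFrame:
    """Voted per-compound per-endpoint hit calls (replicate majority within
    each endpoint separately) — the unit compared against ground truth in
    validation."""
    rows = []
    for repset in repsets:
        preds = predict_replicates(models, repset, binarize_threshold)
        for ep, grp in preds.groupby("endpoint_id"):
            n = len(grp)
            n_tox = int(grp["pred"].sum())
            rows.append(
                {
                    "chemical_id": repset.feature_id,
                    "endpoint_id": ep,
                    "hitc_pred": int(n_tox > n / 2),
                    "n_votes": n,
                }
            )
    return pd.DataFrame(
        rows, columns=["chemical_id", "endpoint_id", "hitc_pred", "n_votes"]
    )


def validate_against_truth(
    voted_calls: pd.DataFrame,
    truth: pd.DataFrame,
    target_map: Mapping[str, str],
    train_compounds: set | None = None,
) -> pd.DataFrame:
    """Per-target mean balanced accuracy of voted calls against ground
    truth.

    ``voted_calls``: columns chemical_id, endpoint_id, hitc_pred.
    ``truth``: columns chemical_id, endpoint_id, hitc.  Every validation
    compound must be absent from every training set (hard leakage error
    otherwise).  Balanced accuracy is computed per endpoint over the
    compounds with both a prediction and a truth record, then averaged
    (unweighted) over each target's endpoints.
    """
    if train_compounds:
        offenders = set(voted_calls["chemical_id"]) & set(train_compounds)
        if offenders:
            raise LeakageError(offenders)

    merged = voted_calls.merge(
        truth, on=["chemical_id", "endpoint_id"], how="inner"
    )
    ep_rows = []
    for ep, grp in merged.groupby("endpoint_id"):
        m = metrics_from_confusion(confusion(grp["hitc"], grp["hitc_pred"]))
        ep_rows.append(
            {
                "endpoint_id": ep,
                "target_id": target_map.get(ep, ep),
                "balanced_accuracy": (
                    m.balanced_accuracy
                    if m.balanced_accuracy is not None else np.nan
                ),
                "n_compounds": len(grp),
            }
        )
    per_endpoint = pd.DataFrame(ep_rows)
    if per_endpoint.empty:
        return pd.DataFrame(
            columns=["target_id", "balanced_accuracy", "n_endpoints"]
        )
    per_target = (
        per_endpoint.groupby("target_id")
        .agg(
            balanced_accuracy=("balanced_accuracy", "mean"),
            n_endpoints=("endpoint_id", "count"),
        )
        .reset_index()
    )
    return per_target
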