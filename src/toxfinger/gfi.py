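"""Global feature importance via interpretable surrogate forests.

A random forest is trained on the same input bits as a trained endpoint
model but against that model's own predictions (not the ground-truth
labels): the surrogate approximates the black box, and its impurity-based
importances attribute the black box's behaviour to individual substructure
bits.  Surrogate fidelity (agreement rate with the black box on the
evaluation set) qualifies the attribution.  Across the endpoints of one
mechanistic target, bits are ranked by recurrence (membership in each
endpoint's top-k importances) combined with mean importance, yielding a
top-10 substructure (SMARTS) list per target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .endpoint_models import EndpointModel

FIDELITY_FLOOR = 0.8


@dataclass
class ImportanceTable:
    endpoint_id: str
    bit_ids: list
    importance: np.ndarray  # normalized, sums to 1
    surrogate_fidelity: float
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bit_id": self.bit_ids, "importance": self.importance}
        ).sort_values("importance", ascending=False).reset_index(drop=True)

    def top_bits(self, k: int) -> list:
        order = np.argsort(-self.importance, kind="stable")
        return [self.bit_ids[i] for i in order[:k]]


@dataclass
class SubstructureRanking:
    target_id: str
    table: pd.DataFrame  # bit_id, smarts, recurrence, mean_importance, score


def surrogate_importance(
    model: EndpointModel,
    X: np.ndarray,
    seed: int = 0,
    n_trees: int = 200,
) -> ImportanceTable:
    """Fit a surrogate forest on (X, black-box predictions) and return
    normalized impurity importances plus fidelity.

    A constant black box yields a zero-information surrogate: importances
    are reported uniform and the table is flagged 'degenerate'.  Tables
    with fidelity below 0.8 are flagged 'low_fidelity' but still returned.
    """
    X = np.asarray(X, dtype=float)
    y_bb = model.predict(X)
    flags: list[str] = []
    n_bits = X.shape[1]

    if len(np.unique(y_bb)) < 2:
        flags.append("degenerate")
        importance = np.full(n_bits, 1.0 / n_bits)
        fidelity = 1.0
    else:
        # half the features per split: concentrates importance on truly
        # predictive bits while still spreading it across co-informative
        # (correlated) bits
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1,
            max_features=0.5,
        )
        forest.fit(X, y_bb)
        fidelity = float(np.mean(forest.predict(X) == y_bb))
        importance = forest.feature_importances_.astype(float)
        total = importance.sum()
        importance = (
            importance / total if total > 0
            else np.full(n_bits, 1.0 / n_bits)
        )
        if fidelity < FIDELITY_FLOOR:
            flags.append("low_fidelity")

    return ImportanceTable(
        endpoint_id=model.endpoint_id,
        bit_ids=list(model.kept_bits) if model.kept_bits
        else [f"bit{i}" for i in range(n_bits)],
        importance=importance,
        surrogate_fidelity=fidelity,
        flags=flags,
    )


def rank_substructures(
    tables: Sequence[ImportanceTable],
    smarts: Mapping[str, str] | None = None,
    target_id: str = "",
    top_k: int = 25,
    top_n: int = 10,
) -> SubstructureRanking:
    """Rank substructure bits for one mechanistic target.

    Recurrence of a bit = the number of endpoint tables in which it ranks
    within that endpoint's top-k importances; score = recurrence × mean
    importance over the endpoints where it recurs.  The top-n bits by score
    are returned (ties broken by recurrence, then bit id); fewer than n
    distinct bits yield a shorter table, never padding.
    """
    if not tables:
        raise ValueError("at least one importance table is required")
    smarts = dict(smarts or {})

    recur: dict = {}
    imp_values: dict = {}
    for table in tables:
        imp = dict(zip(table.bit_ids, table.importance))
        for bit in table.top_bits(top_k):
            recur[bit] = recur.get(bit, 0) + 1
            imp_values.setdefault(bit, []).append(imp[bit])

    rows = []
    for bit, r in recur.items():
        mean_imp = float(np.mean(imp_values[bit]))
        rows.append(
            {
                "bit_id": bit,
                "smarts": smarts.get(bit, ""),
                "recurrence": r,
                "mean_importance": mean_imp,
                "score": r * mean_imp,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["bit_id", "smarts", "recurrence", "mean_importance",
                 "score"],
    )
    df = df.sort_values(
        ["score", "recurrence", "bit_id"], ascending=[False, False, True]
    ).head(top_n).reset_index(drop=True)
    return SubstructureRanking(target_id=target_id, table=df)
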