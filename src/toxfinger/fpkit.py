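"""Molecular-fingerprint preprocessing and similarity metrics.

Fingerprints are sample×bit matrices, either binary (presence/absence of a
substructure, optionally named by a SMARTS pattern) or probabilistic
(posterior Platt probabilities from a spectrum-based predictor).
Probabilistic matrices are binarized at 0.5 (<=0.50 -> 0, >0.50 -> 1).
For modeling, bits with minority-class frequency below 5% or absolute
Pearson correlation above 95% with an earlier kept bit are removed; the
filter is fit on training data only and replayed elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, PreconditionError


@dataclass
class FingerprintMatrix:
    """Sample × bit matrix with ordered identifiers.

    ``mode_tag`` is 'binary' ({0,1} values) or 'probabilistic' ([0,1]
    values).  ``smarts`` optionally maps bit ids to SMARTS strings.
    """

    sample_ids: list
    bit_ids: list
    values: np.ndarray
    mode_tag: str = "binary"
    smarts: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.bit_ids)):
            raise PreconditionError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.bit_ids)} bits"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise PreconditionError("duplicate sample ids")
        if len(set(self.bit_ids)) != len(self.bit_ids):
            raise PreconditionError("duplicate bit ids")
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise PreconditionError("fingerprint values outside [0, 1]")
        if self.mode_tag == "binary" and self.values.size:
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise PreconditionError(
                    "binary matrix contains non-{0,1} values"
                )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.bit_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode_tag: str = "binary",
                   smarts: dict | None = None) -> "FingerprintMatrix":
        bit_ids = [c for c in df.columns if c != "sample_id"]
        return cls(
            sample_ids=list(df["sample_id"]),
            bit_ids=bit_ids,
            values=df[bit_ids].to_numpy(dtype=float),
            mode_tag=mode_tag,
            smarts=smarts or {},
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path,
                 mode_tag: str = "binary") -> "FingerprintMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"), mode_tag=mode_tag)

    def subset_samples(self, indices: Sequence[int]) -> "FingerprintMatrix":
        return FingerprintMatrix(
            sample_ids=[self.sample_ids[i] for i in indices],
            bit_ids=list(self.bit_ids),
            values=self.values[list(indices)].copy(),
            mode_tag=self.mode_tag,
            smarts=dict(self.smarts),
        )

    def select_bits(self, bits: Sequence) -> "FingerprintMatrix":
        missing = [b for b in bits if b not in self.bit_ids]
        if missing:
            raise AlignmentError(f"bits not present in matrix: {missing[:5]}")
        idx = [self.bit_ids.index(b) for b in bits]
        return FingerprintMatrix(
            sample_ids=list(self.sample_ids),
            bit_ids=list(bits),
            values=self.values[:, idx].copy(),
            mode_tag=self.mode_tag,
            smarts={b: self.smarts[b] for b in bits if b in self.smarts},
        )


@dataclass
class BitFilterReport:
    kept_bits: list
    dropped_low_variability: list
    dropped_correlated: list  # (dropped_bit, kept_partner) pairs

    def check_partition(self, original_bits: Sequence) -> bool:
        seen = (
            set(self.kept_bits)
            | set(self.dropped_low_variability)
            | {d for d, _ in self.dropped_correlated}
        )
        return seen == set(original_bits) and len(seen) == (
            len(self.kept_bits)
            + len(self.dropped_low_variability)
            + len(self.dropped_correlated)
        )


def binarize(matrix: FingerprintMatrix,
             threshold: float = 0.5) -> FingerprintMatrix:
    """Binarize probabilistic bits: value <= threshold -> 0, > threshold -> 1.

    Idempotent; already-binary inputs pass through unchanged (0 <= 0.5 and
    1 > 0.5)."""
    return FingerprintMatrix(
        sample_ids=list(matrix.sample_ids),
        bit_ids=list(matrix.bit_ids),
        values=(matrix.values > threshold).astype(float),
        mode_tag="binary",
        smarts=dict(matrix.smarts),
    )


def filter_bits(
    matrix: FingerprintMatrix,
    min_variability: float = 0.05,
    max_correlation: float = 0.95,
) -> tuple[FingerprintMatrix, BitFilterReport]:
    """Drop near-constant and highly intercorrelated bits.

    Stage 1 removes bits whose minority-value frequency is strictly below
    ``min_variability``.  Stage 2 scans the survivors in column order and
    greedily drops any bit whose |Pearson r| with an already-kept bit is
    strictly above ``max_correlation`` (first kept bit wins; deterministic
    and order-stable).  An all-dropped result is legal.
    """
    if matrix.mode_tag != "binary":
        raise PreconditionError("filter_bits requires a binary matrix")
    n = len(matrix.sample_ids)
    if n < 2:
        raise PreconditionError("need at least 2 samples to filter bits")

    vals = matrix.values
    freq_one = vals.mean(axis=0)
    minority = np.minimum(freq_one, 1.0 - freq_one)
    low_var_mask = minority < min_variability
    dropped_low = [b for b, m in zip(matrix.bit_ids, low_var_mask) if m]

    survivors = [i for i, m in enumerate(low_var_mask) if not m]
    kept: list[int] = []       # original column indices
    kept_pos: list[int] = []   # positions within `survivors`
    dropped_corr: list[tuple] = []
    if survivors:
        sub = vals[:, survivors]
        centered = sub - sub.mean(axis=0)
        norms = np.sqrt((centered ** 2).sum(axis=0))
        for j, col_idx in enumerate(survivors):
            if not kept:
                kept.append(col_idx)
                kept_pos.append(j)
                continue
            with np.errstate(invalid="ignore"):
                r = (centered[:, kept_pos].T @ centered[:, j]) / (
                    norms[kept_pos] * norms[j]
                )
            over = np.abs(r) > max_correlation
            if over.any():
                partner = kept[int(np.argmax(over))]
                dropped_corr.append(
                    (matrix.bit_ids[col_idx], matrix.bit_ids[partner])
                )
            else:
                kept.append(col_idx)
                kept_pos.append(j)

    kept_bits = [matrix.bit_ids[i] for i in kept]
    report = BitFilterReport(
        kept_bits=kept_bits,
        dropped_low_variability=dropped_low,
        dropped_correlated=dropped_corr,
    )
    reduced = FingerprintMatrix(
        sample_ids=list(matrix.sample_ids),
        bit_ids=kept_bits,
        values=vals[:, kept].copy(),
        mode_tag="binary",
        smarts={b: matrix.smarts[b] for b in kept_bits if b in matrix.smarts},
    )
    return reduced, report


def tanimoto(a: Sequence[float], b: Sequence[float]) -> float:
    """Tanimoto (Jaccard) coefficient |a AND b| / |a OR b| for binary
    vectors; defined as 1 when both vectors are all-zero."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise PreconditionError(
            f"length mismatch: {a.shape} vs {b.shape}"
        )
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def fingerprint_accuracy(
    pred: FingerprintMatrix, true: FingerprintMatrix
) -> tuple[pd.DataFrame, dict]:
    """Per-sample agreement between predicted and true binary fingerprints.

    For every sample a confusion over bits yields balanced accuracy and
    sensitivity, plus the Tanimoto coefficient; pooled values are unweighted
    means over samples (components with zero denominator are excluded from
    the pooled mean).
    """
    if pred.sample_ids != true.sample_ids or pred.bit_ids != true.bit_ids:
        raise AlignmentError(
            "predicted and true fingerprint matrices must share sample and "
            "bit ids in the same order"
        )
    rows = []
    for i, sid in enumerate(pred.sample_ids):
        p = pred.values[i].astype(bool)
        t = true.values[i].astype(bool)
        tp = int(np.sum(p & t))
        fn = int(np.sum(~p & t))
        tn = int(np.sum(~p & ~t))
        fp = int(np.sum(p & ~t))
        sens = tp / (tp + fn) if (tp + fn) else np.nan
        spec = tn / (tn + fp) if (tn + fp) else np.nan
        bal = np.nanmean([sens, spec]) if not (
            np.isnan(sens) and np.isnan(spec)
        ) else np.nan
        rows.append(
            {
                "sample_id": sid,
                "balanced_accuracy": bal,
                "sensitivity": sens,
                "tanimoto": tanimoto(p, t),
            }
        )
    per_sample = pd.DataFrame(rows)
    pooled = {
        k: float(np.nanmean(per_sample[k]))
        for k in ("balanced_accuracy", "sensitivity", "tanimoto")
    }
    return per_sample, pooled


def write_smarts_sidecar(smarts: dict, path: str | Path) -> None:
    pd.DataFrame(
        sorted(smarts.items()), columns=["bit_id", "smarts"]
    ).to_csv(path, sep="\t", index=False)


def read_smarts_sidecar(path: str | Path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["bit_id"], df["smarts"]))
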