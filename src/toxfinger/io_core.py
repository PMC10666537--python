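"""Readers/writers for the pipeline's tabular formats, configuration and
run manifests.

All tables are UTF-8, tab-separated, '.' decimal, with a mandatory header
row.  Identifiers (chemical ids, endpoint ids, NTS feature ids) are opaque
strings and are never parsed for meaning.  Concentrations are always stored
as log10 micromolar, following the high-throughput screening convention for
assays run over roughly 0.1–100 uM.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, RowError

DOSE_RESPONSE_COLUMNS = [
    "chemical_id",
    "endpoint_id",
    "log10_conc_uM",
    "response",
    "is_baseline",
]

HITCALL_COLUMNS = [
    "chemical_id",
    "endpoint_id",
    "hitc",
    "ac50",
    "acc",
    "winning_model",
    "n_flags",
    "burst_flag",
]


@dataclass
class RunConfig:
    """Global thresholds and tuning knobs for one pipeline run.

    Defaults follow standard high-throughput screening practice: efficacy cutoff at
    ``cutoff_multiplier``×BMAD where BMAD is ``bmad_multiplier``×MAD of the
    baseline; fingerprint binarization at 0.5; bit filters at <5% variability
    and >95% correlation; 80/20 train/test split; random grid search of 50
    draws with early stopping at 20; voting eligibility gate at 0.65 test
    sensitivity and precision; NTS componentization at 5 ppm / 0.5 min with
    quality filters (peak shape >0.8, S/N >10, 5-fold blank ratio, 600 Da
    precursor cap); endpoint inclusion above 500 chemicals and 0.1% actives.
    """

    seed: int = 0
    cutoff_multiplier: float = 6.0
    bmad_multiplier: float = 3.0
    binarize_threshold: float = 0.5
    min_bit_variability: float = 0.05
    max_bit_correlation: float = 0.95
    test_fraction: float = 0.2
    cv_folds: int = 10
    cv_repeats: int = 1
    grid_draws: int = 50
    early_stop: int = 20
    eligibility_threshold: float = 0.65
    max_candidates_per_spectrum: int = 10
    ppm_tol: float = 5.0
    rt_tol_min: float = 0.5
    spectral_match_cutoff: float = 85.0
    peak_shape_min: float = 0.8
    sn_min: float = 10.0
    blank_ratio_min: float = 5.0
    precursor_max_da: float = 600.0
    min_chems_per_endpoint: int = 500
    min_active_fraction: float = 0.001
    max_flags: int = 3
    model_family: str = "xgboost"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        fractions = {
            "binarize_threshold": self.binarize_threshold,
            "min_bit_variability": self.min_bit_variability,
            "max_bit_correlation": self.max_bit_correlation,
            "test_fraction": self.test_fraction,
            "min_active_fraction": self.min_active_fraction,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        for name in ("cutoff_multiplier", "bmad_multiplier", "ppm_tol",
                     "rt_tol_min", "sn_min", "blank_ratio_min",
                     "precursor_max_da"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.grid_draws < 1 or self.early_stop < 1:
            raise ConfigError("grid_draws and early_stop must be >= 1")

    @classmethod
    def retrain_mode(cls, **overrides) -> "RunConfig":
        """Preset mirroring the retraining configuration: 5-fold CV with a
        20-draw random grid search and early stopping at 20."""
        params = dict(cv_folds=5, grid_draws=20, early_stop=20)
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable hash of the full configuration (order-independent)."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_dose_response(path: str | Path) -> list:
    """Read a long-format dose-response table into one series per
    (chemical, endpoint).

    Expected columns: chemical_id, endpoint_id, log10_conc_uM, response,
    is_baseline.  Baseline rows (assay controls) are collected into
    ``baseline_responses`` of the matching series; duplicated concentration
    rows are preserved as replicates (medians are taken downstream, at fit
    time).  Total row count is conserved across the split.
    """
    from .toxcurate import DoseResponseSeries  # avoid cycle at import time

    raw = _read_table(path)
    for col in DOSE_RESPONSE_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"missing required column '{col}' in {path}")

    is_base = raw["is_baseline"].str.strip().str.lower().isin(
        {"1", "true", "yes"}
    ).to_numpy()
    concs = np.empty(len(raw))
    resps = np.empty(len(raw))
    for i, (c, r) in enumerate(zip(raw["log10_conc_uM"], raw["response"])):
        try:
            # baseline rows carry no concentration; blank is allowed there
            concs[i] = math.nan if (is_base[i] and not c.strip()) \
                else float(c)
            resps[i] = float(r)
        except ValueError:
            # header is line 1, data starts at line 2
            raise RowError(i + 2, f"non-numeric value in row: conc={c!r} "
                                  f"response={r!r}") from None

    series: list = []
    frame = raw[["chemical_id", "endpoint_id"]].copy()
    frame["conc"] = concs
    frame["resp"] = resps
    frame["base"] = is_base
    for (chem, ep), grp in frame.groupby(
        ["chemical_id", "endpoint_id"], sort=True
    ):
        test = grp[~grp["base"]]
        base = grp[grp["base"]]
        series.append(
            DoseResponseSeries(
                chemical_id=chem,
                endpoint_id=ep,
                concs=test["conc"].to_numpy(),
                responses=test["resp"].to_numpy(),
                baseline_responses=base["resp"].to_numpy(),
                validate=False,
            )
        )
    return series


def write_dose_response(series: list, path: str | Path) -> None:
    """Serialize series back to the long-format dialect (baseline rows last
    within each series)."""
    rows = []
    for s in series:
        for c, r in zip(s.concs, s.responses):
            rows.append((s.chemical_id, s.endpoint_id, c, r, False))
        for r in s.baseline_responses:
            rows.append((s.chemical_id, s.endpoint_id, math.nan, r, True))
    df = pd.DataFrame(rows, columns=DOSE_RESPONSE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_hitcalls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("chemical_id", "endpoint_id", "hitc"):
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}' in {path}")
    return df


def write_hitcalls(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    """Run provenance: seed, config hash, input checksums, per-stage row
    counts.  Reruns with the same seed and inputs produce identical
    manifests."""

    seed: int
    config_hash: str
    inputs: dict = field(default_factory=dict)     # path -> sha256
    row_counts: dict = field(default_factory=dict)  # stage -> count

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "inputs": dict(sorted(self.inputs.items())),
            "row_counts": dict(sorted(self.row_counts.items())),
        }


def write_manifest(
    config: RunConfig,
    stage_outputs: Mapping[str, int],
    path: str | Path,
    input_paths: Mapping[str, str | Path] | None = None,
) -> Manifest:
    """Write a JSON run manifest recording seed, config hash, input
    checksums and row counts per stage."""
    inputs = {
        name: file_checksum(p) for name, p in (input_paths or {}).items()
    }
    manifest = Manifest(
        seed=config.seed,
        config_hash=config.config_hash(),
        inputs=inputs,
        row_counts=dict(stage_outputs),
    )
    Path(path).write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True),
        encoding="utf-8",
    )
    return manifest


def read_manifest(path: str | Path) -> Manifest:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return Manifest(
        seed=data["seed"],
        config_hash=data["config_hash"],
        inputs=data.get("inputs", {}),
        row_counts=data.get("row_counts", {}),
    )
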