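"""Prioritization of aligned MS1 feature tables for toxicity prediction.

Aligned nontarget-screening feature lists contain redundant signals
(adducts of the same compound) and low-quality peaks.  This module
componentizes features into molecular ions ([M+H]+ / [M−H]−) by neutral
mass (5 ppm) and retention time (0.5 min) agreement, removes annotated
adducts, assigns identification confidence levels (1 = confirmed by
reference standard from a target list; 2a = probable via spectral-library
match at >= 85%; 3 = tentative, partial spectral evidence), and applies
quality filters: unidentified signals need Gaussian peak shape > 0.8 and
signal-to-noise > 10; all features need a 5-fold sample/blank area ratio
and a neutral precursor mass below 600 Da.  Identified features bypass the
shape/SN filter, mirroring the filter ordering in which quality screens are
applied only to the remaining unidentified signals.
"""

from __future__ import annotations

import importlib.resources
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

PROTON = 1.007276

MOLECULAR_IONS = {"pos": "[M+H]+", "neg": "[M-H]-"}

FEATURE_COLUMNS = [
    "feature_id", "mz", "rt", "max_sample_area", "blank_area",
    "peak_shape", "sn", "adduct", "mode", "spectral_match_score",
    "target_match",
]


def load_adduct_table() -> pd.DataFrame:
    """Built-in adduct mass-offset table (mz = neutral mass + offset,
    singly charged)."""
    ref = importlib.resources.files("toxfinger") / "data" / "adducts.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def neutral_mass(mz: float, adduct: str | None, mode: str,
                 offsets: Mapping[str, float]) -> float | None:
    """Neutral-mass estimate; None for unknown adduct annotations.

    Unannotated features are assumed to be the molecular ion of their
    ionization mode ([M+H]+ or [M−H]−)."""
    if adduct is None or (isinstance(adduct, float) and np.isnan(adduct)) \
            or adduct == "":
        adduct = MOLECULAR_IONS[mode]
    if adduct not in offsets:
        return None
    return float(mz) - offsets[adduct]


def componentize(
    features: pd.DataFrame,
    ppm_tol: float = 5.0,
    rt_tol: float = 0.5,
    adduct_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group co-eluting features whose neutral masses agree within ppm_tol
    and |ΔRT| <= rt_tol into one component each, represented by its
    molecular-ion member; annotated adduct members are dropped.

    Features with an unknown adduct annotation pass through ungrouped with
    a warning.  Input order does not affect the result (features are
    processed in neutral-mass order).
    """
    if adduct_table is None:
        adduct_table = load_adduct_table()
    offsets = dict(zip(adduct_table["adduct"], adduct_table["mass_offset"]))

    df = features.copy()
    neutral = []
    for mz, adduct, mode in zip(df["mz"], df.get("adduct"), df["mode"]):
        neutral.append(neutral_mass(mz, adduct, mode, offsets))
    df["neutral_mass"] = neutral

    unknown = df["neutral_mass"].isna()
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} feature(s) with unknown adduct "
            "annotation passed through ungrouped"
        )
    passthrough = df[unknown]
    known = df[~unknown].sort_values(
        ["neutral_mass", "rt", "feature_id"]
    ).reset_index(drop=True)

    # single-linkage grouping along the mass axis with an RT gate
    component_ids = np.full(len(known), -1, dtype=int)
    next_comp = 0
    for i in range(len(known)):
        if component_ids[i] >= 0:
            continue
        component_ids[i] = next_comp
        stack = [i]
        while stack:
            a = stack.pop()
            ma, ra = known.loc[a, "neutral_mass"], known.loc[a, "rt"]
            for b in range(len(known)):
                if component_ids[b] >= 0:
                    continue
                mb = known.loc[b, "neutral_mass"]
                if abs(mb - ma) / ma * 1e6 > ppm_tol:
                    continue
                if abs(known.loc[b, "rt"] - ra) > rt_tol:
                    continue
                component_ids[b] = next_comp
                stack.append(b)
        next_comp += 1
    known = known.assign(component=component_ids)

    representatives = []
    for _, grp in known.groupby("component"):
        is_mol_ion = grp.apply(
            lambda r: (pd.isna(r.get("adduct")) or r.get("adduct") == ""
                       or r.get("adduct") == MOLECULAR_IONS[r["mode"]]),
            axis=1,
        )
        if is_mol_ion.any():
            representatives.append(grp[is_mol_ion].iloc[0])
        # a component of only annotated adducts has no molecular ion to
        # represent it: the adduct members are removed
    out = pd.DataFrame(representatives)
    out = pd.concat([out, passthrough], ignore_index=True)
    return out.sort_values("feature_id").reset_index(drop=True)


def assign_id_level(
    features: pd.DataFrame,
    spectral_match_cutoff: float = 85.0,
) -> pd.DataFrame:
    """Identification confidence levels.

    Level 1: matched to a target list with reference material (boolean
    ``target_match``), taking precedence over any spectral score.  Level
    2a: spectral library match score >= cutoff (inclusive).  Level 3: any
    non-missing sub-cutoff spectral score (partial match evidence).
    Otherwise 'none'.
    """
    df = features.copy()
    levels = []
    for tm, score in zip(
        df.get("target_match", [False] * len(df)),
        df.get("spectral_match_score", [np.nan] * len(df)),
    ):
        if bool(tm) and not pd.isna(tm):
            levels.append("1")
        elif not pd.isna(score) and score >= spectral_match_cutoff:
            levels.append("2a")
        elif not pd.isna(score):
            levels.append("3")
        else:
            levels.append("none")
    df["id_level"] = levels
    return df


def quality_filter(
    features: pd.DataFrame,
    peak_shape_min: float = 0.8,
    sn_min: float = 10.0,
    blank_ratio_min: float = 5.0,
    precursor_max_da: float = 600.0,
) -> pd.DataFrame:
    """Retention decision per feature with a reason code for every drop.

    Identified features (levels 1/2a/3) bypass the shape/SN screen;
    unidentified features are retained only with peak shape strictly above
    ``peak_shape_min`` AND S/N strictly above ``sn_min``.  All features
    must satisfy max_sample_area / blank_area >= ``blank_ratio_min`` and a
    neutral precursor mass strictly below ``precursor_max_da``.
    """
    df = features.copy()
    if "id_level" not in df.columns:
        df = assign_id_level(df)
    mass = df["neutral_mass"] if "neutral_mass" in df.columns else df["mz"]

    retained = []
    reasons = []
    for i, row in df.iterrows():
        blank = row.get("blank_area", 0.0)
        ratio = np.inf if (pd.isna(blank) or blank <= 0) \
            else row["max_sample_area"] / blank
        identified = row["id_level"] in ("1", "2a", "3")
        if not pd.isna(mass.loc[i]) and mass.loc[i] >= precursor_max_da:
            retained.append(False)
            reasons.append("precursor_mass")
        elif ratio < blank_ratio_min:
            retained.append(False)
            reasons.append("blank_ratio")
        elif not identified and not (row["peak_shape"] > peak_shape_min):
            retained.append(False)
            reasons.append("peak_shape")
        elif not identified and not (row["sn"] > sn_min):
            retained.append(False)
            reasons.append("signal_to_noise")
        else:
            retained.append(True)
            reasons.append("identified" if identified else "quality_pass")
    df["retained"] = retained
    df["retained_reason"] = reasons
    return df


def prioritize(
    features: pd.DataFrame,
    ppm_tol: float = 5.0,
    rt_tol: float = 0.5,
    spectral_match_cutoff: float = 85.0,
    peak_shape_min: float = 0.8,
    sn_min: float = 10.0,
    blank_ratio_min: float = 5.0,
    precursor_max_da: float = 600.0,
) -> pd.DataFrame:
    """Full prioritization: componentize, assign ID levels, quality-filter."""
    comp = componentize(features, ppm_tol=ppm_tol, rt_tol=rt_tol)
    comp = assign_id_level(comp, spectral_match_cutoff=spectral_match_cutoff)
    return quality_filter(
        comp,
        peak_shape_min=peak_shape_min,
        sn_min=sn_min,
        blank_ratio_min=blank_ratio_min,
        precursor_max_da=precursor_max_da,
    )
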