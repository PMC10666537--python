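"""Curation of multi-concentration screening data into binary hit calls.

The workflow mirrors the standard high-throughput screening pipeline for
concentration–response data: a baseline noise level (BMAD = 3×MAD of the
baseline/control responses) sets an efficacy cutoff (6×BMAD by default);
three curve models — constant (pure noise), hill, and gain-loss — are fit
to per-concentration median responses by least squares; the winner is
picked by AIC; and an active (toxic) call requires a hill or gain-loss
winner whose modeled top AND at least one concentration median exceed the
cutoff.  Points of departure are the AC50 (curve midpoint location) and the
ACC (lowest concentration at which the winning curve crosses the cutoff).

Downstream filters demote likely false positives: a caution-flag count
threshold, and a cytotoxicity-burst filter in a strict (+CTB) or mild
(−CTB) variant.  Finally, endpoints are selected for modeling (more than
500 chemicals and more than 0.1% actives) and endpoints sharing a
mechanistic target are concatenated by an OR rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .errors import (
    ConfigError,
    DegenerateAssayError,
    MappingError,
    PreconditionError,
)

RSS_FLOOR = 1e-12

# parameter bounds for curve fitting: slopes within [0.3, 8], locations
# within the tested concentration range +/- 2 log units
SLOPE_BOUNDS = (0.3, 8.0)
LOC_MARGIN = 2.0


@dataclass
class DoseResponseSeries:
    """One chemical × endpoint concentration/response record.

    Concentrations are log10 uM; ``responses`` may contain replicates per
    concentration.  ``baseline_responses`` hold assay control measurements
    used for the BMAD noise estimate.
    """

    chemical_id: str
    endpoint_id: str
    concs: np.ndarray
    responses: np.ndarray
    baseline_responses: np.ndarray
    validate: bool = True

    def __post_init__(self):
        self.concs = np.asarray(self.concs, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.baseline_responses = np.asarray(
            self.baseline_responses, dtype=float
        )
        if self.validate:
            self.check()

    def check(self) -> None:
        if len(self.concs) != len(self.responses):
            raise PreconditionError("concs and responses differ in length")
        if len(self.concs) < 4:
            raise PreconditionError("need at least 4 response points")
        if len(self.baseline_responses) == 0:
            raise PreconditionError("baseline_responses must be non-empty")

    def conc_medians(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique concentrations (sorted) and the median response at each."""
        concs = np.unique(self.concs)
        meds = np.array(
            [np.median(self.responses[self.concs == c]) for c in concs]
        )
        return concs, meds


@dataclass
class CurveFit:
    model: str  # constant | hill | gainloss
    tp: float = 0.0
    ga: float = math.nan
    gw: float = math.nan
    la: float = math.nan
    lw: float = math.nan
    rss: float = math.nan
    aic: float = math.nan
    n_params: int = 1
    success: bool = True


@dataclass
class HitCall:
    chemical_id: str
    endpoint_id: str
    hitc: int
    cutoff: float
    bmad: float
    ac50: float | None = None
    acc: float | None = None
    winning_model: str = "constant"
    n_flags: int = 0
    burst_flag: str = "none"
    note: str = ""


def compute_bmad(baseline_responses: Sequence[float],
                 bmad_multiplier: float = 3.0) -> float:
    """Baseline median absolute deviation: 3 × median(|x − median(x)|)."""
    x = np.asarray(baseline_responses, dtype=float)
    if x.size == 0:
        raise PreconditionError("baseline_responses is empty")
    return float(bmad_multiplier * np.median(np.abs(x - np.median(x))))


LN10 = math.log(10.0)


def _gain_term(x, ga, gw):
    # overflow-safe 1 / (1 + 10^((ga - x) gw))
    from scipy.special import expit

    return expit(-(ga - np.asarray(x, dtype=float)) * gw * LN10)


def _loss_term(x, la, lw):
    from scipy.special import expit

    return expit(-(np.asarray(x, dtype=float) - la) * lw * LN10)


def hill_curve(x, tp, ga, gw):
    """Gain hill: f(x) = tp / (1 + 10^((ga − x)·gw)); x, ga in log10 uM."""
    return tp * _gain_term(x, ga, gw)


def gainloss_curve(x, tp, ga, gw, la, lw):
    """Product of the hill gain term with a mirrored loss term."""
    return tp * _gain_term(x, ga, gw) * _loss_term(x, la, lw)


def _aic(rss: float, n: int, n_params: int) -> float:
    return n * math.log(max(rss, RSS_FLOOR) / n) + 2 * n_params


def _hill_residual_jac(concs, meds):
    def residual(p):
        return hill_curve(concs, *p) - meds

    def jac(p):
        tp, ga, gw = p
        g = _gain_term(concs, ga, gw)
        dg = g * (1.0 - g) * LN10
        return np.column_stack([g, -tp * dg * gw, -tp * dg * (ga - concs)])

    return residual, jac


def _gainloss_residual_jac(concs, meds):
    def residual(p):
        return gainloss_curve(concs, *p) - meds

    def jac(p):
        tp, ga, gw, la, lw = p
        g = _gain_term(concs, ga, gw)
        l = _loss_term(concs, la, lw)
        dg = g * (1.0 - g) * LN10
        dl = l * (1.0 - l) * LN10
        return np.column_stack([
            g * l,
            -tp * dg * gw * l,
            -tp * dg * (ga - concs) * l,
            tp * g * dl * lw,
            -tp * g * dl * (concs - la),
        ])

    return residual, jac


def _fit_hill(concs, meds):
    lo, hi = concs.min() - LOC_MARGIN, concs.max() + LOC_MARGIN
    top0 = float(np.max(np.abs(meds))) or 1.0
    bounds = (
        [0.0, lo, SLOPE_BOUNDS[0]],
        [5.0 * top0 + 1.0, hi, SLOPE_BOUNDS[1]],
    )
    residual, jac = _hill_residual_jac(concs, meds)
    # hill least squares is multi-modal: 5 starts with the midpoint guess
    # swept across the tested range
    best = None
    for q in (0.2, 0.35, 0.5, 0.65, 0.8):
        x0 = [top0, float(np.quantile(concs, q)), 1.0]
        try:
            res = least_squares(residual, x0, jac=jac, bounds=bounds,
                                method="trf", max_nfev=50)
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        return None
    rss, (tp, ga, gw) = best
    return CurveFit("hill", tp=float(tp), ga=float(ga), gw=float(gw),
                    rss=rss, aic=_aic(rss, len(meds), 4), n_params=4)


def _fit_gainloss(concs, meds):
    lo, hi = concs.min() - LOC_MARGIN, concs.max() + LOC_MARGIN
    top0 = float(np.max(np.abs(meds))) or 1.0
    bounds = (
        [0.0, lo, SLOPE_BOUNDS[0], lo, SLOPE_BOUNDS[0]],
        [5.0 * top0 + 1.0, hi, SLOPE_BOUNDS[1], hi, SLOPE_BOUNDS[1]],
    )
    residual, jac = _gainloss_residual_jac(concs, meds)
    best = None
    for qg, ql in ((0.2, 0.8), (0.35, 0.8), (0.5, 0.9), (0.3, 0.6),
                   (0.2, 0.95)):
        x0 = [2.0 * top0, float(np.quantile(concs, qg)), 1.0,
              float(np.quantile(concs, ql)), 1.0]
        try:
            res = least_squares(residual, x0, jac=jac, bounds=bounds,
                                method="trf", max_nfev=60)
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        return None
    rss, (tp, ga, gw, la, lw) = best
    return CurveFit("gainloss", tp=float(tp), ga=float(ga), gw=float(gw),
                    la=float(la), lw=float(lw),
                    rss=rss, aic=_aic(rss, len(meds), 6), n_params=6)


def fit_models(series: DoseResponseSeries) -> tuple[dict, CurveFit | None]:
    """Fit constant, hill, and gain-loss models to per-concentration median
    responses and pick the AIC winner (ties toward fewer parameters).

    A model whose optimizer fails is excluded from the contest with a
    warning; if every model fails the winner is ``None`` (series marked
    unfittable by the caller).
    """
    concs, meds = series.conc_medians()
    n = len(meds)

    fits: dict[str, CurveFit] = {}
    rss_const = float(np.sum(meds ** 2))  # constant model: response == 0
    fits["constant"] = CurveFit("constant", tp=0.0, rss=rss_const,
                                aic=_aic(rss_const, n, 1), n_params=1)
    for name, fitter in (("hill", _fit_hill), ("gainloss", _fit_gainloss)):
        fit = fitter(concs, meds)
        if fit is None:
            warnings.warn(
                f"{name} fit failed for {series.chemical_id}/"
                f"{series.endpoint_id}; excluded from model contest"
            )
        else:
            fits[name] = fit

    if not fits:
        return fits, None
    winner = min(fits.values(), key=lambda f: (f.aic, f.n_params))
    return fits, winner


def acc_hill(tp: float, ga: float, gw: float, cutoff: float) -> float | None:
    """Analytic inversion of the hill curve at the cutoff response:
    acc = ga − log10(tp/cutoff − 1)/gw.  None when the curve never reaches
    the cutoff (tp <= cutoff)."""
    if tp <= cutoff:
        return None
    return ga - math.log10(tp / cutoff - 1.0) / gw


def _acc_gainloss(fit: CurveFit, cutoff: float,
                  conc_range: tuple[float, float]) -> float | None:
    lo = conc_range[0] - LOC_MARGIN
    hi = conc_range[1] + LOC_MARGIN
    xs = np.linspace(lo, hi, 2000)
    ys = gainloss_curve(xs, fit.tp, fit.ga, fit.gw, fit.la, fit.lw) - cutoff
    for i in range(len(xs) - 1):
        if ys[i] <= 0.0 <= ys[i + 1] or ys[i] >= 0.0 >= ys[i + 1]:
            if ys[i] == 0.0:
                return float(xs[i])
            return float(brentq(
                lambda x: gainloss_curve(
                    x, fit.tp, fit.ga, fit.gw, fit.la, fit.lw) - cutoff,
                xs[i], xs[i + 1],
            ))
    return None


def call_hit(series: DoseResponseSeries, winner: CurveFit | None,
             cutoff: float, bmad: float | None = None,
             n_flags: int = 0) -> HitCall:
    """Apply the hit rule: active iff the winner is hill or gain-loss AND
    both the modeled top and at least one concentration median response
    exceed the efficacy cutoff.  Active calls carry AC50 (= curve midpoint
    location ga) and ACC (lowest concentration where the winning curve
    equals the cutoff)."""
    if cutoff <= 0:
        raise DegenerateAssayError(
            f"cutoff must be positive, got {cutoff}; a non-positive cutoff "
            "would call every series active"
        )
    if bmad is None:
        bmad = compute_bmad(series.baseline_responses)
    base = dict(chemical_id=series.chemical_id,
                endpoint_id=series.endpoint_id,
                cutoff=cutoff, bmad=bmad, n_flags=n_flags)
    if winner is None:
        return HitCall(hitc=0, winning_model="unfittable",
                       note="all model fits failed", **base)

    _, meds = series.conc_medians()
    active = (
        winner.model in ("hill", "gainloss")
        and winner.tp > cutoff
        and float(np.max(meds)) > cutoff
    )
    if not active:
        return HitCall(hitc=0, winning_model=winner.model, **base)

    if winner.model == "hill":
        acc = acc_hill(winner.tp, winner.ga, winner.gw, cutoff)
    else:
        acc = _acc_gainloss(
            winner, cutoff,
            (float(series.concs.min()), float(series.concs.max())),
        )
    return HitCall(hitc=1, ac50=winner.ga, acc=acc,
                   winning_model=winner.model, **base)


def hitcalls_to_frame(calls: Iterable[HitCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chemical_id": c.chemical_id,
                "endpoint_id": c.endpoint_id,
                "hitc": c.hitc,
                "ac50": c.ac50 if c.ac50 is not None else np.nan,
                "acc": c.acc if c.acc is not None else np.nan,
                "winning_model": c.winning_model,
                "n_flags": c.n_flags,
                "burst_flag": c.burst_flag,
            }
            for c in calls
        ]
    )


def curate_series(
    series_list: Sequence[DoseResponseSeries],
    cutoff_multiplier: float = 6.0,
    bmad_multiplier: float = 3.0,
    flag_counts: Mapping[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Fit and call every series; returns the hit-call table."""
    flag_counts = flag_counts or {}
    calls = []
    for s in series_list:
        bmad = compute_bmad(s.baseline_responses, bmad_multiplier)
        cutoff = cutoff_multiplier * bmad
        if cutoff <= 0:
            # flat baseline: fall back to the spread of the test responses
            # so the assay is not degenerate
            cutoff = cutoff_multiplier * max(
                compute_bmad(s.responses, bmad_multiplier), RSS_FLOOR
            )
        _, winner = fit_models(s)
        calls.append(
            call_hit(s, winner, cutoff, bmad=bmad,
                     n_flags=flag_counts.get(
                         (s.chemical_id, s.endpoint_id), 0))
        )
    return hitcalls_to_frame(calls)


def flag_filter(hitcalls: pd.DataFrame, max_flags: int = 3) -> pd.DataFrame:
    """Demote active calls carrying more than ``max_flags`` caution flags.

    Inactive calls are untouched; demotions are annotated in
    ``burst_flag`` as 'flags'."""
    if (hitcalls["n_flags"] < 0).any():
        raise PreconditionError("negative caution-flag count")
    out = hitcalls.copy()
    demote = (out["hitc"] == 1) & (out["n_flags"] > max_flags)
    out.loc[demote, "hitc"] = 0
    out.loc[demote, "burst_flag"] = "flags"
    return out


def burst_filter(
    hitcalls: pd.DataFrame,
    cytotox_endpoint_ids: set,
    mode: str = "strict",
    margin_multiplier: float = 3.0,
) -> pd.DataFrame:
    """Cytotoxicity-burst filter removing target-endpoint false positives.

    Per chemical, the cytotoxicity point is the median AC50 over that
    chemical's active cytotoxicity endpoints; the global spread is the MAD
    of all cytotoxicity points.  Strict mode (+CTB) demotes active
    target-endpoint calls with AC50 ≥ point − margin·spread; mild mode
    (−CTB) demotes only AC50 ≥ point (the most extreme false positives).
    Chemicals with no active cytotoxicity endpoint are never demoted.
    """
    if mode not in ("strict", "mild"):
        raise ConfigError(f"burst filter mode must be strict|mild, got {mode}")

    out = hitcalls.copy()
    is_cyto = out["endpoint_id"].isin(cytotox_endpoint_ids)
    cyto_active = out[is_cyto & (out["hitc"] == 1) & out["ac50"].notna()]
    if cyto_active.empty:
        return out
    points = cyto_active.groupby("chemical_id")["ac50"].median()
    spread = float(np.median(np.abs(points - np.median(points))))

    for chem, point in points.items():
        thr = point - margin_multiplier * spread if mode == "strict" else point
        demote = (
            (out["chemical_id"] == chem)
            & ~is_cyto
            & (out["hitc"] == 1)
            & (out["ac50"] >= thr)
        )
        out.loc[demote, "hitc"] = 0
        out.loc[demote, "burst_flag"] = mode
    return out


def select_endpoints(
    hitcalls: pd.DataFrame,
    min_chems: int = 500,
    min_active_fraction: float = 0.001,
) -> list[str]:
    """Endpoints kept for modeling: strictly more than ``min_chems``
    chemicals and strictly more than ``min_active_fraction`` active hits."""
    kept = []
    for ep, grp in hitcalls.groupby("endpoint_id", sort=True):
        n = grp["chemical_id"].nunique()
        frac = grp["hitc"].mean() if n else 0.0
        if n > min_chems and frac > min_active_fraction:
            kept.append(ep)
    return kept


def concatenate_endpoints(
    hitcalls: pd.DataFrame, target_map: Mapping[str, str]
) -> pd.DataFrame:
    """Concatenate endpoints covering the same mechanistic target.

    One row per (chemical, target); a chemical is active for the target iff
    it is active in at least one constituent endpoint.  Unmapped endpoints
    pass through as singleton targets.  An endpoint mapped to two targets is
    a mapping error (target_map is a plain endpoint→target mapping, so the
    check guards against duplicate keys in tabular inputs upstream).
    """
    # tabular maps may present one endpoint twice; detect via a frame
    if isinstance(target_map, pd.DataFrame):
        dup = target_map["endpoint_id"].duplicated()
        if dup.any():
            raise MappingError(
                "endpoint(s) mapped to multiple targets: "
                f"{sorted(target_map.loc[dup, 'endpoint_id'])}"
            )
        target_map = dict(
            zip(target_map["endpoint_id"], target_map["target_id"])
        )
    df = hitcalls.copy()
    df["target_id"] = [
        target_map.get(ep, ep) for ep in df["endpoint_id"]
    ]
    grouped = (
        df.groupby(["chemical_id", "target_id"], sort=True)["hitc"]
        .max()
        .reset_index()
    )
    return grouped
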