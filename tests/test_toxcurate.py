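import numpy as np
import pandas as pd
import pytest

from toxfinger.errors import (
    ConfigError,
    DegenerateAssayError,
    MappingError,
    PreconditionError,
)
from toxfinger.toxcurate import (
    DoseResponseSeries,
    acc_hill,
    burst_filter,
    call_hit,
    compute_bmad,
    concatenate_endpoints,
    fit_models,
    flag_filter,
    gainloss_curve,
    hill_curve,
    select_endpoints,
)

GRID = np.linspace(-1.0, 2.0, 8)


def make_series(responses, concs=None, baseline=(0.0, 0.1, -0.1)):
    concs = GRID if concs is None else concs
    return DoseResponseSeries("chem", "ep", concs, responses,
                              np.asarray(baseline))


# ------------------------------------------------------------------ BMAD

def test_bmad_zero_spread():
    assert compute_bmad([0.0, 0.0, 0.0]) == 0.0


def test_bmad_symmetric_triplet():
    # median 0, absolute deviations {1, 0, 1}, MAD 1, BMAD 3
    assert compute_bmad([-1.0, 0.0, 1.0]) == 3.0


def test_bmad_matches_sort_based_oracle():
    rng = np.random.default_rng(42)
    x = rng.normal(0.0, 2.0, size=200)
    med = sorted(x)[99:101]
    med = (med[0] + med[1]) / 2
    devs = sorted(abs(v - med) for v in x)
    mad = (devs[99] + devs[100]) / 2
    assert compute_bmad(x) == pytest.approx(3 * mad, rel=1e-12)


def test_bmad_empty_is_error():
    with pytest.raises(PreconditionError):
        compute_bmad([])


# ------------------------------------------------------------- model fits

def test_flat_data_constant_wins():
    series = make_series(np.zeros(len(GRID)))
    fits, winner = fit_models(series)
    assert winner.model == "constant"
    assert fits["constant"].rss == 0.0


def test_noiseless_hill_recovered_within_one_percent():
    y = hill_curve(GRID, 50.0, 0.5, 1.0)
    fits, winner = fit_models(make_series(y))
    assert winner.model == "hill"
    assert winner.tp == pytest.approx(50.0, rel=0.01)


def test_rise_then_fall_prefers_gainloss_by_aic():
    y = gainloss_curve(GRID, 60.0, 0.0, 1.5, 1.5, 2.0)
    fits, winner = fit_models(make_series(y))
    assert winner.model == "gainloss"
    assert fits["gainloss"].aic < fits["hill"].aic


def test_aic_tie_breaks_toward_fewer_parameters():
    # perfectly flat data: hill can also reach rss ~ 0 with tp ~ 0, but the
    # constant model must win on parameter count
    series = make_series(np.zeros(len(GRID)))
    _, winner = fit_models(series)
    assert winner.n_params == 1


# -------------------------------------------------------------- hit calls

def test_constant_winner_is_never_active():
    series = make_series(np.zeros(len(GRID)))
    _, winner = fit_models(series)
    hit = call_hit(series, winner, cutoff=1.0)
    assert hit.hitc == 0
    assert hit.acc is None


def test_acc_equals_ga_when_top_is_twice_cutoff():
    # at the half-maximum the hill curve crosses tp/2 exactly at ga
    assert acc_hill(tp=2.0, ga=0.7, gw=1.3, cutoff=1.0) == pytest.approx(
        0.7, abs=1e-12
    )


def bisect_acc(curve, cutoff, lo, hi, tol=1e-7):
    """Independent bisection oracle for the lowest cutoff crossing."""
    xs = np.linspace(lo, hi, 4000)
    ys = curve(xs) - cutoff
    for i in range(len(xs) - 1):
        if ys[i] <= 0.0 <= ys[i + 1]:
            a, b = xs[i], xs[i + 1]
            while b - a > tol:
                m = (a + b) / 2
                if curve(m) - cutoff <= 0:
                    a = m
                else:
                    b = m
            return (a + b) / 2
    return None


def test_acc_analytic_matches_bisection_oracle():
    cutoff = 1.0
    acc = acc_hill(tp=10.0, ga=0.0, gw=1.0, cutoff=cutoff)
    oracle = bisect_acc(lambda x: hill_curve(x, 10.0, 0.0, 1.0), cutoff,
                        -5.0, 5.0)
    assert acc == pytest.approx(oracle, abs=1e-4)


def test_acc_inversion_agrees_with_bisection_on_random_draws():
    rng = np.random.default_rng(7)
    for _ in range(100):
        tp = rng.uniform(2.0, 20.0)
        ga = rng.uniform(-1.0, 2.0)
        gw = rng.uniform(0.3, 8.0)
        cutoff = rng.uniform(0.5, tp * 0.9)
        acc = acc_hill(tp, ga, gw, cutoff)
        oracle = bisect_acc(lambda x: hill_curve(x, tp, ga, gw), cutoff,
                            ga - 10, ga + 10)
        assert acc == pytest.approx(oracle, abs=1e-4)


def test_hit_rule_requires_median_above_cutoff():
    # modeled top above cutoff but all observed medians below: not a hit
    y = hill_curve(GRID, 10.0, 4.0, 1.0)  # midpoint beyond tested range
    series = make_series(y)
    fits, winner = fit_models(series)
    if winner.model in ("hill", "gainloss"):
        hit = call_hit(series, winner, cutoff=5.0)
        assert hit.hitc == 0


def test_nonpositive_cutoff_is_degenerate():
    series = make_series(np.zeros(len(GRID)))
    _, winner = fit_models(series)
    with pytest.raises(DegenerateAssayError):
        call_hit(series, winner, cutoff=0.0)


def test_hitc_invariant_to_uniform_rescaling():
    rng = np.random.default_rng(3)
    y = hill_curve(GRID, 8.0, 0.5, 1.2) + rng.normal(0, 0.3, len(GRID))
    cutoff = 1.0
    for scale in (0.1, 1.0, 25.0):
        series = make_series(y * scale)
        _, winner = fit_models(series)
        hit = call_hit(series, winner, cutoff=cutoff * scale)
        assert hit.hitc == 1


# ----------------------------------------------------------- flag filter

def hit_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chemical_id", "endpoint_id", "hitc", "ac50", "acc",
                 "winning_model", "n_flags", "burst_flag"],
    )


def test_flag_filter_behaviour():
    table = hit_frame([
        ("c1", "e1", 1, 0.0, 0.0, "hill", 0, "none"),
        ("c2", "e1", 1, 0.0, 0.0, "hill", 4, "none"),
        ("c3", "e1", 0, np.nan, np.nan, "constant", 9, "none"),
    ])
    out = flag_filter(table, max_flags=3)
    assert out.loc[0, "hitc"] == 1            # clean hit untouched
    assert out.loc[1, "hitc"] == 0            # boundary + 1 demoted
    assert out.loc[1, "burst_flag"] == "flags"
    assert out.loc[2, "hitc"] == 0            # inactive untouched
    assert out.loc[2, "burst_flag"] == "none"
    # input not mutated
    assert table.loc[1, "hitc"] == 1


def test_flag_filter_demotion_count_matches_hand_count():
    flags = [0, 1, 2, 3, 4, 5, 0, 4, 3, 7]
    table = hit_frame([
        (f"c{i}", "e1", 1, 0.0, 0.0, "hill", nf, "none")
        for i, nf in enumerate(flags)
    ])
    out = flag_filter(table, max_flags=3)
    assert (out["hitc"] == 0).sum() == sum(1 for f in flags if f > 3) == 4


def test_flag_filter_rejects_negative_counts():
    table = hit_frame([("c1", "e1", 1, 0.0, 0.0, "hill", -1, "none")])
    with pytest.raises(PreconditionError):
        flag_filter(table)


# ----------------------------------------------------------- burst filter

def test_burst_filter_leaves_chemicals_without_cytotox_activity():
    table = hit_frame([
        ("c1", "target_ep", 1, 0.2, 0.1, "hill", 0, "none"),
        ("c1", "cyto_ep", 0, np.nan, np.nan, "constant", 0, "none"),
    ])
    for mode in ("strict", "mild"):
        out = burst_filter(table, {"cyto_ep"}, mode=mode)
        assert out.loc[0, "hitc"] == 1


def test_burst_filter_retains_much_more_potent_hits():
    table = hit_frame([
        ("c1", "target_ep", 1, -2.0, -2.2, "hill", 0, "none"),
        ("c1", "cyto_ep", 1, 1.0, 0.9, "hill", 0, "none"),
        ("c2", "cyto_ep", 1, 1.2, 1.1, "hill", 0, "none"),
    ])
    # target hit 3 log units more potent than the cytotoxicity point
    for mode in ("strict", "mild"):
        out = burst_filter(table, {"cyto_ep"}, mode=mode)
        assert out.loc[0, "hitc"] == 1


def test_burst_filter_matches_row_by_row_hand_evaluation():
    rng = np.random.default_rng(11)
    rows = []
    cyto_points = {}
    for i in range(20):
        chem = f"c{i:02d}"
        cyto_ac50 = rng.uniform(-1.0, 2.0)
        cyto_points[chem] = cyto_ac50
        rows.append((chem, "cyto_ep", 1, cyto_ac50, cyto_ac50, "hill", 0,
                     "none"))
        rows.append((chem, "target_ep", 1, rng.uniform(-2.0, 3.0),
                     0.0, "hill", 0, "none"))
    table = hit_frame(rows)

    points = pd.Series(cyto_points)
    spread = float(np.median(np.abs(points - np.median(points))))
    strict = burst_filter(table, {"cyto_ep"}, mode="strict")
    mild = burst_filter(table, {"cyto_ep"}, mode="mild")

    strict_demoted, mild_demoted = set(), set()
    for i, row in table.iterrows():
        if row["endpoint_id"] != "target_ep":
            continue
        point = cyto_points[row["chemical_id"]]
        if row["ac50"] >= point - 3 * spread:
            strict_demoted.add(i)
        if row["ac50"] >= point:
            mild_demoted.add(i)
    assert set(strict.index[strict["hitc"] == 0]) == strict_demoted
    assert set(mild.index[mild["hitc"] == 0]) == mild_demoted
    # strict demotions always include mild demotions
    assert strict_demoted >= mild_demoted


def test_burst_filter_rejects_unknown_mode():
    with pytest.raises(ConfigError):
        burst_filter(hit_frame([]), set(), mode="medium")


# ------------------------------------------------------ endpoint selection

def _endpoint_table(n_chems, n_active, endpoint="e1"):
    return pd.DataFrame(
        {
            "chemical_id": [f"c{i}" for i in range(n_chems)],
            "endpoint_id": endpoint,
            "hitc": [1] * n_active + [0] * (n_chems - n_active),
        }
    )


def test_endpoint_with_exactly_500_chemicals_excluded():
    assert select_endpoints(_endpoint_table(500, 10)) == []


def test_endpoint_without_actives_excluded():
    assert select_endpoints(_endpoint_table(1000, 0)) == []


def test_endpoint_with_two_per_mille_actives_included():
    assert select_endpoints(_endpoint_table(1000, 2)) == ["e1"]


def test_selection_monotone_in_added_actives():
    base = _endpoint_table(600, 1)
    assert select_endpoints(base) == ["e1"]
    more = pd.concat(
        [base, _endpoint_table(50, 50).assign(
            chemical_id=[f"x{i}" for i in range(50)])],
        ignore_index=True,
    )
    assert select_endpoints(more) == ["e1"]


# --------------------------------------------------------- concatenation

def test_concatenation_uses_or_rule():
    hits = pd.DataFrame(
        {
            "chemical_id": ["c1", "c1"],
            "endpoint_id": ["e1", "e2"],
            "hitc": [1, 0],
        }
    )
    out = concatenate_endpoints(hits, {"e1": "T", "e2": "T"})
    assert out.loc[0, "hitc"] == 1
    assert len(out) == 1


def test_untested_chemical_absent_from_target_table():
    hits = pd.DataFrame(
        {"chemical_id": ["c1"], "endpoint_id": ["e1"], "hitc": [1]}
    )
    out = concatenate_endpoints(hits, {"e1": "T", "e2": "T"})
    assert set(out["chemical_id"]) == {"c1"}


def test_disjoint_endpoints_union_chemical_sets():
    hits = pd.DataFrame(
        {
            "chemical_id": [f"a{i}" for i in range(100)]
            + [f"b{i}" for i in range(100)],
            "endpoint_id": ["e1"] * 100 + ["e2"] * 100,
            "hitc": [0] * 200,
        }
    )
    out = concatenate_endpoints(hits, {"e1": "T", "e2": "T"})
    assert len(out) == 200


def test_endpoint_mapped_to_two_targets_is_error():
    hits = pd.DataFrame(
        {"chemical_id": ["c1"], "endpoint_id": ["e1"], "hitc": [1]}
    )
    bad_map = pd.DataFrame(
        {"endpoint_id": ["e1", "e1"], "target_id": ["T1", "T2"]}
    )
    with pytest.raises(MappingError):
        concatenate_endpoints(hits, bad_map)


def test_unmapped_endpoint_passes_through_as_singleton():
    hits = pd.DataFrame(
        {"chemical_id": ["c1"], "endpoint_id": ["lonely"], "hitc": [1]}
    )
    out = concatenate_endpoints(hits, {})
    assert out.loc[0, "target_id"] == "lonely"
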