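"""Positivity calling, category assignment, densities, Treg profiling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tregspatial import (
    MarkerThresholds,
    assign_category,
    call_positivity,
    cancer_fractions,
    classify_mean_cd25,
    dichotomize,
    infiltration_density,
    treg_subgroup_profile,
)
from tregspatial.scoring import TregProfile

from conftest import make_table


def test_positivity_boundary_is_closed():
    t = make_table([[0, 0], [1, 1]], {"CD8": [5.0, 0.0]})
    calls = call_positivity(t, MarkerThresholds({("*", "CD8"): 5.0}))
    assert list(calls["CD8"]) == [True, False]


def test_positivity_missing_threshold_errors():
    t = make_table([[0, 0]], {"CD8": [1.0]})
    with pytest.raises(KeyError, match="CD8"):
        call_positivity(t, MarkerThresholds({("*", "CD3"): 1.0}))


def test_positivity_mixture_confusion_matches_per_cell_oracle():
    """Two-component mixture with known memberships: thresholding at the
    midpoint reproduces the brute-force per-cell comparison exactly."""
    rng = np.random.default_rng(7)
    member = rng.uniform(size=1000) < 0.3
    intensity = np.where(member, rng.lognormal(2.0, 0.3, 1000),
                         rng.lognormal(-1.0, 0.3, 1000))
    tau = np.exp(0.5)  # midpoint in log space
    t = make_table(rng.uniform(0, 100, (1000, 2)), {"CD8": intensity})
    calls = call_positivity(t, MarkerThresholds({("*", "CD8"): tau}))
    oracle = intensity >= tau
    assert (calls["CD8"].to_numpy() == oracle).all()


def test_positivity_monotone_in_threshold():
    rng = np.random.default_rng(3)
    t = make_table(rng.uniform(0, 100, (200, 2)), {"CD8": rng.lognormal(0, 1, 200)})
    counts = [
        call_positivity(t, MarkerThresholds({("*", "CD8"): tau}))["CD8"].sum()
        for tau in (0.0, 0.5, 1.0, 2.0, 5.0)
    ]
    assert counts == sorted(counts, reverse=True)


def _precedence_oracle(cd4, cd25, foxp3, cd8):
    if cd4 and cd25 and foxp3:
        return "tpTreg"
    if foxp3:
        return "FOXP3"
    if cd8:
        return "CD8"
    return "other"


def test_category_assignment_all_16_call_patterns():
    patterns = list(itertools.product([False, True], repeat=4))
    calls = pd.DataFrame(patterns, columns=["CD4", "CD25", "FOXP3", "CD8"])
    cats = assign_category(calls)
    for (cd4, cd25, foxp3, cd8), cat in zip(patterns, cats):
        assert cat == _precedence_oracle(cd4, cd25, foxp3, cd8)


def test_categories_partition_cells():
    rng = np.random.default_rng(5)
    calls = pd.DataFrame(rng.uniform(size=(500, 4)) < 0.3,
                         columns=["CD4", "CD25", "FOXP3", "CD8"])
    cats = assign_category(calls)
    assert cats.value_counts().sum() == 500
    assert set(cats.cat.categories) == {"CD8", "FOXP3", "tpTreg", "other"}


def test_density_arithmetic():
    t = make_table([[0, 0]] * 10, {"CD8": [1.0] * 10})
    pos = np.ones(10, bool)
    s = infiltration_density(t, pos, "CD8", area_mm2=0.5)
    assert s.density == pytest.approx(20.0)
    assert s.log2_density == pytest.approx(np.log2(21.0))

    s0 = infiltration_density(t, np.zeros(10, bool), "CD8", area_mm2=1.0)
    assert s0.density == 0.0 and s0.log2_density == 0.0

    disc_area = np.pi / 4
    t2 = make_table([[0, 0]] * 100, {"CD8": [1.0] * 100})
    s2 = infiltration_density(t2, np.ones(100, bool), "CD8", area_mm2=disc_area)
    assert s2.density == pytest.approx(127.32, rel=1e-3)
    assert s2.log2_density == pytest.approx(7.0036, rel=1e-3)


def test_density_log2_strictly_increasing_in_count():
    t = make_table([[0, 0]] * 50, {"CD8": [1.0] * 50})
    prev = -1.0
    for k in range(0, 51, 10):
        pos = np.zeros(50, bool)
        pos[:k] = True
        s = infiltration_density(t, pos, "CD8", area_mm2=0.7)
        assert s.log2_density > prev
        prev = s.log2_density


def test_density_errors():
    t = make_table([[0, 0]], {"CD8": [1.0]})
    with pytest.raises(ValueError, match="area"):
        infiltration_density(t, [True], "CD8", area_mm2=0.0)
    with pytest.raises(ValueError, match="region"):
        infiltration_density(t, [True], "CD8", compartment="stromal")


def test_cancer_fractions_counting_oracle():
    rng = np.random.default_rng(11)
    regions = rng.choice(["epithelial", "stromal"], 100, p=[0.3, 0.7])
    t = make_table(rng.uniform(0, 100, (100, 2)), {"CD8": np.ones(100)},
                   regions=regions)
    cf, af = cancer_fractions(t, epithelial_area_mm2=0.3, total_area_mm2=1.0)
    assert cf == pytest.approx(np.mean(regions == "epithelial"))
    assert af == pytest.approx(0.3)
    t_all = make_table([[0, 0], [1, 1]], {"CD8": [1, 1]},
                       regions=["epithelial", "epithelial"])
    assert cancer_fractions(t_all)[0] == 1.0


def test_dichotomize_median_and_ties():
    labels, cut = dichotomize([1.0, 2.0, 3.0, 4.0])
    assert cut == 2.5
    assert list(labels) == ["Low", "Low", "High", "High"]
    labels, _ = dichotomize([2.0, 2.0, 2.0])
    assert list(labels) == ["Low", "Low", "Low"]


@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=3, max_size=300))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_dichotomize_matches_brute_force(scores):
    labels, cut = dichotomize(scores)
    med = float(np.median(scores))
    assert cut == med
    for s, lab in zip(scores, labels):
        assert lab == ("High" if s > med else "Low")


def test_dichotomize_odd_distinct_split():
    rng = np.random.default_rng(2)
    scores = rng.permutation(np.arange(1001, dtype=float))
    labels, _ = dichotomize(scores)
    assert (labels == "High").sum() == 500  # floor(n/2)


# ---------------------------------------------------------------------------
# Treg profiles


def _tp_table(cd25, foxp3, sample_id="S1", series_id="1"):
    n = len(cd25)
    coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return make_table(coords, {"CD4": np.full(n, 5.0), "CD25": cd25,
                               "FOXP3": foxp3, "CD8": np.zeros(n),
                               "CD3": np.full(n, 5.0)},
                      sample_id=sample_id, series_id=series_id)


def _tp_categories(table):
    return pd.Series(["tpTreg"] * table.n_cells, index=table.cells.index)


def test_treg_thresholds_nearest_rank():
    cd25 = np.arange(1.0, 101.0)
    t = _tp_table(cd25, cd25[::-1].copy())
    profiles, summary = treg_subgroup_profile([t], {"S1": _tp_categories(t)})
    p = profiles[0]
    assert p.cd25_threshold == 75.0 and p.foxp3_threshold == 75.0
    # cells 76..100 are CD25-High (strict >)
    assert p.counts["HH"] + p.counts["HL"] == 25


def test_treg_identical_intensities_all_low():
    t = _tp_table(np.full(10, 4.0), np.full(10, 2.0))
    profiles, _ = treg_subgroup_profile([t], {"S1": _tp_categories(t)})
    p = profiles[0]
    assert p.counts == {"HH": 0, "HL": 0, "LH": 0, "LL": 0} or \
        p.counts["LL"] == 10  # strict >: all Low
    assert p.counts["LL"] == 10


def test_treg_subgroups_sum_and_empty_sample():
    rng = np.random.default_rng(9)
    t1 = _tp_table(rng.lognormal(1.5, 0.5, 40), rng.lognormal(0.6, 0.5, 40))
    t2 = make_table([[0, 0]], {"CD4": [0.0], "CD25": [0.0], "FOXP3": [0.0],
                               "CD8": [0.0], "CD3": [0.0]}, sample_id="S2")
    cats = {"S1": _tp_categories(t1),
            "S2": pd.Series(["other"], index=t2.cells.index)}
    profiles, summary = treg_subgroup_profile([t1, t2], cats)
    by_id = {p.sample_id: p for p in profiles}
    assert sum(by_id["S1"].counts.values()) == 40
    assert by_id["S2"].n_tpTreg == 0
    assert by_id["S2"].mean_cd25 is None
    assert by_id["S2"].mean_cd25_class == "Negative"
    assert summary["n_tpTreg_total"] == 40


def test_pooled_high_fraction_approaches_25_percent():
    """Nearest-rank 75th percentile with strict >: the single-marker High
    fraction is <= 25% and approaches it for large continuous pools."""
    rng = np.random.default_rng(21)
    t = _tp_table(rng.lognormal(1.5, 0.7, 20000), rng.lognormal(0.6, 0.8, 20000))
    profiles, _ = treg_subgroup_profile([t], {"S1": _tp_categories(t)})
    p = profiles[0]
    hi25 = (p.counts["HH"] + p.counts["HL"]) / p.n_tpTreg
    assert hi25 <= 0.25
    assert hi25 == pytest.approx(0.25, abs=0.01)


def test_classify_mean_cd25_explicit_and_negative():
    profiles = [
        TregProfile("A", "1", 5, mean_cd25=9.0),
        TregProfile("B", "1", 5, mean_cd25=6.9),
        TregProfile("C", "1", 0),
    ]
    classify_mean_cd25(profiles, cutoff=7.0)
    assert [p.mean_cd25_class for p in profiles] == ["High", "Low", "Negative"]


def test_classify_mean_cd25_auto_bimodal():
    """Equal mixture of sample means at 5 and 9 (sd 0.5): the automatic
    cutoff lands in the valley near 7."""
    rng = np.random.default_rng(17)
    means = np.concatenate([rng.normal(5, 0.5, 100), rng.normal(9, 0.5, 100)])
    profiles = [TregProfile(f"S{i}", "1", 10, mean_cd25=float(m))
                for i, m in enumerate(means)]
    cutoffs = classify_mean_cd25(profiles, cutoff="auto")
    assert cutoffs["1"] == pytest.approx(7.0, abs=0.5)
    for p in profiles:
        assert p.mean_cd25_class == ("High" if p.mean_cd25 > cutoffs["1"] else "Low")


def test_suggest_threshold_separates_mixture_components():
    """The suggested positivity threshold falls in the gap between the
    negative and positive lognormal components."""
    from tregspatial import suggest_threshold

    rng = np.random.default_rng(23)
    neg = rng.lognormal(np.log(0.2), 0.4, 2000)
    pos = rng.lognormal(np.log(5.0), 0.4, 1000)
    tau = suggest_threshold(np.concatenate([neg, pos]))
    assert np.percentile(neg, 99) < tau < np.percentile(pos, 1)


def test_classify_mean_cd25_auto_unimodal_errors():
    rng = np.random.default_rng(19)
    profiles = [TregProfile(f"S{i}", "1", 10, mean_cd25=float(m))
                for i, m in enumerate(rng.normal(6, 1, 100))]
    with pytest.raises(ValueError, match="manual"):
        classify_mean_cd25(profiles, cutoff="auto")
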