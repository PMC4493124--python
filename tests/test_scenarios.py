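"""Marker-set sampling, training/validation splits, the grid engine, LSD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ibmgs import (
    SCENARIOS,
    GridSpec,
    build_split,
    estimate_variance_anova,
    lsd_bonferroni,
    run_grid,
    sample_marker_set,
    summary_matrix,
)
from ibmgs.io import PlotPhenotypes
from ibmgs.popsim import make_marker_map


def _study_inputs(study):
    genos = study.genotypes
    means = {p: study.line_means(p) for p in genos}
    plots = pd.concat([study.traits[p].plot_phenotypes.table for p in genos])
    var = estimate_variance_anova(PlotPhenotypes(plots))
    return genos, means, var


def test_sample_full_panel_is_identity():
    gmap = make_marker_map(200)
    rng = np.random.default_rng(20)
    assert sample_marker_set(gmap, 200, rng) == list(gmap.marker_ids)


def test_sample_marker_set_distinct_sorted_and_sized():
    gmap = make_marker_map(500)
    rng = np.random.default_rng(21)
    for n_m in (10, 47, 333):
        picked = sample_marker_set(gmap, n_m, rng)
        assert len(picked) == n_m == len(set(picked))
        idx = gmap.index_of(picked)
        assert np.all(np.diff(idx) > 0)  # map order


def test_sample_marker_set_warns_below_chromosome_count():
    gmap = make_marker_map(100)
    with pytest.warns(UserWarning, match="uncovered"):
        sample_marker_set(gmap, 5, np.random.default_rng(0))


def test_stratified_sampling_beats_simple_random_on_max_gap():
    """Stratified draws leave smaller maximum gaps than simple random draws."""
    gmap = make_marker_map(1000)
    rng = np.random.default_rng(22)
    from ibmgs.popsim import _cumulative_cm

    cum, _ = _cumulative_cm(gmap)
    pos = {m: c for m, c in zip(gmap.marker_ids, cum)}

    def max_gap(ids):
        p = np.sort([pos[m] for m in ids])
        return np.max(np.diff(p))

    wins = 0
    trials = 400
    for _ in range(trials):
        strat = max_gap(sample_marker_set(gmap, 50, rng))
        srs = max_gap([gmap.marker_ids[i]
                       for i in rng.choice(1000, size=50, replace=False)])
        wins += strat < srs
    assert wins / trials >= 0.97


def test_build_split_within_population_counts():
    rng = np.random.default_rng(23)
    pops = {"syn10": [f"a{i}" for i in range(194)],
            "syn4": [f"b{i}" for i in range(244)]}
    train, val = build_split(SCENARIOS[1], pops, 180, rng)
    assert len(train) == 180 and len(val) == 14
    assert not set(train) & set(val)


@pytest.mark.parametrize("sid", list(SCENARIOS))
@pytest.mark.parametrize("seed", [0, 7])
def test_build_split_disjoint_and_sourced(sid, seed):
    rng = np.random.default_rng(seed)
    pops = {"syn10": [f"a{i}" for i in range(60)],
            "syn4": [f"b{i}" for i in range(80)]}
    scenario = SCENARIOS[sid]
    train, val = build_split(scenario, pops, 30, rng)
    assert len(train) == 30
    assert not set(train) & set(val)
    if scenario.prediction_type == "between":
        # validation is the entire other population
        assert sorted(val) == sorted(pops[scenario.validation_source])
    if scenario.training_source == "mixed":
        assert sum(t.startswith("a") for t in train) == 15
        assert sum(t.startswith("b") for t in train) == 15
    if scenario.validation_source != "mixed":
        prefix = "a" if scenario.validation_source == "syn10" else "b"
        assert all(v.startswith(prefix) for v in val)


def test_build_split_errors():
    rng = np.random.default_rng(24)
    pops = {"syn10": [f"a{i}" for i in range(20)],
            "syn4": [f"b{i}" for i in range(20)]}
    with pytest.raises(ValueError, match="validation"):
        build_split(SCENARIOS[1], pops, 20, rng)
    with pytest.raises(ValueError, match="even"):
        build_split(SCENARIOS[5], pops, 31, rng)


def test_run_grid_shape_and_summary(study_small):
    genos, means, var = _study_inputs(study_small)
    grid = GridSpec(marker_counts=(100,), training_sizes=(60,), n_repeats=2, seed=5)
    table = run_grid([2], grid, genos, means, var)
    assert len(table.repeats) == 2
    assert len(table.summary) == 1
    assert table.summary.iloc[0]["n"] == 2
    assert table.summary.iloc[0]["mean_r_MG"] == pytest.approx(
        table.repeats["r_MG"].mean())
    assert list(table.repeats.columns) == ["scenario", "N_P", "N_M", "repeat",
                                           "r_MP", "r_MG"]


def test_run_grid_deterministic_under_fixed_seed(study_small):
    genos, means, var = _study_inputs(study_small)
    grid = GridSpec(marker_counts=(80, None), training_sizes=(30,), n_repeats=3,
                    seed=11)
    t1 = run_grid([1, 5], grid, genos, means, var)
    t2 = run_grid([1, 5], grid, genos, means, var)
    pd.testing.assert_frame_equal(t1.repeats, t2.repeats)
    pd.testing.assert_frame_equal(t1.summary, t2.summary)


def test_between_population_accuracy_below_within_at_low_density(study_small):
    """Cross-population prediction loses accuracy at low marker density."""
    genos, means, var = _study_inputs(study_small)
    grid = GridSpec(marker_counts=(100,), training_sizes=(180,), n_repeats=30,
                    seed=13)
    table = run_grid([1, 3], grid, genos, means, var)
    within = table.cell_mean(1, 180, 100)
    between = table.cell_mean(3, 180, 100)
    assert between < within


def test_accuracy_grows_with_training_size(study_small):
    genos, means, var = _study_inputs(study_small)
    n_full = study_small.genotypes["syn4"].n_markers
    grid = GridSpec(marker_counts=(None,), training_sizes=(30, 180), n_repeats=20,
                    seed=17)
    table = run_grid([2], grid, genos, means, var)
    lo = table.repeats.query("N_P == 30")["r_MG"]
    hi = table.repeats.query("N_P == 180")["r_MG"]
    assert 0.2 < hi.mean() < 1.1
    t, p = stats.ttest_ind(hi, lo, alternative="greater")
    assert p < 0.05
    assert table.cell_mean(2, 180, n_full) > table.cell_mean(2, 30, n_full)


def test_lsd_two_cell_toy_matches_pooled_t():
    """2 cells x 3 repeats: MSE = 0.01; flag agrees with the pooled t-test."""
    repeats = pd.DataFrame({
        "scenario": [1] * 6,
        "N_P": [30] * 3 + [60] * 3,
        "N_M": [100] * 6,
        "repeat": [0, 1, 2] * 2,
        "r_MP": np.nan,
        "r_MG": [0.1, 0.2, 0.3, 0.5, 0.6, 0.7],
    })
    from ibmgs.scenarios import AccuracyTable

    table = AccuracyTable(repeats=repeats, summary=pd.DataFrame(),
                          failures=pd.DataFrame())
    res = lsd_bonferroni(table, alpha=0.05)[1]
    assert res.mse == pytest.approx(0.01)
    assert res.alpha_adjusted == pytest.approx(0.05)  # k = 2: no adjustment
    t_crit = stats.t.ppf(0.975, 4)
    assert res.lsd == pytest.approx(t_crit * np.sqrt(2 * 0.01 / 3))
    # pooled two-sample t statistic 0.4/sqrt(2*0.01/3) exceeds t_crit
    assert res.flags["significant"].tolist() == [True]


def test_lsd_identical_cells_flag_nothing():
    repeats = pd.DataFrame({
        "scenario": [2] * 9,
        "N_P": [30, 30, 30, 60, 60, 60, 90, 90, 90],
        "N_M": [100] * 9,
        "repeat": list(range(3)) * 3,
        "r_MP": np.nan,
        "r_MG": [0.4, 0.5, 0.6] * 3,
    })
    from ibmgs.scenarios import AccuracyTable

    table = AccuracyTable(repeats=repeats, summary=pd.DataFrame(),
                          failures=pd.DataFrame())
    res = lsd_bonferroni(table)[2]
    assert not res.flags["significant"].any()
    assert res.alpha_adjusted == pytest.approx(0.05 / 3)


def test_summary_matrix_layout(study_small):
    genos, means, var = _study_inputs(study_small)
    grid = GridSpec(marker_counts=(50, 100), training_sizes=(30, 60), n_repeats=2,
                    seed=19)
    table = run_grid([1], grid, genos, means, var)
    mat = summary_matrix(table, 1)
    assert mat.shape == (2, 2)
    assert list(mat.index) == [30, 60]
    assert list(mat.columns) == [50, 100]
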