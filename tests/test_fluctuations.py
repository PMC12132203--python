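"""Heterogeneity statistics: fits, correlations, patchiness, Fisher z."""

import dataclasses

import numpy as np
import pytest

from sepalgrowth import (
    DegradedFitError,
    InsufficientDataError,
    SimParams,
    compare_correlations_ztest,
    compute_fluctuations,
    cumulative_fluctuations,
    cumulative_growth,
    fit_target_growth,
    patchiness,
    simulate_series,
    temporal_correlation,
)

from conftest import hex_lattice_neighbors, make_frame, make_series


# --- target-growth fit -----------------------------------------------------

def test_constant_growth_fits_exactly():
    x = np.linspace(0, 1, 20)
    coeffs, fitted = fit_target_growth(x, np.full(20, 1.5))
    assert np.allclose(fitted, 1.5)
    assert np.allclose(coeffs[1:], 0.0, atol=1e-12)


def test_exact_cubic_has_zero_residuals():
    x = np.linspace(0, 1, 50)
    g = 1 + 0.5 * x - 0.2 * x**2 + 0.1 * x**3
    _, fitted = fit_target_growth(x, g)
    assert np.max(np.abs(g - fitted)) < 1e-10


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 1, 200)
    g = 1.4 - 0.6 * x + 0.3 * x**2 - 0.1 * x**3 + rng.normal(0, 0.1, 200)
    coeffs, fitted = fit_target_growth(x, g)
    # independent oracle: solve the normal equations directly
    X = np.vander(x, 4, increasing=True)
    oracle = np.linalg.solve(X.T @ X, X.T @ g)
    assert np.max(np.abs(coeffs - oracle)) < 1e-8
    assert abs(np.sum(g - fitted)) < 1e-9 * len(x)


def test_too_few_distinct_positions_raises():
    x = np.array([0.1, 0.1, 0.5, 0.5, 0.9, 0.9])
    with pytest.raises(DegradedFitError, match="degree"):
        fit_target_growth(x, np.ones(6))


# --- fluctuation table -----------------------------------------------------

def test_interval_mean_fluctuation_is_zero(medium_series):
    table, _ = compute_fluctuations(medium_series)
    for _, sub in table.groupby("interval"):
        assert abs(sub["fluctuation"].mean()) < 1e-9
        assert np.allclose(
            sub["fluctuation"], sub["growth_ratio"] - sub["target"], atol=1e-12
        )


def test_untracked_lineages_are_counted(medium_series):
    pruned = dataclasses.replace(medium_series)
    pruned.growth = [dict(g) for g in medium_series.growth]
    for lid in sorted(pruned.growth[0])[:3]:
        del pruned.growth[0][lid]
    _, excluded = compute_fluctuations(pruned)
    assert excluded[0] == 3
    assert excluded[1] == 0


def test_log_scale_fluctuations_use_log_growth(medium_series):
    table, _ = compute_fluctuations(medium_series, log_scale=True)
    assert np.allclose(
        table["fluctuation"],
        np.log(table["growth_ratio"]) - table["target"],
        atol=1e-12,
    )


# --- temporal correlation --------------------------------------------------

def _two_interval_table(f0, f1):
    frames = [
        make_frame({f"c{i}": 1.0 for i in range(len(f0))}, frame_index=0),
        make_frame(
            {f"c{i}": 1.0 for i in range(len(f0))},
            parents={f"c{i}": f"c{i}" for i in range(len(f0))},
            frame_index=1,
        ),
    ]
    import pandas as pd

    rows = []
    for t, f in enumerate((f0, f1)):
        for i, v in enumerate(f):
            rows.append(
                {"replicate": "r1", "interval": t, "lineage_id": f"c{i}",
                 "pd_position": i / len(f), "growth_ratio": 1 + v,
                 "target": 1.0, "fluctuation": v}
            )
    return pd.DataFrame(rows)


def test_identical_fluctuations_give_unit_correlation():
    f = [0.1, -0.2, 0.05, 0.3, -0.15]
    scores = temporal_correlation(_two_interval_table(f, f))
    assert scores.r_bar == pytest.approx(1.0)


def test_negated_fluctuations_give_minus_one():
    f = np.array([0.1, -0.2, 0.05, 0.3, -0.15])
    scores = temporal_correlation(_two_interval_table(f, -f))
    assert scores.r_bar == pytest.approx(-1.0)


def test_zero_variance_pair_is_flagged_not_nan():
    scores = temporal_correlation(_two_interval_table([0.0] * 5, [0.1, -0.1, 0.2, 0.0, -0.2]))
    assert scores.r_bar is None
    assert scores.undefined_pairs == [0]


def test_too_few_shared_lineages_raise():
    with pytest.raises(InsufficientDataError, match="share"):
        temporal_correlation(_two_interval_table([0.1, 0.2], [0.1, 0.2]))


def test_single_interval_is_rejected():
    table = _two_interval_table([0.1] * 5, [0.1] * 5)
    with pytest.raises(InsufficientDataError):
        temporal_correlation(table[table["interval"] == 0])


def test_per_cell_variant_agrees_on_persistent_fluctuations():
    f = [0.1, -0.2, 0.05, 0.3, -0.15]
    import pandas as pd

    rows = []
    for t in range(3):
        for i, v in enumerate(f):
            scale = [1.0, 2.0, 3.0][t]  # monotone per-cell trajectories
            rows.append(
                {"replicate": "r1", "interval": t, "lineage_id": f"c{i}",
                 "pd_position": i / 5, "growth_ratio": 1 + v * scale,
                 "target": 1.0, "fluctuation": v * scale}
            )
    scores = temporal_correlation(pd.DataFrame(rows), per_cell=True)
    assert scores.r_bar == pytest.approx(1.0)


# --- cumulative growth -----------------------------------------------------

def test_cumulative_growth_is_product_of_interval_ratios():
    frames = [
        make_frame({"a": 100.0}),
        make_frame({"a": 110.0}, parents={"a": "a"}, frame_index=1),
        make_frame({"a": 132.0}, parents={"a": "a"}, frame_index=2),
        make_frame({"a": 171.6}, parents={"a": "a"}, frame_index=3),
    ]
    series = make_series(frames, [{"a": (1.1, 0, 0.5)}, {"a": (1.2, 0, 0.5)},
                                  {"a": (1.3, 0, 0.5)}])
    cum, excluded = cumulative_growth(series)
    assert cum["a"] == pytest.approx(1.716)
    assert excluded == []


def test_division_footprint_sums_daughter_areas():
    frames = [
        make_frame({"p": 100.0}),
        make_frame(
            {"d1": 60.0, "d2": 80.0}, parents={"d1": "p", "d2": "p"}, frame_index=1
        ),
    ]
    series = make_series(frames, [{"p": (1.4, 0, 0.5)}])
    cum, _ = cumulative_growth(series)
    assert cum["p"] == pytest.approx(1.4)


def test_simulator_cumulative_matches_area_ratio(medium_series):
    cum, excluded = cumulative_growth(medium_series)
    assert excluded == []
    first, last = medium_series.frames[0], medium_series.frames[-1]
    for lid, ratio in cum.items():
        assert ratio == pytest.approx(
            last.cells[lid].area / first.cells[lid].area, abs=1e-10
        )


def test_broken_lineage_is_excluded_and_reported():
    frames = [
        make_frame({"a": 100.0, "b": 50.0}),
        make_frame({"a": 110.0}, parents={"a": "a"}, frame_index=1),
    ]
    series = make_series(frames, [{"a": (1.1, 0, 0.5)}])
    cum, excluded = cumulative_growth(series)
    assert set(cum) == {"a"} and excluded == ["b"]


# --- patchiness ------------------------------------------------------------

def _brute_force_patchiness(fluct, neighbors):
    """Independent oracle: explicit neighborhood enumeration."""
    means = []
    for cid in sorted(fluct):
        hood = [fluct[cid]] + [fluct[n] for n in sorted(neighbors.get(cid, ())) if n in fluct]
        means.append(sum(hood) / len(hood))
    mu = sum(means) / len(means)
    return (sum((m - mu) ** 2 for m in means) / len(means)) ** 0.5


def test_zero_fluctuations_give_zero_patchiness():
    nbrs = hex_lattice_neighbors(4, 4)
    assert patchiness({c: 0.0 for c in nbrs}, nbrs) == 0.0


def test_empty_graph_reduces_to_plain_sd():
    rng = np.random.default_rng(1)
    f = {f"c{i}": float(v) for i, v in enumerate(rng.normal(0, 0.2, 30))}
    vals = np.array(list(f.values()))
    assert patchiness(f, {}) == pytest.approx(float(np.std(vals)))


def test_patchiness_matches_brute_force_and_shrinks_iid_noise():
    nbrs = hex_lattice_neighbors(8, 8)
    rng = np.random.default_rng(2)
    f = {c: float(v) for c, v in zip(sorted(nbrs), rng.normal(0, 1.0, len(nbrs)))}
    P = patchiness(f, nbrs)
    assert P == pytest.approx(_brute_force_patchiness(f, nbrs), abs=1e-14)
    assert P < 1.0  # neighborhood averaging cancels i.i.d. noise


def test_patchiness_shift_invariance_and_linear_scaling():
    nbrs = hex_lattice_neighbors(5, 5)
    rng = np.random.default_rng(3)
    f = {c: float(v) for c, v in zip(sorted(nbrs), rng.normal(0, 0.5, len(nbrs)))}
    P = patchiness(f, nbrs)
    shifted = {c: v + 7.0 for c, v in f.items()}
    scaled = {c: 3.0 * v for c, v in f.items()}
    assert patchiness(shifted, nbrs) == pytest.approx(P, abs=1e-12)
    assert patchiness(scaled, nbrs) == pytest.approx(3.0 * P, rel=1e-12)


def test_spatial_correlation_raises_patchiness_paired_seed():
    from sepalgrowth.synthetic import CELL_SPACING_UM

    base = SimParams(n_cells=400, n_intervals=3, rho_time=0.8, seed=17)
    patchy = dataclasses.replace(base, ell_space=3 * CELL_SPACING_UM)
    vals = []
    for params in (base, patchy):
        series = simulate_series(params)
        f, _ = cumulative_fluctuations(series)
        vals.append(patchiness(f, series.frames[0].neighbor_map()))
    assert vals[1] > vals[0]


# --- Fisher z-test ---------------------------------------------------------

def test_equal_correlations_give_zero_statistic():
    t = compare_correlations_ztest(0.4, 50, 0.4, 50)
    assert t.z == 0.0
    assert t.p == pytest.approx(1.0)


def test_ztest_matches_closed_form_values():
    t = compare_correlations_ztest(0.5, 103, 0.0, 103)
    assert t.z == pytest.approx(3.884, abs=0.001)
    assert t.p == pytest.approx(1.0e-4, rel=0.05)
    t2 = compare_correlations_ztest(0.9, 53, 0.1, 53)
    assert t2.z == pytest.approx(6.86, abs=0.01)


@pytest.mark.parametrize("r1,n1,r2,n2", [(0.5, 3, 0.2, 50), (1.0, 50, 0.2, 50)])
def test_ztest_domain_errors(r1, n1, r2, n2):
    with pytest.raises(ValueError):
        compare_correlations_ztest(r1, n1, r2, n2)
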