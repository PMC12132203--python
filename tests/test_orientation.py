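"""Axial alignment statistics and group comparisons."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sepalgrowth import (
    SimParams,
    anisotropy,
    axial_angle,
    build_orientation_table,
    generate_tissue,
    mt_growth_alignment,
    neighbor_alignment,
    permutation_test_groups,
    simulate_growth,
    simulate_microtubules,
    stratify_by_relative_growth,
    weighted_angle_histogram,
)

from conftest import make_frame, make_series


# --- axial angles ----------------------------------------------------------

@pytest.mark.parametrize(
    "t1,t2,expected", [(30, 30, 0), (10, 100, 90), (170, 10, 20), (0, 90, 90)]
)
def test_axial_angle_examples(t1, t2, expected):
    assert axial_angle(t1, t2) == pytest.approx(expected)


@given(
    st.floats(-720, 720, allow_nan=False),
    st.floats(-720, 720, allow_nan=False),
)
def test_axial_angle_is_symmetric_bounded_and_periodic(a, b):
    d = axial_angle(a, b)
    assert 0.0 <= d <= 90.0
    assert d == pytest.approx(axial_angle(b, a))
    assert d == pytest.approx(axial_angle(a + 180.0, b), abs=1e-6)


# --- anisotropy ------------------------------------------------------------

@pytest.mark.parametrize("mx,mn,expected", [(2.0, 2.0, 0.0), (5.0, 0.0, 1.0),
                                            (3.0, 1.0, 0.5), (0.0, 0.0, 0.0)])
def test_anisotropy_examples(mx, mn, expected):
    assert anisotropy(mx, mn) == pytest.approx(expected)


def test_anisotropy_rejects_swapped_arguments():
    with pytest.raises(ValueError):
        anisotropy(1.0, 3.0)


# --- histogram -------------------------------------------------------------

def test_all_mass_in_last_bin_for_near_perpendicular():
    edges, mass = weighted_angle_histogram(np.full(10, 89.0), np.ones(10))
    assert mass[-1] == pytest.approx(10.0)
    assert mass[:-1].sum() == 0.0
    assert edges[0] == 0.0 and edges[-1] == 90.0


def test_last_bin_is_closed_at_ninety():
    _, mass = weighted_angle_histogram([90.0], [1.0])
    assert mass[-1] == 1.0


def test_zero_weights_give_empty_histogram():
    _, mass = weighted_angle_histogram(np.linspace(0, 90, 50), np.zeros(50))
    assert mass.sum() == 0.0


def test_uniform_axial_angles_fill_bins_uniformly():
    p = SimParams(n_cells=1000, n_intervals=1, kappa_mt=0.0, seed=21)
    series = simulate_microtubules(simulate_growth(generate_tissue(p), p), p)
    table = build_orientation_table(series)
    _, mass = weighted_angle_histogram(table["alpha_mg_deg"], None, n_bins=9)
    n = mass.sum()
    # multinomial 99% envelope for 9 equiprobable bins
    expect = n / 9
    sd = np.sqrt(n * (1 / 9) * (8 / 9))
    assert np.all(np.abs(mass - expect) < 3.1 * sd)


# --- alignment statistics --------------------------------------------------

def test_parallel_everywhere_gives_minus_one():
    assert mt_growth_alignment(np.zeros(100)) == pytest.approx(-1.0)


def test_perpendicular_everywhere_gives_plus_one():
    assert mt_growth_alignment(np.full(100, 90.0)) == pytest.approx(1.0)


def test_weighted_alignment_mixes_by_weight():
    stat = mt_growth_alignment([0.0, 90.0], weights=[1.0, 3.0], weighted=True)
    assert stat == pytest.approx(0.5)


def test_zero_total_weight_is_flagged_undefined():
    assert mt_growth_alignment([45.0], weights=[0.0], weighted=True) is None


def test_sign_convention_is_minus_cos_double_angle():
    rng = np.random.default_rng(5)
    alpha = rng.uniform(0, 90, 200)
    stat = mt_growth_alignment(alpha)
    assert stat == pytest.approx(-float(np.mean(np.cos(2 * np.deg2rad(alpha)))))
    assert -1.0 <= stat <= 1.0


def test_equal_neighbor_directions_give_plus_one():
    angles = {"a": 37.0, "b": 37.0, "c": 37.0}
    nbrs = {"a": {"b", "c"}, "b": {"a", "c"}, "c": {"a", "b"}}
    _, grand, isolated = neighbor_alignment(angles, nbrs)
    assert grand == pytest.approx(1.0)
    assert isolated == 0


def test_perpendicular_checkerboard_gives_minus_one():
    # bipartite 4x4 lattice, classes carry 0 and 90 degrees
    angles, nbrs = {}, {}
    for i in range(4):
        for j in range(4):
            cid = f"c{i}{j}"
            angles[cid] = 0.0 if (i + j) % 2 == 0 else 90.0
            nbrs[cid] = {
                f"c{ii}{jj}"
                for ii, jj in [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
                if 0 <= ii < 4 and 0 <= jj < 4
            }
    _, grand, _ = neighbor_alignment(angles, nbrs)
    assert grand == pytest.approx(-1.0)


def test_mixed_neighbors_average_to_zero():
    angles = {"f": 0.0, "n1": 0.0, "n2": 90.0}
    nbrs = {"f": {"n1", "n2"}, "n1": {"f"}, "n2": {"f"}}
    per_cell, _, _ = neighbor_alignment(angles, nbrs)
    assert per_cell["f"] == pytest.approx(0.0)


def test_isolated_cells_are_excluded_and_counted():
    angles = {"a": 10.0, "b": 20.0, "lone": 30.0}
    nbrs = {"a": {"b"}, "b": {"a"}, "lone": set()}
    per_cell, grand, isolated = neighbor_alignment(angles, nbrs)
    assert isolated == 1 and "lone" not in per_cell
    assert grand is not None


# --- stratification --------------------------------------------------------

def _stratify_fixture():
    frame = make_frame(
        {"a": 1.0, "b": 1.0, "c": 1.0, "lone": 1.0},
        neighbors={"a": {"b", "c"}, "b": {"a", "c"}, "c": {"a", "b"}, "lone": set()},
    )
    growth = [{"a": (1.3, 0, 0.5), "b": (1.1, 0, 0.5), "c": (1.1, 0, 0.5),
               "lone": (1.2, 0, 0.5)}]
    return make_series([frame], growth)


def test_stratification_rules():
    labels = stratify_by_relative_growth(_stratify_fixture(), 0)
    assert labels["a"] == "overgrowing"  # 1.3 > mean(1.1, 1.1)
    assert labels["b"] == "undergrowing"  # 1.1 < mean(1.3, 1.1)
    assert labels["c"] == "undergrowing"
    assert labels["lone"] == "excluded"  # no neighbors


def test_exact_tie_is_excluded():
    frame = make_frame({"a": 1.0, "b": 1.0}, neighbors={"a": {"b"}, "b": {"a"}})
    series = make_series([frame], [{"a": (1.2, 0, 0.5), "b": (1.2, 0, 0.5)}])
    labels = stratify_by_relative_growth(series, 0)
    assert labels == {"a": "excluded", "b": "excluded"}


# --- permutation test ------------------------------------------------------

def test_exhaustive_permutation_gives_exact_p():
    p = permutation_test_groups([0, 0, 0, 1, 1, 1], ["x", "x", "x", "y", "y", "y"])
    assert p == pytest.approx(2 / 20)


def test_identical_values_give_p_one():
    p = permutation_test_groups([1.0] * 6, ["x"] * 3 + ["y"] * 3)
    assert p == pytest.approx(1.0)


def test_permutation_requires_two_groups():
    with pytest.raises(ValueError):
        permutation_test_groups([1, 2, 3], ["x", "x", "x"])


def test_monte_carlo_permutation_is_seeded():
    rng = np.random.default_rng(0)
    vals = rng.normal(0, 1, 40)
    labels = ["x"] * 20 + ["y"] * 20
    p1 = permutation_test_groups(vals, labels, n_perm=500, seed=3)
    p2 = permutation_test_groups(vals, labels, n_perm=500, seed=3)
    assert p1 == p2


# --- coupling properties ---------------------------------------------------

def test_alignment_increases_with_microtubule_concentration():
    means = []
    for kappa in (0.0, 1.0, 4.0, 16.0):
        stats = []
        for seed in range(10):
            p = SimParams(
                n_cells=300, n_intervals=1, kappa_mt=kappa,
                mt_coupling="perpendicular_to_growth", seed=100 + seed,
            )
            series = simulate_microtubules(simulate_growth(generate_tissue(p), p), p)
            table = build_orientation_table(series)
            stats.append(mt_growth_alignment(table["alpha_mg_deg"].to_numpy()))
        means.append(np.mean(stats))
    assert all(means[i] < means[i + 1] for i in range(3))


def test_overgrowing_cells_align_less_with_neighbors():
    """Growth directions blended towards the neighborhood mean for
    undergrowing cells and towards own-microtubule-perpendicular for
    overgrowing cells reproduce the expected stratified contrast."""
    p = SimParams(n_cells=400, n_intervals=1, seed=31)
    frame = generate_tissue(p)
    series = simulate_growth(frame, p)
    rng = np.random.default_rng(31)
    records = series.growth[0]
    labels = stratify_by_relative_growth(series, 0)
    # rebuild growth directions: overgrowing follow own MT + 90, under
    # growing copy the neighborhood mean direction (axial mean)
    mt = {cid: rng.uniform(0, 180) for cid in frame.cells}
    new_records = {}
    for lid, rec in records.items():
        nbrs = [n for n in frame.cells[lid].neighbor_ids if n in records]
        mean_nbr = (
            np.rad2deg(
                0.5 * np.angle(np.mean(np.exp(2j * np.deg2rad([records[n].growth_angle for n in nbrs]))))
            ) % 180.0
            if nbrs
            else rec.growth_angle
        )
        if labels.get(lid) == "overgrowing":
            ang = (mt[lid] + 90.0 + rng.normal(0, 5)) % 180.0
        else:
            ang = (mean_nbr + rng.normal(0, 5)) % 180.0
        new_records[lid] = dataclasses.replace(rec, growth_angle=float(ang))
    series.growth[0] = new_records
    frames = [
        dataclasses.replace(
            frame,
            cells={
                cid: dataclasses.replace(c, mt_angle=mt[cid], mt_aniso=0.5)
                for cid, c in frame.cells.items()
            },
        )
    ] + series.frames[1:]
    series = series.with_frames(frames)
    table = build_orientation_table(series)
    over = table[table["relative_growth_class"] == "overgrowing"]
    under = table[table["relative_growth_class"] == "undergrowing"]
    a_over = mt_growth_alignment(over["alpha_mg_deg"].to_numpy())
    a_under = mt_growth_alignment(under["alpha_mg_deg"].to_numpy())
    assert a_over > a_under  # overgrowing: MT perpendicular to growth
    assert over["neighbor_alignment"].mean() < under["neighbor_alignment"].mean()
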