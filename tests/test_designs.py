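import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eescreen import (
    ParameterSpace,
    ParameterSpec,
    build_radial_block,
    build_winding_block,
    count_total_effects,
    generate_design,
    generate_eot_design,
    generate_radial_design,
    generate_winding_design,
    pin_coordinate,
    select_eot,
    select_ot_bruteforce,
    set_spread,
    trajectory_distance,
)
from eescreen.designs import CoincidenceError, STRATEGIES, _random_winding_block


def unit_square(levels=4):
    return ParameterSpace(
        [ParameterSpec("x1", levels=levels), ParameterSpec("x2", levels=levels)]
    )


# ---------------------------------------------------------------- winding


def test_winding_block_up_steps():
    b = build_winding_block([0, 1 / 3], [2 / 3, 2 / 3], [1, 1], [0, 1], unit_square())
    np.testing.assert_allclose(
        b.unit_points, [[0, 1 / 3], [2 / 3, 1 / 3], [2 / 3, 1]], atol=1e-12
    )
    b.validate()


def test_winding_block_down_steps_start_at_top():
    b = build_winding_block([0, 1 / 3], [2 / 3, 2 / 3], [-1, -1], [0, 1], unit_square())
    np.testing.assert_allclose(
        b.unit_points, [[2 / 3, 1], [0, 1], [0, 1 / 3]], atol=1e-12
    )
    assert all(r.delta == pytest.approx(-2 / 3) for r in b.step_records)


def test_winding_block_one_change_per_row_pair(rng):
    space = unit_square()
    for _ in range(20):
        b = _random_winding_block(space, space.default_deltas(), rng)
        b.validate()
        for t in range(1, 3):
            assert np.sum(b.unit_points[t] != b.unit_points[t - 1]) == 1


def test_winding_block_rejects_off_grid_start():
    with pytest.raises(ValueError, match="restricted grid"):
        build_winding_block([0.5, 0], [2 / 3, 2 / 3], [1, 1], [0, 1], unit_square())


def test_winding_block_rejects_cross_level_permutation():
    space = ParameterSpace(
        [ParameterSpec("a", levels=4), ParameterSpec("b", levels=2)]
    )
    with pytest.raises(ValueError, match="permutation"):
        build_winding_block([0, 0], [2 / 3, 1], [1, 1], [1, 0], space)


def test_boolean_space_designs_stay_on_01():
    space = ParameterSpace([ParameterSpec(f"b{i}", vtype="boolean", levels=2) for i in range(3)])
    for strategy in ("sobol-winding", "rd-radial", "eot"):
        d = generate_design(space, strategy, 4, M=20, rng=0)
        pts = d.unit_matrix()
        assert np.all(np.isin(pts, [0.0, 1.0]))


def test_winding_design_counts_and_grid_membership():
    space = unit_square()
    d = generate_winding_design(space, 4, base_source="sobol", pinned=True)
    assert d.n_points == 12
    grid = np.arange(4) / 3
    pts = d.unit_matrix()
    assert np.all(np.isclose(pts[..., None], grid[None, None, :], atol=1e-12).any(axis=-1))


def test_designs_are_deterministic():
    space = unit_square()
    for strategy in ("sobol-radial", "rd-winding", "pinned-sobol-radial"):
        d1 = generate_design(space, strategy, 5)
        d2 = generate_design(space, strategy, 5)
        np.testing.assert_array_equal(d1.unit_matrix(), d2.unit_matrix())
    d1 = generate_eot_design(space, 4, M=20, rng=3)
    d2 = generate_eot_design(space, 4, M=20, rng=3)
    np.testing.assert_array_equal(d1.unit_matrix(), d2.unit_matrix())


# ---------------------------------------------------------------- pinning / radial


@pytest.mark.parametrize("x, p, expected", [(0.3, 4, 1 / 3), (1.0, 4, 1.0), (0.0, 7, 0.0)])
def test_pin_coordinate(x, p, expected):
    assert pin_coordinate(x, p) == pytest.approx(expected)


@given(st.floats(min_value=0, max_value=1), st.integers(min_value=2, max_value=9))
@settings(derandomize=True, deadline=None, max_examples=60)
def test_pin_lands_on_level_grid(x, p):
    pinned = pin_coordinate(x, p)
    assert pinned in set(np.arange(p) / (p - 1))


def test_radial_block_structure_matches_star_pattern():
    space = ParameterSpace([ParameterSpec(f"x{i}") for i in range(3)])
    a, b = np.array([0.2, 0.4, 0.6]), np.array([0.7, 0.1, 0.9])
    blk = build_radial_block(a, b, space)
    blk.validate()
    np.testing.assert_allclose(blk.unit_points[0], a)
    for i in range(3):
        expected = a.copy()
        expected[i] = b[i]
        np.testing.assert_allclose(blk.unit_points[i + 1], expected)
        assert blk.step_records[i].delta == pytest.approx(b[i] - a[i])


def test_radial_pinned_steps_keep_point_inside():
    space = ParameterSpace([ParameterSpec("x", levels=4)])
    blk = build_radial_block([0.3], [0.9], space, pinned=True)
    # 0.3 pins to 1/3; only +2/3 keeps the point in [0, 1]
    assert blk.unit_points[0, 0] == pytest.approx(1 / 3)
    assert blk.unit_points[1, 0] == pytest.approx(1.0)
    blk2 = build_radial_block([0.999, ], [0.0], space, pinned=True)
    # pinned near 1: forced downward step
    assert blk2.step_records[0].delta < 0


def test_radial_coincidence_raises():
    space = ParameterSpace([ParameterSpec("x"), ParameterSpec("y")])
    with pytest.raises(CoincidenceError):
        build_radial_block([0.2, 0.4], [0.2, 0.9], space)


def test_radial_design_uses_single_2k_stream_with_shift():
    from eescreen.qr import sobol_points

    space = ParameterSpace([ParameterSpec("x"), ParameterSpec("y")])
    r, q = 6, 4
    d = generate_radial_design(space, r, seq="sobol", q=q)
    rows = sobol_points(r + q, 2 * space.k)
    for i in range(r):
        np.testing.assert_allclose(d.blocks[i].unit_points[0], rows[i, :2])
        perturbed = [d.blocks[i].unit_points[j + 1, j] for j in range(2)]
        np.testing.assert_allclose(perturbed, rows[i + q, 2:])


def test_radial_design_q_zero_pairs_rows_directly():
    # R_d rows never have coincident halves, so no regeneration interferes
    space = ParameterSpace([ParameterSpec("x")])
    from eescreen.qr import rd_points

    d = generate_radial_design(space, 3, seq="rd", q=0)
    rows = rd_points(3, 2)
    for i, blk in enumerate(d.blocks):
        assert blk.unit_points[0, 0] == rows[i, 0]
        assert blk.unit_points[1, 0] == rows[i, 1]


def test_all_strategies_keep_discrete_inputs_integer(mixed_space):
    for strategy in STRATEGIES:
        if strategy == "ot":
            continue
        d = generate_design(mixed_space, strategy, 4, M=12, rng=1)
        actual = d.actual_matrix()
        for i, p in enumerate(mixed_space):
            if p.is_discrete:
                np.testing.assert_allclose(
                    actual[:, i], np.round(actual[:, i]), atol=1e-9,
                    err_msg=f"{strategy}: {p.name} produced non-integer values",
                )


def test_all_unit_coordinates_in_bounds(mixed_space):
    for strategy in ("sobol-radial", "rd-radial", "pinned-rd-winding", "eot"):
        d = generate_design(mixed_space, strategy, 5, M=15, rng=2)
        pts = d.unit_matrix()
        assert np.all(pts >= -1e-12) and np.all(pts <= 1 + 1e-12)
        for blk in d.blocks:
            blk.validate()


# ---------------------------------------------------------------- spread / selection


def one_d_block(points):
    from eescreen.designs import Block, StepRecord

    pts = np.asarray(points, float).reshape(-1, 1)
    return Block(pts, pts, (StepRecord(0, 0, 1, 2 / 3, 2 / 3),), "winding")


def test_trajectory_distance_hand_value_and_symmetry():
    t1, t2 = one_d_block([0, 2 / 3]), one_d_block([1 / 3, 1])
    assert trajectory_distance(t1, t2) == pytest.approx(2.0)
    assert trajectory_distance(t2, t1) == pytest.approx(2.0)
    assert trajectory_distance(t1, t1) == 0.0


def test_set_spread_counts_ordered_pairs():
    t1, t2 = one_d_block([0, 2 / 3]), one_d_block([1 / 3, 1])
    assert set_spread([t1, t2]) == pytest.approx(8.0)  # 2 * d^2
    with pytest.raises(ValueError):
        set_spread([t1])


def test_set_spread_invariant_under_reordering(rng):
    space = unit_square()
    blocks = [_random_winding_block(space, space.default_deltas(), rng) for _ in range(5)]
    D = set_spread(blocks)
    perm = list(rng.permutation(5))
    assert set_spread([blocks[i] for i in perm]) == pytest.approx(D)


def test_bruteforce_matches_exhaustive_enumeration(rng):
    space = unit_square()
    pool = [_random_winding_block(space, space.default_deltas(), rng) for _ in range(5)]
    best = select_ot_bruteforce(pool, 2, space=space)
    spreads = {
        combo: set_spread([pool[i] for i in combo])
        for combo in itertools.combinations(range(5), 2)
    }
    assert best.provenance["spread"] == pytest.approx(max(spreads.values()))


def test_eot_never_beats_bruteforce_and_m_equals_r_returns_pool(rng):
    space = unit_square()
    for trial in range(10):
        pool = [_random_winding_block(space, space.default_deltas(), rng) for _ in range(6)]
        eot = select_eot(pool, 3, space=space)
        ot = select_ot_bruteforce(pool, 3, space=space)
        assert eot.provenance["spread"] <= ot.provenance["spread"] + 1e-9
    pool = [_random_winding_block(space, space.default_deltas(), rng) for _ in range(3)]
    forced = select_eot(pool, 3, space=space)
    assert sorted(forced.provenance["selected"]) == [0, 1, 2]


def test_eot_beats_random_subsets_on_average(rng):
    space = unit_square()
    pool = [_random_winding_block(space, space.default_deltas(), rng) for _ in range(12)]
    eot_spread = select_eot(pool, 4, space=space).provenance["spread"]
    random_spreads = []
    for _ in range(100):
        idx = rng.choice(12, size=4, replace=False)
        random_spreads.append(set_spread([pool[i] for i in idx]))
    assert eot_spread >= np.mean(random_spreads)


def test_bruteforce_cap_refuses_large_pools(rng):
    space = unit_square()
    pool = [_random_winding_block(space, space.default_deltas(), rng) for _ in range(20)]
    with pytest.raises(ValueError, match="select_eot"):
        select_ot_bruteforce(pool, 10, space=space, cap=1000)


# ---------------------------------------------------------------- effect counts


def test_count_total_effects_examples():
    one = ParameterSpace([ParameterSpec("x", levels=4)])
    assert count_total_effects(one, [2 / 3]) == [2]
    k50 = ParameterSpace([ParameterSpec(f"x{i}", levels=4) for i in range(50)])
    counts = count_total_effects(k50, [2 / 3] * 50)
    assert counts[0] == 2 * 4**49
    mixed = ParameterSpace(
        [ParameterSpec("a", levels=4), ParameterSpec("b", levels=2)]
    )
    assert count_total_effects(mixed, [2 / 3, 1.0]) == [4, 4]


def test_count_total_effects_homogeneous_reduction():
    for p, c in [(4, 2), (6, 3)]:
        space = ParameterSpace([ParameterSpec(f"x{i}", levels=p) for i in range(3)])
        delta = c / (p - 1)
        expected = p**2 * (p - round(delta * (p - 1)))
        assert count_total_effects(space, [delta] * 3) == [expected] * 3


def test_count_total_effects_rejects_off_grid_step():
    space = ParameterSpace([ParameterSpec("x", levels=4)])
    with pytest.raises(ValueError, match="grid"):
        count_total_effects(space, [0.5])


def test_equal_level_sampling_probability(rng):
    # p=4, delta=2/3: each level visited with frequency ~1/4 over random blocks
    space = ParameterSpace([ParameterSpec("x", levels=4)])
    counts = np.zeros(4)
    n = 5000
    for _ in range(n):
        b = _random_winding_block(space, [2 / 3], rng)
        for v in b.unit_points[:, 0]:
            counts[round(v * 3)] += 1
    freqs = counts / (2 * n)
    np.testing.assert_allclose(freqs, 0.25, atol=0.02)
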