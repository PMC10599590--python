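import numpy as np
import pytest

from eescreen import (
    ParameterSpace,
    ParameterSpec,
    compute_effects,
    evaluate_design,
    generate_radial_design,
    generate_winding_design,
    input_scaling,
    scale_effects,
    summarize_effects,
)
from eescreen.effects import ModelEvaluationError
from eescreen.testfuncs import f6_function, default_space


def additive(X):
    return X[:, 0] + X[:, 1]


def test_constant_model_gives_constant_column_and_zero_effects(two_range_space):
    d = generate_winding_design(two_range_space, 3, base_source="random", rng=0)
    out = evaluate_design(d, lambda x: 7.0)
    assert np.all(out.values == 7.0)
    table = compute_effects(d, out)
    assert np.all(table.effects == 0.0)


def test_identity_model_outputs_equal_coordinates():
    space = ParameterSpace([ParameterSpec("x")])
    d = generate_radial_design(space, 3)
    out = evaluate_design(d, lambda X: X[:, 0], vectorized=True)
    np.testing.assert_allclose(out.values[:, 0], d.actual_matrix()[:, 0])


def test_additive_model_unit_effects(two_range_space):
    d = generate_winding_design(two_range_space, 4, base_source="random", rng=1)
    table = compute_effects(d, evaluate_design(d, additive, vectorized=True))
    np.testing.assert_allclose(table.effects, 1.0, atol=1e-9)


def test_quadratic_model_effects_match_closed_form(two_range_space):
    # Y = X1^2 + X2: EE_1 = Delta_1 + 2 X1 (at the from-point), EE_2 = 1
    d = generate_radial_design(two_range_space, 5)
    out = evaluate_design(d, lambda X: X[:, 0] ** 2 + X[:, 1], vectorized=True)
    table = compute_effects(d, out)
    for n, blk in enumerate(d.blocks):
        for rec in blk.step_records:
            ee = table.effects[rec.param_index, 0, n]
            if rec.param_index == 0:
                x1 = blk.actual_points[rec.from_row, 0]
                assert ee == pytest.approx(rec.Delta + 2 * x1, rel=1e-9)
            else:
                assert ee == pytest.approx(1.0, abs=1e-9)


def test_effect_sign_matches_derivative_for_downward_steps():
    space = ParameterSpace([ParameterSpec("x", min=0, max=10, levels=4)])
    d = generate_winding_design(space, 20, base_source="random", rng=2)
    table = compute_effects(d, evaluate_design(d, lambda X: 3.0 * X[:, 0], vectorized=True))
    np.testing.assert_allclose(table.effects, 3.0, atol=1e-9)
    deltas = [b.step_records[0].Delta for b in d.blocks]
    assert min(deltas) < 0 < max(deltas)  # both directions occurred


def test_model_failure_carries_block_and_row(two_range_space):
    d = generate_winding_design(two_range_space, 3, base_source="random", rng=0)

    calls = {"n": 0}

    def flaky(x):
        calls["n"] += 1
        if calls["n"] == 5:
            raise RuntimeError("boom")
        return 1.0

    with pytest.raises(ModelEvaluationError) as err:
        evaluate_design(d, flaky)
    assert err.value.block == 1 and err.value.row == 1


def test_scaling_rules_table_values(two_range_space):
    # ranges (20, 2): range rule (20, 2); discrete-uniform std rule (6.06, 0.82)
    np.testing.assert_allclose(input_scaling(two_range_space, "range"), [20.0, 2.0])
    np.testing.assert_allclose(
        input_scaling(two_range_space, "std"), [6.0553, 0.8165], atol=1e-4
    )
    np.testing.assert_allclose(input_scaling(two_range_space, "mean"), [10.0, 10.0])
    np.testing.assert_allclose(input_scaling(two_range_space, "none"), [1.0, 1.0])


def test_scale_effects_applies_and_records_factors(two_range_space):
    d = generate_winding_design(two_range_space, 4, base_source="random", rng=3)
    table = compute_effects(d, evaluate_design(d, additive, vectorized=True))
    scaled = scale_effects(table, c_x="range", space=two_range_space)
    np.testing.assert_allclose(scaled.effects[0], 20.0, atol=1e-8)
    np.testing.assert_allclose(scaled.effects[1], 2.0, atol=1e-9)
    assert scaled.scaled
    with pytest.raises(ValueError, match="already scaled"):
        scale_effects(scaled, c_x="range", space=two_range_space)
    identity = scale_effects(table, c_x=np.ones(2))
    np.testing.assert_allclose(identity.effects, table.effects)
    with pytest.raises(ValueError, match="positive"):
        scale_effects(table, c_x=np.array([1.0, -1.0]))


def test_scaled_mean_equals_mean_of_scaled(two_range_space):
    d = generate_radial_design(two_range_space, 6)
    table = compute_effects(
        d, evaluate_design(d, lambda X: X[:, 0] ** 2 - X[:, 1] ** 2, vectorized=True)
    )
    scaled = scale_effects(table, c_x="range", space=two_range_space)
    m_raw = summarize_effects(table)
    m_scaled = summarize_effects(scaled)
    c = input_scaling(two_range_space, "range")
    np.testing.assert_allclose(m_scaled.mu_star, m_raw.mu_star * c[:, None])
    np.testing.assert_allclose(m_scaled.chi, m_raw.chi * c[:, None])


def test_additive_model_radial_and_winding_effects_identical():
    # purely additive f6: same QR stream => identical effects per (input, block)
    space = default_space("f6")
    r = 8
    rad = generate_radial_design(space, r, seq="sobol")
    win = generate_winding_design(space, r, base_source="sobol")
    t_rad = compute_effects(rad, evaluate_design(rad, f6_function, vectorized=True))
    t_win = compute_effects(win, evaluate_design(win, f6_function, vectorized=True))
    np.testing.assert_allclose(t_rad.effects, t_win.effects, atol=1e-10)


def test_f6_outputs_bounded(two_range_space):
    space = default_space("f6")
    d = generate_radial_design(space, 10)
    out = evaluate_design(d, f6_function, vectorized=True)
    # bounding each additive term by its amplitude: sum g_i in [-6.71, -1.37]
    assert np.all(out.values >= -6.71) and np.all(out.values <= -1.37)


def test_row_count_mismatch_rejected(two_range_space):
    d = generate_winding_design(two_range_space, 3, base_source="random", rng=0)
    out = evaluate_design(d, additive, vectorized=True)
    from eescreen.effects import ModelOutputs

    bad = ModelOutputs(values=out.values[:-1], output_names=out.output_names)
    with pytest.raises(ValueError, match="rows"):
        compute_effects(d, bad)
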