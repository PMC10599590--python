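import numpy as np
import pytest

from eescreen import (
    EffectTable,
    ParameterSpace,
    ParameterSpec,
    classify_wu,
    normalized_index,
    summarize_effects,
    wang_beta,
    wang_tau,
    wu_index,
)


def table_from(effects):
    effects = np.asarray(effects, dtype=float)
    if effects.ndim == 2:  # (k, r) single output
        effects = effects[:, None, :]
    k = effects.shape[0]
    return EffectTable(
        effects=effects,
        input_names=tuple(f"x{i}" for i in range(k)),
        output_names=tuple(f"Y{j}" for j in range(effects.shape[1])),
    )


def test_summaries_mean_std_absolute_median():
    m = summarize_effects(table_from([[1.0, 2.0, 3.0, 4.0]]))
    assert m.mu[0, 0] == 2.5
    assert m.mu_star[0, 0] == 2.5
    assert m.chi[0, 0] == 2.5  # even r: midpoint of central values
    assert m.sigma[0, 0] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))


def test_cancellation_vs_absolute():
    m = summarize_effects(table_from([[1.0, -1.0]]))
    assert m.mu[0, 0] == 0.0
    assert m.mu_star[0, 0] == 1.0
    assert m.mu_star[0, 0] >= abs(m.mu[0, 0])


def test_single_effect_has_no_sigma():
    m = summarize_effects(table_from([[2.0]]))
    assert m.sigma is None
    with pytest.raises(ValueError, match="sigma"):
        m.aggregate("sigma")


def test_normalized_index_table3_values(two_range_space):
    # constant unit effects scaled by ranges (20, 2) -> (20/22, 2/22)
    m = summarize_effects(table_from([[1.0] * 4, [1.0] * 4]))
    S = normalized_index(m, "mu_star", space=two_range_space, c_x="range")
    np.testing.assert_allclose(S[:, 0], [20 / 22, 2 / 22])
    assert S[:, 0].sum() == pytest.approx(1.0, abs=1e-12)


def test_normalized_index_single_input_and_scale_invariance():
    space = ParameterSpace([ParameterSpec("only", min=0, max=5)])
    m = summarize_effects(table_from([[0.3, 0.4]]))
    assert normalized_index(m, "mu_star", space=space)[0, 0] == 1.0
    space2 = ParameterSpace([ParameterSpec("a", max=3.0), ParameterSpec("b", max=3.0)])
    m2 = summarize_effects(table_from([[1.0, 2.0], [3.0, 4.0]]))
    S = normalized_index(m2, "mu_star", space=space2)
    S_scaled = normalized_index(m2, "mu_star", c_x=np.array([7.0, 7.0]))
    np.testing.assert_allclose(S, S_scaled)


def test_normalized_index_all_zero_denominator_flagged():
    space = ParameterSpace([ParameterSpec("a"), ParameterSpec("b")])
    m = summarize_effects(table_from([[0.0, 0.0], [0.0, 0.0]]))
    with pytest.raises(ZeroDivisionError, match="undefined"):
        normalized_index(m, "mu_star", space=space)


def test_chi_and_mu_star_sum_to_one_per_output(rng):
    effects = rng.normal(size=(5, 3, 7))
    space = ParameterSpace([ParameterSpec(f"x{i}", max=float(i + 1)) for i in range(5)])
    m = summarize_effects(table_from(effects))
    for which in ("mu_star", "chi", "sigma"):
        S = normalized_index(m, which, space=space)
        np.testing.assert_allclose(S.sum(axis=0), 1.0, atol=1e-12)
        assert np.all((S >= 0) & (S <= 1))


# --------------------------------------------------------- legacy measures


def test_wang_tau_hand_example():
    # per-trajectory |EE| pairs (1,1) and (3,1): tau_1 = (1/2 + 3/4)/2
    t = table_from([[1.0, 3.0], [1.0, 1.0]])
    tau = wang_tau(t, dimensionless=True)
    assert tau[0, 0] == pytest.approx(0.625)
    assert tau[1, 0] == pytest.approx(0.375)
    np.testing.assert_allclose(tau.sum(axis=0), 1.0)
    np.testing.assert_allclose(wang_beta(tau), [0.625, 0.375])


def test_single_input_legacy_indices_are_one():
    t = table_from([[2.0, 5.0]])
    assert wang_tau(t, dimensionless=True)[0, 0] == 1.0
    assert wu_index(summarize_effects(t), dimensionless=True)[0, 0] == 1.0


def test_legacy_measures_refuse_dimensional_spaces(two_range_space):
    t = table_from([[1.0, 2.0], [3.0, 4.0]])
    with pytest.raises(ValueError, match="dimensionless"):
        wang_tau(t, space=two_range_space)
    with pytest.raises(ValueError, match="dimensionless"):
        wu_index(summarize_effects(t), space=two_range_space)
    unit = ParameterSpace([ParameterSpec("a"), ParameterSpec("b")])
    wang_tau(t, space=unit)  # unit-interval dimensionless space passes


# --------------------------------------------------------- classification


def test_classify_wu_worked_example():
    S = np.array([0.4, 0.3, 0.2, 0.06, 0.03, 0.01])
    c = classify_wu(S, h=10)
    assert c.q_unimportant == 2
    assert sorted(S[i] for i in c.unimportant) == [0.01, 0.03]
    assert c.threshold == pytest.approx(0.0624, abs=1e-3)
    assert sorted(S[i] for i in c.important) == [0.2, 0.3, 0.4]
    assert [S[i] for i in c.neither] == [0.06]


def test_classify_wu_partition_is_complete():
    S = np.array([0.5, 0.25, 0.13, 0.07, 0.05])
    c = classify_wu(S, h=30)
    assert sorted(c.unimportant + c.important + c.neither) == list(range(5))
    if c.unimportant:
        assert max(S[i] for i in c.unimportant) <= min(
            S[i] for i in c.important + c.neither
        )


def test_classify_wu_tiny_h_reports_undefined_threshold():
    c = classify_wu(np.array([0.6, 0.4]), h=1e-9)
    assert c.q_unimportant == 0
    assert c.threshold is None
    assert c.important == []


def test_classify_wu_single_unimportant_warns_sigma_zero():
    S = np.array([0.5, 0.3, 0.15, 0.05])
    with pytest.warns(UserWarning, match="sigma"):
        c = classify_wu(S, h=10)
    assert c.q_unimportant == 1
    assert c.threshold == pytest.approx(0.05)


def test_raising_n_sigma_never_adds_important():
    rng = np.random.default_rng(0)
    for _ in range(10):
        S = rng.dirichlet(np.ones(8))
        counts = []
        for ns in (1.0, 2.0, 3.0, 5.0):
            c = classify_wu(S, h=20, n_sigma=ns)
            counts.append(len(c.important))
        assert counts == sorted(counts, reverse=True)


def test_classify_wu_rejects_bad_inputs():
    with pytest.raises(ValueError, match="sum to 1"):
        classify_wu(np.array([0.5, 0.2]), h=10)
    with pytest.raises(ValueError, match="percentage"):
        classify_wu(np.array([0.5, 0.5]), h=0.0)
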