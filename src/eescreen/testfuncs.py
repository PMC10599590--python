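"""Built-in benchmark models and their canonical parameter spaces.

Four models of increasing realism, all accepting (n, k) matrices:

* ``K`` — alternating nested product, K(x) = sum_i (-1)^i prod_{j<=i} x_j on
  the unit hypercube; mildly nonlinear, importance decays with index.
* ``G*`` — shifted/curved product function with per-input shape constants
  a_i (importance damping), alpha_i (curvature) and offsets eta_i; strongly
  nonlinear with interactions.
* ``f6`` — purely additive sum of six fixed 1-D terms (the sixth constant),
  so radial and winding designs driven by the same stream give identical
  effects.
* ``PM`` — the Penman-Monteith equation for evapotranspiration in energy
  flux rate form, a dimensional model with eight inputs on heterogeneous
  ranges (the realistic screening case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .space import ParameterSpace, ParameterSpec

__all__ = [
    "k_function",
    "gstar_function",
    "f6_function",
    "penman_monteith",
    "default_space",
    "default_gstar_constants",
    "get_test_function",
    "TestFunction",
]


def k_function(x: np.ndarray) -> np.ndarray:
    """K(x) = sum_{i=1..k} (-1)^i prod_{j<=i} x_j, x in [0,1]^k; (n, k) -> (n,)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    prods = np.cumprod(x, axis=1)
    signs = (-1.0) ** np.arange(1, x.shape[1] + 1)
    return prods @ signs


def gstar_function(
    x: np.ndarray, a: np.ndarray, alpha: np.ndarray, eta: np.ndarray
) -> np.ndarray:
    """G*(x; a, alpha, eta) = prod_i [(1+alpha_i)|2(x_i+eta_i-floor(x_i+eta_i))-1|^alpha_i + a_i]/(1+a_i)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    a = np.asarray(a, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if np.any(a < 0) or np.any(alpha <= 0):
        raise ValueError("G* requires a_i >= 0 and alpha_i > 0")
    if np.any((eta < 0) | (eta > 1)):
        raise ValueError("G* requires eta_i in [0, 1]")
    s = x + eta
    inner = np.abs(2.0 * (s - np.floor(s)) - 1.0)
    factors = ((1.0 + alpha) * inner**alpha + a) / (1.0 + a)
    return factors.prod(axis=1)


def _f6_terms(x: np.ndarray) -> np.ndarray:
    g = np.empty_like(x)
    g[:, 0] = -np.sin(np.pi * x[:, 0]) - 0.3 * np.sin(3.33 * np.pi * x[:, 0])
    g[:, 1] = -0.76 * np.sin(np.pi * (x[:, 1] - 0.2)) - 0.315
    g[:, 2] = (
        -0.12 * np.sin(1.05 * np.pi * (x[:, 2] - 0.2))
        - 0.02 * np.sin(95.24 * np.pi * x[:, 2])
        - 0.96
    )
    g[:, 3] = -0.12 * np.sin(1.05 * np.pi * (x[:, 3] - 0.2)) - 0.96
    g[:, 4] = -0.05 * np.sin(np.pi * (x[:, 4] - 0.2)) - 1.02
    g[:, 5] = -1.08
    return g


def f6_function(x: np.ndarray) -> np.ndarray:
    """Additive six-input test function f6(x) = sum_i g_i(x_i) on [0,1]^6."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != 6:
        raise ValueError("f6 takes exactly 6 inputs")
    return _f6_terms(x).sum(axis=1)


_PM_RANGES = (
    # name, units, min, max
    ("Delta_ET", "kPa C-1", 0.05, 0.4),
    ("A_ET", "W m-2", 0.0, 400.0),
    ("rho_a", "kg m-3", 1.1, 1.3),
    ("c_p", "J kg-1 C-1", 1000.0, 1050.0),
    ("VPD", "kPa", 0.3, 3.0),
    ("g_a", "m s-1", 0.0133, 0.25),
    ("gamma", "kPa C-1", 0.065, 0.07),
    ("g_s", "m s-1", 0.005, 0.02),
)


def penman_monteith(X: np.ndarray) -> np.ndarray:
    """Evapotranspiration ET [W m-2] in energy flux rate form.

    Inputs in column order (Delta_ET, A_ET, rho_a, c_p, VPD, g_a, gamma, g_s):
    saturation-humidity slope, available energy, dry-air density, specific
    heat of air, vapor pressure deficit, air conductivity, psychrometric
    constant and stomatal conductivity. Values outside the canonical
    screening ranges warn; a nonpositive stomatal conductivity is an error.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != 8:
        raise ValueError("Penman-Monteith takes exactly 8 inputs")
    d, A, rho, cp, vpd, ga, gamma, gs = X.T
    if np.any(gs <= 0):
        raise ValueError("stomatal conductivity g_s must be positive")
    for col, (name, _, lo, hi) in zip(X.T, _PM_RANGES):
        if np.any(col < lo) or np.any(col > hi):
            warnings.warn(
                f"Penman-Monteith input {name} outside canonical range [{lo}, {hi}]",
                stacklevel=2,
            )
            break
    return (d * A + rho * cp * ga * vpd) / (d + gamma * (1.0 + ga / gs))


def _unit_space(k: int, levels: int = 4) -> ParameterSpace:
    return ParameterSpace(
        [ParameterSpec(name=f"x{i + 1}", min=0.0, max=1.0, levels=levels) for i in range(k)]
    )


def default_gstar_constants(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (a, alpha) constants for the G* benchmark at k = 10 or 50."""
    base = [0.0, 0.1, 0.2, 0.3, 0.4, 0.8, 1.0, 2.0, 3.0, 4.0]
    if k == 10:
        a = np.array(base)
        alpha = np.full(10, 2.0)
    elif k == 50:
        a = np.array(
            base
            + base
            + [0.0, 1.0, 2.0, 3.0, 4.0, 8.0, 10.0, 20.0, 30.0, 40.0]
            + [0.0, 2.0, 4.0, 6.0, 8.0, 16.0, 20.0, 40.0, 60.0, 80.0]
            + [0.0, 5.0, 10.0, 15.0, 20.0, 40.0, 50.0, 100.0, 150.0, 200.0]
        )
        alpha = np.concatenate([np.full(10, 2.0), np.full(40, 0.2)])
    else:
        raise ValueError(f"no canonical G* constants for k={k}")
    return a, alpha


def default_space(func_id: str, k: int | None = None, levels: int = 4) -> ParameterSpace:
    """Canonical parameter space for a benchmark function id."""
    if func_id == "K":
        if k not in (10, 50, 75, 100):
            raise ValueError(f"K-function supports k in {{10, 50, 75, 100}}, got {k}")
        return _unit_space(k, levels)
    if func_id == "G*":
        if k not in (10, 50):
            raise ValueError(f"G* supports k in {{10, 50}}, got {k}")
        return _unit_space(k, levels)
    if func_id == "f6":
        if k not in (None, 6):
            raise ValueError("f6 has exactly 6 inputs")
        return _unit_space(6, levels)
    if func_id == "PM":
        if k not in (None, 8):
            raise ValueError("Penman-Monteith has exactly 8 inputs")
        return ParameterSpace(
            [
                ParameterSpec(name=n, units=u, min=lo, max=hi, levels=levels)
                for (n, u, lo, hi) in _PM_RANGES
            ]
        )
    raise ValueError(f"unknown test function {func_id!r}")


@dataclass(frozen=True)
class TestFunction:
    """A registered benchmark model bound to its canonical space."""

    id: str
    k: int
    space: ParameterSpace
    evaluator: Callable[[np.ndarray], np.ndarray]  # (n, k) -> (n,)
    constants: dict


def get_test_function(
    func_id: str,
    k: int | None = None,
    eta: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    levels: int = 4,
) -> TestFunction:
    """Instantiate a benchmark by id.

    For G*, ``eta`` defaults to zeros (deterministic); pass ``rng`` to sample
    the offsets uniformly per the benchmark's replicate protocol (the total
    sensitivity indices do not depend on eta).
    """
    space = default_space(func_id, k, levels=levels)
    kk = space.k
    constants: dict = {}
    if func_id == "K":
        ev = k_function
    elif func_id == "G*":
        a, alpha = default_gstar_constants(kk)
        if eta is None:
            if rng is not None:
                eta = np.random.default_rng(rng).random(kk)
            else:
                eta = np.zeros(kk)
        constants = {"a": a, "alpha": alpha, "eta": np.asarray(eta, dtype=float)}
        ev = lambda x, a=a, alpha=alpha, eta=constants["eta"]: gstar_function(x, a, alpha, eta)
    elif func_id == "f6":
        ev = f6_function
    elif func_id == "PM":
        ev = penman_monteith
    else:
        raise ValueError(f"unknown test function {func_id!r}")
    return TestFunction(id=func_id, k=kk, space=space, evaluator=ev, constants=constants)
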