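"""Mixed-type, dimensional input parameters and their unit-hypercube discretization.

An elementary-effects analysis works on the discrete unit hypercube: each input
``X_i`` with bounds ``[min_i, max_i]`` (in its own units) is mapped to a scaled
dimensionless coordinate ``x_i = (X_i - min_i)/(max_i - min_i)`` that takes
values on a regular grid of ``p_i`` levels, ``{j/(p_i-1) : j = 0..p_i-1}``.
Boolean inputs force ``p_i = 2`` on ``{0, 1}``; integer inputs require the range
to be a multiple of ``p_i - 1`` so every grid level maps back to an integer.

Non-uniform input distributions are supported through an optional inverse-CDF
hook: levels stay equi-spaced in unit space and the hook maps unit coordinates
to actual values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "ParameterSpec",
    "ParameterSpace",
    "StepSpec",
    "to_unit",
    "from_unit",
    "level_grid",
    "optimal_step",
    "validate_space",
]

_VTYPES = ("real", "integer", "boolean")


@dataclass(frozen=True)
class ParameterSpec:
    """One named, typed, ranged, unit-annotated model input.

    Parameters
    ----------
    name : str
        Identifier; unique within a space.
    vtype : {"real", "integer", "boolean"}
        Value type. Booleans are encoded 0/1.
    min, max : float
        Bounds in actual units, ``min < max``.
    levels : int
        Number of grid levels ``p_i >= 2`` in unit space.
    units : str
        Free-text unit label; opaque (no dimensional algebra is performed).
    inv_cdf : callable, optional
        Monotone map [0, 1] -> [min, max] used instead of the uniform affine
        map when the input is not uniformly distributed.
    """

    name: str
    vtype: str = "real"
    min: float = 0.0
    max: float = 1.0
    levels: int = 4
    units: str = ""
    inv_cdf: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.vtype not in _VTYPES:
            raise ValueError(
                f"parameter {self.name!r}: vtype must be one of {_VTYPES}, "
                f"got {self.vtype!r}"
            )
        if not self.min < self.max:
            raise ValueError(
                f"parameter {self.name!r}: require min < max, got "
                f"[{self.min}, {self.max}]"
            )
        if self.levels < 2:
            raise ValueError(
                f"parameter {self.name!r}: levels must be >= 2, got {self.levels}"
            )

    @property
    def range(self) -> float:
        """Input range ``max - min`` (actual units)."""
        return self.max - self.min

    @property
    def is_discrete(self) -> bool:
        return self.vtype in ("integer", "boolean")

    def violations(self) -> list[str]:
        """Per-parameter invariant violations (empty list when valid)."""
        out: list[str] = []
        if self.vtype == "boolean":
            if (self.min, self.max) != (0.0, 1.0):
                out.append(
                    f"{self.name}: boolean inputs must have bounds [0, 1], "
                    f"got [{self.min}, {self.max}]"
                )
            if self.levels != 2:
                out.append(
                    f"{self.name}: boolean inputs must have exactly 2 levels, "
                    f"got {self.levels}"
                )
        elif self.vtype == "integer":
            span = Fraction(self.max - self.min).limit_denominator(10**9)
            m = span / (self.levels - 1)
            if m.denominator != 1 or m <= 0:
                out.append(
                    f"{self.name}: integer inputs require max - min to be a "
                    f"positive integer multiple of levels - 1 "
                    f"(got range {self.max - self.min} with {self.levels} levels)"
                )
        return out


@dataclass(frozen=True)
class StepSpec:
    """A fixed perturbation step in unit (``delta``) and actual (``Delta``) space."""

    delta: float
    Delta: float

    @classmethod
    def for_spec(cls, spec: ParameterSpec, delta: float) -> "StepSpec":
        return cls(delta=delta, Delta=spec.range * delta)


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered collection of :class:`ParameterSpec`; file/config order is column order."""

    params: tuple[ParameterSpec, ...]

    def __init__(self, params: Sequence[ParameterSpec]):
        params = tuple(params)
        if len(params) < 1:
            raise ValueError("a parameter space needs at least one parameter")
        names = [p.name for p in params]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate parameter names: {dupes}")
        object.__setattr__(self, "params", params)

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.params]

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self.params)

    def __getitem__(self, i: int) -> ParameterSpec:
        return self.params[i]

    # -- vectorized transforms over all coordinates ------------------------

    def to_unit(self, X: np.ndarray) -> np.ndarray:
        """Map actual-space points (n, k) or (k,) to unit space."""
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X, dtype=float)
        for i, p in enumerate(self.params):
            out[..., i] = to_unit(X[..., i], p)
        return out

    def from_unit(self, x: np.ndarray) -> np.ndarray:
        """Map unit-space points (n, k) or (k,) to actual space."""
        x = np.asarray(x, dtype=float)
        out = np.empty_like(x, dtype=float)
        for i, p in enumerate(self.params):
            out[..., i] = from_unit(x[..., i], p)
        return out

    def ranges(self) -> np.ndarray:
        return np.array([p.range for p in self.params])

    def default_deltas(self) -> np.ndarray:
        """Per-parameter fixed step magnitudes |delta_i| (see :func:`optimal_step`)."""
        return np.array([optimal_step(p.levels) for p in self.params])


def to_unit(X, spec: ParameterSpec):
    """Scale an actual value to the unit interval.

    Uniform specs use the affine map ``(X - min)/(max - min)``; a spec with an
    ``inv_cdf`` hook is inverted numerically (bisection on the monotone map).
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < spec.min - 1e-12 * max(1.0, abs(spec.min))) or np.any(
        X > spec.max + 1e-12 * max(1.0, abs(spec.max))
    ):
        raise ValueError(
            f"value out of range for parameter {spec.name!r}: "
            f"{X!r} not in [{spec.min}, {spec.max}]"
        )
    if spec.inv_cdf is None:
        return (X - spec.min) / (spec.max - spec.min)
    # invert the monotone hook by bisection
    scalar = X.ndim == 0
    Xf = np.atleast_1d(X)
    lo = np.zeros_like(Xf)
    hi = np.ones_like(Xf)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        too_low = np.asarray(spec.inv_cdf(mid), dtype=float) < Xf
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    res = 0.5 * (lo + hi)
    return res[0] if scalar else res


def from_unit(x, spec: ParameterSpec):
    """Map a unit-interval value to the actual parameter range."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError(
            f"unit coordinate out of [0, 1] for parameter {spec.name!r}: {x!r}"
        )
    if spec.inv_cdf is None:
        return spec.min + x * (spec.max - spec.min)
    return np.asarray(spec.inv_cdf(x), dtype=float)


def level_grid(spec: ParameterSpec) -> np.ndarray:
    """Unit-space grid ``{j/(p-1) : j = 0..p-1}``, strictly increasing, endpoints 0 and 1."""
    p = spec.levels
    return np.arange(p) / (p - 1)


def optimal_step(levels: int) -> float:
    """Fixed step magnitude |delta| giving (near-)equal level sampling probabilities.

    For even ``p`` the optimum ``p/(2(p-1))`` is itself a grid multiple of
    ``1/(p-1)`` and is returned exactly. For odd ``p`` the optimum is not
    attainable on the grid; the nearest admissible multiple below it,
    ``floor(p/2)/(p-1)``, is used and a warning is emitted.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    p = levels
    if p % 2 == 0:
        return p / (2 * (p - 1))
    warnings.warn(
        f"optimal step p/(2(p-1)) is not a grid multiple for odd p={p}; "
        f"using {p // 2}/{p - 1}",
        stacklevel=2,
    )
    return (p // 2) / (p - 1)


def validate_space(space: ParameterSpace) -> list[str]:
    """Collect invariant violations for every parameter (diagnostics, not exceptions)."""
    out: list[str] = []
    for p in space:
        out.extend(p.violations())
    return out
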