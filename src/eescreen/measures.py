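"""Aggregation of elementary effects into sensitivity measures and rankings.

Per (input, output) the classical summaries are the mean mu, the
(r-1)-denominator standard deviation sigma, the mean of absolute effects
mu_star (which filters sign cancellation) and the median of absolute effects
chi (robust to the heavy tails common at small r). From the range-scaled
aggregates, the dimensionless normalized indices

    S_m(i, j) = m_ij * c_x_i / sum_l m_lj * c_x_l,   m in {mu_star, chi, sigma}

take values in [0, 1] and sum to one per output, enabling the threshold-based
importance classification of Wu: sort the indices ascending, call the largest
prefix with cumulative mass < h/100 unimportant, and call important every
index above mu_hat_0 + n_sigma * sigma_hat_0 of that unimportant group.

The legacy dimensionless-model measures (per-trajectory normalized tau, its
output average beta, and the normalized mu_star index) sum effects across
inputs and are therefore uninterpretable when inputs carry different units;
they are gated behind an explicit ``dimensionless`` flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .effects import EffectTable, input_scaling

__all__ = [
    "MeasureSet",
    "Classification",
    "summarize_effects",
    "normalized_index",
    "wang_tau",
    "wang_beta",
    "wu_index",
    "classify_wu",
]


@dataclass
class MeasureSet:
    """Aggregated measures per (input i, output j); arrays of shape (k, q)."""

    mu: np.ndarray
    sigma: np.ndarray | None
    mu_star: np.ndarray
    chi: np.ndarray
    input_names: tuple[str, ...]
    output_names: tuple[str, ...]
    r: int

    def aggregate(self, which: str) -> np.ndarray:
        if which == "mu_star":
            return self.mu_star
        if which == "chi":
            return self.chi
        if which == "sigma":
            if self.sigma is None:
                raise ValueError("sigma was not computed (r < 2)")
            return self.sigma
        raise ValueError(f"unknown aggregate {which!r}")


@dataclass
class Classification:
    """Wu importance partition for one output."""

    order: np.ndarray  # input indices sorted by ascending S
    S_sorted: np.ndarray
    q_unimportant: int
    threshold: float | None  # S_0 = mu_hat_0 + n_sigma * sigma_hat_0; None if q = 0
    unimportant: list[int]
    important: list[int]
    neither: list[int]
    h: float
    n_sigma: float


def summarize_effects(table: EffectTable) -> MeasureSet:
    """mu, sigma, mu_star and chi over the r effects per (input, output).

    sigma uses the (r-1) denominator and is only defined for r >= 2; the
    median for even r is the midpoint of the two central values.
    """
    eff = table.effects
    r = table.r
    if r < 1:
        raise ValueError("need at least one effect per input")
    mu = eff.mean(axis=2)
    sigma = eff.std(axis=2, ddof=1) if r >= 2 else None
    abs_eff = np.abs(eff)
    return MeasureSet(
        mu=mu,
        sigma=sigma,
        mu_star=abs_eff.mean(axis=2),
        chi=np.median(abs_eff, axis=2),
        input_names=table.input_names,
        output_names=table.output_names,
        r=r,
    )


def normalized_index(
    measures: MeasureSet,
    which: str = "mu_star",
    space=None,
    c_x: np.ndarray | str = "range",
) -> np.ndarray:
    """Normalized dimensionless sensitivity index S(i, j), shape (k, q).

    The chosen aggregate is scaled by c_x_i (default: input range) and
    normalized to sum to one over inputs for each output. If the table was
    already scaled, pass ``c_x="none"``.
    """
    m = measures.aggregate(which)
    if isinstance(c_x, str):
        if c_x == "none":
            c_x = np.ones(m.shape[0])
        else:
            if space is None:
                raise ValueError("a ParameterSpace is required for a named c_x rule")
            c_x = input_scaling(space, c_x)
    scaled = m * np.asarray(c_x, dtype=float)[:, None]
    denom = scaled.sum(axis=0)
    if np.any(denom == 0):
        bad = [measures.output_names[j] for j in np.where(denom == 0)[0]]
        raise ZeroDivisionError(
            f"all scaled aggregates are zero for output(s) {bad}; "
            "normalized index undefined"
        )
    return scaled / denom


def _require_dimensionless(space, dimensionless: bool, name: str) -> None:
    if dimensionless:
        return
    if space is not None and all(p.units == "" and p.min == 0 and p.max == 1 for p in space):
        return
    raise ValueError(
        f"{name} sums effects across inputs and is only interpretable for "
        "dimensionless unit-interval models; pass dimensionless=True to override"
    )


def wang_tau(table: EffectTable, space=None, dimensionless: bool = False) -> np.ndarray:
    """Per-trajectory normalized effect, averaged over trajectories; shape (k, q)."""
    _require_dimensionless(space, dimensionless, "wang_tau")
    abs_eff = np.abs(table.effects)  # (k, q, r)
    denom = abs_eff.sum(axis=0, keepdims=True)
    if np.any(denom == 0):
        raise ZeroDivisionError("all effects zero on some trajectory")
    return (abs_eff / denom).mean(axis=2)


def wang_beta(taus: np.ndarray) -> np.ndarray:
    """Average of tau over outputs; shape (k,)."""
    return np.asarray(taus).mean(axis=1)


def wu_index(measures: MeasureSet, space=None, dimensionless: bool = False) -> np.ndarray:
    """mu_star normalized over inputs (no input scaling); shape (k, q)."""
    _require_dimensionless(space, dimensionless, "wu_index")
    denom = measures.mu_star.sum(axis=0)
    if np.any(denom == 0):
        raise ZeroDivisionError("all mu_star zero for some output")
    return measures.mu_star / denom


def classify_wu(S: np.ndarray, h: float = 30.0, n_sigma: float = 3.0) -> Classification:
    """Importance classification from one output's normalized indices.

    Sort S ascending; the unimportant set is the largest prefix whose
    cumulative sum stays strictly below h/100. The importance threshold
    S_0 = mu_hat_0 + n_sigma * sigma_hat_0 is computed over that prefix
    (sigma_hat_0 = 0 with a warning when the prefix has a single member, and
    the threshold is undefined when it is empty). Inputs above S_0 are
    important; the rest are neither.
    """
    S = np.asarray(S, dtype=float).ravel()
    if not 0 < h < 100:
        raise ValueError("h must be a percentage in (0, 100)")
    if not np.isclose(S.sum(), 1.0, atol=1e-9):
        raise ValueError("S must sum to 1 over inputs")
    order = np.argsort(S, kind="stable")
    S_sorted = S[order]
    cum = np.cumsum(S_sorted)
    q = int(np.sum(cum < h / 100))
    unimportant = [int(i) for i in order[:q]]
    if q == 0:
        # empty unimportant group: no threshold can be formed
        threshold = None
        important: list[int] = []
        neither = [int(i) for i in order]
    else:
        mu0 = float(S_sorted[:q].mean())
        if q == 1:
            warnings.warn(
                "single unimportant parameter: sigma_hat_0 undefined, using 0",
                stacklevel=2,
            )
            sig0 = 0.0
        else:
            sig0 = float(S_sorted[:q].std(ddof=1))
        threshold = mu0 + n_sigma * sig0
        rest = [int(i) for i in order[q:]]
        important = [i for i in rest if S[i] > threshold]
        neither = [i for i in rest if S[i] <= threshold]
    return Classification(
        order=order,
        S_sorted=S_sorted,
        q_unimportant=q,
        threshold=threshold,
        unimportant=unimportant,
        important=important,
        neither=neither,
        h=h,
        n_sigma=n_sigma,
    )
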